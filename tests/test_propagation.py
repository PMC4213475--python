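"""Signal-transmission probability: requirements, inclusion-exclusion, oracle checks."""

import numpy as np
import pandas as pd
import pytest

from sigcircuits.circuits import enumerate_circuits, pathway_circuits
from sigcircuits.pathway_io import ACTIVATION, INHIBITION, NodeSpec, PathwayGraph
from sigcircuits.propagation import (
    activity_matrix,
    circuit_events,
    circuit_probability,
    path_probability,
    path_requirements,
    union_probability,
)
from sigcircuits.simulate import make_random_pathway


def build(nodes, edges, pid="t"):
    specs = {n: NodeSpec(n, "single", (f"g{n}",)) for n in nodes}
    return PathwayGraph(pathway_id=pid, nodes=specs, edges=edges)


def mc_oracle(events, node_probs, draws, rng):
    """Bernoulli-sampling oracle: any path's requirements satisfied?"""
    nodes = sorted(node_probs)
    idx = {n: i for i, n in enumerate(nodes)}
    states = rng.random((draws, len(nodes))) < np.array([node_probs[n] for n in nodes])
    hit = np.zeros(draws, dtype=bool)
    for ev in events:
        ok = np.ones(draws, dtype=bool)
        for node, state in ev.requirements:
            ok &= states[:, idx[node]] == state
        hit |= ok
    return hit.mean()


class TestPathRequirements:
    def test_plain_activation_chain(self):
        g = build("ABC", [("A", "B", ACTIVATION), ("B", "C", ACTIVATION)])
        (circ,) = enumerate_circuits(g)
        ev = path_requirements(circ.paths[0], g)
        assert ev.consistent and ev.net_activating
        assert dict(ev.requirements) == {"A": True, "B": True, "C": True}

    def test_external_inhibitor_required_inactive(self):
        g = build(
            "ABCI",
            [("A", "B", ACTIVATION), ("B", "C", ACTIVATION), ("I", "B", INHIBITION)],
        )
        circ = [c for c in enumerate_circuits(g) if c.input_node == "A"][0]
        ev = path_requirements(circ.paths[0], g)
        assert dict(ev.requirements) == {"A": True, "B": True, "C": True, "I": False}

    def test_on_path_inhibitor_of_same_path_is_contradiction(self):
        # D is on the path A->B->D but also inhibits B through a side edge
        g = build(
            "ABD",
            [("A", "B", ACTIVATION), ("B", "D", ACTIVATION), ("D", "B", INHIBITION)],
        )
        from sigcircuits.circuits import LinearPath

        p = LinearPath(nodes=("A", "B", "D"), signs=(ACTIVATION, ACTIVATION))
        ev = path_requirements(p, g)
        assert not ev.consistent
        assert path_probability(ev, {"A": 0.9, "B": 0.9, "D": 0.9}) == 0.0

    def test_in_path_inhibition_flips_downstream_state(self):
        g = build("ABC", [("A", "B", INHIBITION), ("B", "C", ACTIVATION)])
        (circ,) = enumerate_circuits(g)
        ev = path_requirements(circ.paths[0], g)
        assert dict(ev.requirements) == {"A": True, "B": False, "C": False}
        assert not ev.net_activating

    def test_double_inhibition_restores_activating_parity(self):
        g = build("ABC", [("A", "B", INHIBITION), ("B", "C", INHIBITION)])
        (circ,) = enumerate_circuits(g)
        ev = path_requirements(circ.paths[0], g)
        assert ev.net_activating
        assert dict(ev.requirements) == {"A": True, "B": False, "C": True}


class TestPathProbability:
    def test_product_of_active_requirements(self):
        g = build("AB", [("A", "B", ACTIVATION)])
        (circ,) = enumerate_circuits(g)
        ev = path_requirements(circ.paths[0], g)
        assert path_probability(ev, {"A": 0.9, "B": 0.8}) == pytest.approx(0.72)

    def test_inhibitor_limits(self):
        g = build(
            "ABI", [("A", "B", ACTIVATION), ("I", "B", INHIBITION)]
        )
        circ = [c for c in enumerate_circuits(g) if c.input_node == "A"][0]
        ev = path_requirements(circ.paths[0], g)
        assert path_probability(ev, {"A": 1.0, "B": 1.0, "I": 0.0}) == pytest.approx(1.0)
        assert path_probability(ev, {"A": 1.0, "B": 1.0, "I": 1.0}) == pytest.approx(0.0)


class TestCircuitProbability:
    def test_single_path_equals_path_probability(self):
        g = build("ABC", [("A", "B", ACTIVATION), ("B", "C", ACTIVATION)])
        (circ,) = enumerate_circuits(g)
        probs = {"A": 0.5, "B": 0.7, "C": 0.9}
        ev = path_requirements(circ.paths[0], g)
        assert circuit_probability(circ, probs, g) == pytest.approx(
            path_probability(ev, probs)
        )

    def test_two_disjoint_paths_obey_independence_formula(self):
        g = build(
            "SXYT",
            [
                ("S", "X", ACTIVATION),
                ("S", "Y", ACTIVATION),
                ("X", "T", ACTIVATION),
                ("Y", "T", ACTIVATION),
            ],
        )
        (circ,) = enumerate_circuits(g)
        # shared endpoints S and T; condition on them to get the union formula
        probs = {"S": 1.0, "T": 1.0, "X": 0.6, "Y": 0.3}
        p, q = 0.6, 0.3
        assert circuit_probability(circ, probs, g) == pytest.approx(p + q - p * q)

    def test_shared_node_correlates_paths(self):
        """Both paths require the shared node D: union < independent combination."""
        g = build(
            "ADFGH",
            [
                ("A", "D", ACTIVATION),
                ("D", "F", ACTIVATION),
                ("D", "G", ACTIVATION),
                ("F", "H", ACTIVATION),
                ("G", "H", ACTIVATION),
            ],
        )
        (circ,) = enumerate_circuits(g)
        probs = dict.fromkeys("ADFGH", 0.5)
        got = circuit_probability(circ, probs, g)
        # exact union: P(A,D,H all on) * P(F on or G on) = 0.5^3 * 0.75
        assert got == pytest.approx(0.5**3 * 0.75)

    def test_permuting_path_order_leaves_result_unchanged(self, fig6):
        circ = [c for c in enumerate_circuits(fig6) if c.circuit_id == "A->H"][0]
        probs = {n: 0.3 + 0.05 * i for i, n in enumerate(sorted(circ.node_ids))}
        forward = circuit_probability(circ, probs, fig6)
        circ.paths.reverse()
        assert circuit_probability(circ, probs, fig6) == pytest.approx(forward)

    def test_union_bounds(self, rng):
        for seed in range(10):
            g = make_random_pathway(np.random.default_rng(seed), n_nodes=8)
            kept, _ = pathway_circuits(g)
            for circ in kept:
                probs = {n: rng.random() for n in g.nodes}
                events = circuit_events(circ, g)
                if not events:
                    continue
                per_path = [path_probability(e, probs) for e in events]
                u = circuit_probability(circ, probs, g)
                assert max(per_path) - 1e-12 <= u <= min(1.0, sum(per_path)) + 1e-12

    def test_monotone_in_node_probabilities(self, fig6):
        circ = [c for c in enumerate_circuits(fig6) if c.circuit_id == "A->H"][0]
        probs = dict.fromkeys(fig6.nodes, 0.5)
        base = circuit_probability(circ, probs, fig6)
        for node in circ.node_ids:
            raised = dict(probs, **{node: 0.8})
            assert circuit_probability(circ, raised, fig6) >= base - 1e-12

    def test_raising_external_inhibitor_never_increases(self, inhib):
        kept, _ = pathway_circuits(inhib)
        circ = [c for c in kept if c.input_node == "X"][0]
        lo = circuit_probability(circ, {"X": 0.8, "Y": 0.8, "Z": 0.8, "N": 0.1}, inhib)
        hi = circuit_probability(circ, {"X": 0.8, "Y": 0.8, "Z": 0.8, "N": 0.9}, inhib)
        assert hi <= lo

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_bernoulli_sampling_oracle(self, seed):
        """Inclusion-exclusion equals Monte-Carlo over independent node states."""
        gen = np.random.default_rng(seed)
        g = make_random_pathway(gen, n_nodes=8, inhibition_prob=0.3, pathway_id=f"o{seed}")
        kept, _ = pathway_circuits(g)
        probs = {n: float(gen.random()) for n in g.nodes}
        draws = 200_000
        mc_rng = np.random.default_rng(10_000 + seed)
        for circ in kept[:3]:
            events = circuit_events(circ, g)
            exact = circuit_probability(circ, probs, g)
            approx = mc_oracle(events, probs, draws, mc_rng)
            sd = np.sqrt(max(exact * (1 - exact), 1e-12) / draws)
            assert abs(exact - approx) <= 3 * sd + 1e-6


class TestActivityMatrix:
    def test_identical_samples_give_identical_entries(self, fig6):
        kept, _ = pathway_circuits(fig6)
        nodes = pd.DataFrame(
            np.full((len(fig6.nodes), 2), 0.6),
            index=list(fig6.nodes),
            columns=["s1", "s2"],
        )
        act = activity_matrix(kept, nodes, fig6)
        assert act.shape == (5, 2)
        np.testing.assert_allclose(act["s1"], act["s2"])

    def test_all_ones_on_activation_only_circuit(self, fig6):
        kept, _ = pathway_circuits(fig6)
        nodes = pd.DataFrame(
            np.ones((len(fig6.nodes), 1)), index=list(fig6.nodes), columns=["s"]
        )
        act = activity_matrix(kept, nodes, fig6)
        np.testing.assert_allclose(act["s"], 1.0)

    def test_certain_external_inhibitor_zeroes_circuit(self, inhib):
        kept, _ = pathway_circuits(inhib)
        nodes = pd.DataFrame(
            np.ones((len(inhib.nodes), 1)), index=list(inhib.nodes), columns=["s"]
        )
        act = activity_matrix(kept, nodes, inhib)
        assert act.loc["X->Z", "s"] == pytest.approx(0.0)

    def test_values_lie_in_unit_interval(self, fig6, rng):
        kept, _ = pathway_circuits(fig6)
        nodes = pd.DataFrame(
            rng.random((len(fig6.nodes), 5)), index=list(fig6.nodes),
            columns=[f"s{i}" for i in range(5)],
        )
        act = activity_matrix(kept, nodes, fig6)
        assert ((act.to_numpy() >= 0) & (act.to_numpy() <= 1)).all()
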