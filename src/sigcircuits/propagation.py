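"""Probability of signal transmission along circuits.

A linear path transmits when (a) the nodes it traverses are in the state the
chain of edge signs requires and (b) every external inhibitor of an
active-required on-path node is itself inactive.  Node activations are treated
as independent Bernoulli events shared across paths, so the probability that
a circuit transmits — that at least one of its linear paths does — is the
probability of a union of correlated events, computed exactly by
inclusion–exclusion:

    P(U A_k) = sum P(A_k) - sum P(A_i ∩ A_j) + ... + (-1)^(n+1) P(A_1 ∩ ... ∩ A_n)

where each intersection is the product over the merged requirement set (zero
when a node would be required both active and inactive).

Repression convention: an inhibition edge along a path requires its source
present (it transmits the repressive signal) and inverts the required state
of everything downstream; a second in-path inhibition restores activating
parity.  A path counts toward circuit *activation* only when its net parity
is activating.  This convention lives entirely in :func:`path_requirements`
so it can be swapped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping

import numpy as np
import pandas as pd

from .circuits import Circuit, LinearPath
from .pathway_io import INHIBITION, PathwayGraph

logger = logging.getLogger("sigcircuits.propagation")

MAX_EXACT_PATHS = 20
MC_DRAWS = 100_000

Number = float | np.ndarray


@dataclass(frozen=True)
class PathEvent:
    """Requirement set of one linear path.

    ``requirements`` maps node_id -> required activity (True = active).
    ``net_activating`` is whether the path delivers an activating signal to
    the effector (even number of in-path inhibitions).  ``consistent`` is
    False when some node would be required both active and inactive, which
    makes the event impossible.
    """

    requirements: tuple[tuple[str, bool], ...]
    net_activating: bool
    consistent: bool

    def as_dict(self) -> dict[str, bool]:
        return dict(self.requirements)


def path_requirements(path: LinearPath, graph: PathwayGraph) -> PathEvent:
    """Node-state requirements for one linear path to transmit signal.

    On-path nodes are required active until an in-path inhibition edge flips
    the required state of everything downstream of it.  For every on-path node
    required active, sources of inhibition edges into it (other than the
    path's own edge) are required inactive; if such a source is itself
    required active on the path the event is inconsistent.
    """
    req: dict[str, bool] = {}
    consistent = True

    def require(node: str, state: bool) -> None:
        nonlocal consistent
        if req.setdefault(node, state) != state:
            consistent = False

    parity = 0
    states: list[bool] = []
    for i, node in enumerate(path.nodes):
        state = parity % 2 == 0
        states.append(state)
        require(node, state)
        if i < len(path.signs) and path.signs[i] == INHIBITION:
            parity += 1

    path_edges = set(zip(path.nodes, path.nodes[1:]))
    for node, state in zip(path.nodes, states):
        if not state:
            continue  # a repressed node needs no guard on its inhibitors
        for inhibitor in graph.inhibitors_of(node):
            if (inhibitor, node) in path_edges:
                continue  # the path's own repressive edge, handled by parity
            require(inhibitor, False)

    return PathEvent(
        requirements=tuple(sorted(req.items())),
        net_activating=parity % 2 == 0,
        consistent=consistent,
    )


def path_probability(
    requirements: PathEvent | Mapping[str, bool],
    node_probs: Mapping[str, Number],
) -> Number:
    """Product over requirements: P(active) or 1 - P(active) per node.

    Node probabilities may be scalars or per-sample arrays (broadcast).
    Nodes absent from ``node_probs`` are non-informative and contribute no
    factor.  An inconsistent event has probability 0.
    """
    if isinstance(requirements, PathEvent):
        if not requirements.consistent:
            return 0.0
        items = requirements.requirements
    else:
        items = tuple(requirements.items())
    prob: Number = 1.0
    skipped = 0
    for node, state in items:
        p = node_probs.get(node)
        if p is None:
            skipped += 1
            continue
        p = np.asarray(p, dtype=float) if not np.isscalar(p) else p
        prob = prob * (p if state else 1.0 - p)
    if skipped:
        logger.debug("path probability computed with %d non-informative node(s)", skipped)
    return prob


def circuit_events(circuit: Circuit, graph: PathwayGraph) -> list[PathEvent]:
    """Consistent, net-activating path events of a circuit (may be empty)."""
    events = [path_requirements(p, graph) for p in circuit.paths]
    return [e for e in events if e.consistent and e.net_activating]


def circuit_probability(
    circuit: Circuit,
    node_probs: Mapping[str, Number],
    graph: PathwayGraph,
    max_exact_paths: int = MAX_EXACT_PATHS,
    mc_draws: int = MC_DRAWS,
    rng: np.random.Generator | None = None,
) -> Number:
    """P(signal transmission) for one circuit by inclusion–exclusion.

    Each intersection P(A_i ∩ A_j ∩ ...) is the path probability of the union
    of the requirement sets (0 when contradictory), which is exact under
    independent node activations even when paths share nodes.  Beyond
    ``max_exact_paths`` paths the 2^n-term sum is replaced by a seeded
    Monte-Carlo estimate over Bernoulli node states (flagged in the log).
    """
    events = circuit_events(circuit, graph)
    if not events:
        return 0.0
    if len(events) > max_exact_paths:
        logger.warning(
            "circuit %s: %d paths exceed the exact cap (%d); Monte-Carlo estimate",
            circuit.circuit_id, len(events), max_exact_paths,
        )
        return _mc_union_probability(events, node_probs, mc_draws, rng)
    return union_probability(events, node_probs)


def union_probability(events: list[PathEvent], node_probs: Mapping[str, Number]) -> Number:
    """Exact inclusion–exclusion over path events with shared nodes."""
    dicts = [e.as_dict() for e in events]
    total: Number = 0.0
    for r in range(1, len(dicts) + 1):
        sign = 1.0 if r % 2 == 1 else -1.0
        for combo in combinations(dicts, r):
            merged: dict[str, bool] = {}
            ok = True
            for d in combo:
                for node, state in d.items():
                    if merged.setdefault(node, state) != state:
                        ok = False
                        break
                if not ok:
                    break
            if not ok:
                continue
            total = total + sign * path_probability(merged, node_probs)
    return np.clip(total, 0.0, 1.0) if not np.isscalar(total) else float(min(max(total, 0.0), 1.0))


def _mc_union_probability(
    events: list[PathEvent],
    node_probs: Mapping[str, Number],
    draws: int,
    rng: np.random.Generator | None,
) -> Number:
    """Monte-Carlo estimate of the union over independent Bernoulli node states."""
    rng = rng or np.random.default_rng(0)
    nodes = sorted({n for e in events for n, _ in e.requirements if n in node_probs})
    probs = np.stack([np.atleast_1d(np.asarray(node_probs[n], dtype=float)) for n in nodes])
    n_samples = probs.shape[1]
    out = np.empty(n_samples)
    idx = {n: i for i, n in enumerate(nodes)}
    for s in range(n_samples):
        u = rng.random((draws, len(nodes)))
        states = u < probs[:, s]
        hit = np.zeros(draws, dtype=bool)
        for e in events:
            ok = np.ones(draws, dtype=bool)
            for node, state in e.requirements:
                if node not in idx:
                    continue
                col = states[:, idx[node]]
                ok &= col if state else ~col
            hit |= ok
        out[s] = hit.mean()
    return float(out[0]) if n_samples == 1 and np.isscalar(next(iter(node_probs.values()), 0.0)) else out


def circuit_completeness(circuit: Circuit, node_probs: Mapping[str, Number], graph: PathwayGraph) -> float:
    """Fraction of nodes referenced by the circuit's requirements that are measured."""
    needed: set[str] = set()
    for p in circuit.paths:
        needed.update(n for n, _ in path_requirements(p, graph).requirements)
    if not needed:
        return 1.0
    return sum(1 for n in needed if n in node_probs) / len(needed)


def activity_matrix(
    circuits: list[Circuit],
    node_activation: pd.DataFrame,
    graph: PathwayGraph,
    max_exact_paths: int = MAX_EXACT_PATHS,
    mc_draws: int = MC_DRAWS,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Circuit x sample matrix of signal-transmission probabilities.

    ``node_activation`` is a node x sample matrix; circuits none of whose
    required nodes are measured are dropped with a log message.
    """
    node_probs = {str(n): node_activation.loc[n].to_numpy() for n in node_activation.index}
    rows: dict[str, np.ndarray] = {}
    for circuit in circuits:
        if circuit_completeness(circuit, node_probs, graph) == 0.0:
            logger.warning("circuit %s: all nodes unmeasured; dropped", circuit.circuit_id)
            continue
        p = circuit_probability(
            circuit, node_probs, graph,
            max_exact_paths=max_exact_paths, mc_draws=mc_draws, rng=rng,
        )
        rows[circuit.circuit_id] = np.broadcast_to(
            np.asarray(p, dtype=float), (node_activation.shape[1],)
        )
    if not rows:
        raise ValueError("no circuit with measured nodes")
    return pd.DataFrame(
        np.vstack(list(rows.values())),
        index=pd.Index(list(rows), name="circuit_id"),
        columns=node_activation.columns,
    )
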