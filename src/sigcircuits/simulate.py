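"""Synthetic fixtures and simulation experiments.

Provides (i) deterministic toy pathways exercising every node kind and edge
sign, including the worked bifurcating topology whose ProtA->ProtH circuit
has exactly the two printed linear paths; (ii) a null simulation in which
every probe of every node shares one activation probability plus Gaussian
noise, so any circuit called differential between two halves of a dataset is
a false positive; and (iii) an expression-level study generator with known
ground truth for end-to-end recovery tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

from .activation import GENE_PERCENTILE
from .circuits import Circuit, pathway_circuits
from .difftest import adjust_fdr, wilcoxon_circuit
from .pathway_io import ACTIVATION, INHIBITION, NodeSpec, PathwayGraph
from .propagation import circuit_events, union_probability

logger = logging.getLogger("sigcircuits.simulate")

# Study-generator expression scale: inactive and active component means and
# spreads of the log-intensity mixture each probe is drawn from.
MU_INACTIVE = 4.0
MU_ACTIVE = 9.0
COMPONENT_SD = 1.0
STUDY_ACTIVITY_SD = 0.1
STUDY_PROBE_SD = 0.5
PROBES_PER_GENE = 3


# ---------------------------------------------------------------------------
# toy pathways
# ---------------------------------------------------------------------------

def _single(node_id: str) -> NodeSpec:
    return NodeSpec(node_id=node_id, kind="single", genes=(f"g{node_id}",))


def fig6_pathway() -> PathwayGraph:
    """Bifurcating toy topology with 3 inputs, 3 outputs and 5 circuits.

    The A->H circuit runs through the two linear paths A,B,D,F,H and
    A,B,D,G,H.  Only those two paths and the input/output/circuit counts are
    prescribed; the remaining edges (C->B, F->I, E->L->J) are a synthetic
    completion consistent with them.
    """
    node_ids = list("ABCDEFGHIJ") + ["L"]
    nodes = {nid: _single(nid) for nid in node_ids}
    edges = [
        ("A", "B", ACTIVATION),
        ("C", "B", ACTIVATION),
        ("B", "D", ACTIVATION),
        ("D", "F", ACTIVATION),
        ("D", "G", ACTIVATION),
        ("F", "H", ACTIVATION),
        ("G", "H", ACTIVATION),
        ("F", "I", ACTIVATION),
        ("E", "L", ACTIVATION),
        ("L", "J", ACTIVATION),
    ]
    return PathwayGraph(pathway_id="fig6", nodes=nodes, edges=edges)


def complex_alternatives_pathway() -> PathwayGraph:
    """Chain receptor -> complex -> alternative proteins -> effector."""
    nodes = {
        "R1": NodeSpec("R1", "single", ("gR1",)),
        "CX": NodeSpec("CX", "complex", ("gCXa", "gCXb")),
        "AL": NodeSpec("AL", "alternatives", ("gALa", "gALb")),
        "T1": NodeSpec("T1", "single", ("gT1",)),
    }
    edges = [
        ("R1", "CX", ACTIVATION),
        ("CX", "AL", ACTIVATION),
        ("AL", "T1", ACTIVATION),
    ]
    return PathwayGraph(pathway_id="cxalt", nodes=nodes, edges=edges)


def inhibitor_pathway() -> PathwayGraph:
    """Linear chain X->Y->Z with an external inhibitor I of Y."""
    nodes = {nid: _single(nid) for nid in ("X", "Y", "Z", "N")}
    edges = [
        ("X", "Y", ACTIVATION),
        ("Y", "Z", ACTIVATION),
        ("N", "Y", INHIBITION),
    ]
    return PathwayGraph(pathway_id="inhib", nodes=nodes, edges=edges)


def cycle_pathway() -> PathwayGraph:
    """Chain whose only route runs through a 2-cycle; all circuits are looped."""
    nodes = {nid: _single(nid) for nid in ("Q", "W", "V", "U")}
    edges = [
        ("Q", "W", ACTIVATION),
        ("W", "V", ACTIVATION),
        ("V", "W", ACTIVATION),
        ("V", "U", ACTIVATION),
    ]
    return PathwayGraph(pathway_id="cyc", nodes=nodes, edges=edges)


def make_random_pathway(
    rng: np.random.Generator,
    n_nodes: int = 8,
    edge_prob: float = 0.35,
    inhibition_prob: float = 0.25,
    pathway_id: str = "rand",
) -> PathwayGraph:
    """Random DAG pathway (topological edge orientation) with random inhibitions."""
    names = [f"n{i}" for i in range(n_nodes)]
    nodes = {f"{pathway_id}_{n}": _single(f"{pathway_id}_{n}") for n in names}
    ids = list(nodes)
    edges = []
    for i in range(n_nodes):
        for j in range(i + 1, n_nodes):
            if rng.random() < edge_prob:
                sign = INHIBITION if rng.random() < inhibition_prob else ACTIVATION
                edges.append((ids[i], ids[j], sign))
    return PathwayGraph(pathway_id=pathway_id, nodes=nodes, edges=edges)


def make_toy_pathways(seed: int = 0, n_random: int = 2) -> list[PathwayGraph]:
    """Deterministic fixture set: the four fixed toys plus seeded random DAGs."""
    rng = np.random.default_rng(seed)
    out = [
        fig6_pathway(),
        complex_alternatives_pathway(),
        inhibitor_pathway(),
        cycle_pathway(),
    ]
    for k in range(n_random):
        out.append(
            make_random_pathway(rng, n_nodes=8, pathway_id=f"rnd{k}")
        )
    return out


def dag_toy_pathways() -> list[PathwayGraph]:
    """The acyclic fixed toys (the set used by the null experiment)."""
    return [fig6_pathway(), complex_alternatives_pathway(), inhibitor_pathway()]


def make_probe_map(
    pathways: Iterable[PathwayGraph], probes_per_gene: int = PROBES_PER_GENE
) -> pd.DataFrame:
    """Probe->gene table with ``probes_per_gene`` probes per pathway gene."""
    rows = []
    seen: set[str] = set()
    for g in pathways:
        for gene in sorted(g.genes()):
            if gene in seen:
                continue
            seen.add(gene)
            for k in range(probes_per_gene):
                rows.append({"probe_id": f"{gene}_p{k}", "gene_id": gene})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# shared probe-probability -> circuit-activity pipeline
# ---------------------------------------------------------------------------

@dataclass
class _CompiledPathways:
    """Precompiled aggregation plan from probe probabilities to circuit activity."""

    probe_ids: list[str]
    gene_rows: dict[str, np.ndarray]          # gene -> probe row indices
    node_plans: list[tuple[str, str, list[str]]]  # (node_id, kind, genes)
    circuits: list[Circuit]
    events: dict[str, list]                    # circuit_id -> path events
    node_gene_probe_rows: dict[str, np.ndarray]  # alternatives: pooled probe rows


def compile_pathways(
    pathways: Sequence[PathwayGraph],
    probe_map: pd.DataFrame,
    max_paths_per_circuit: int = 10_000,
) -> _CompiledPathways:
    probe_ids = list(probe_map["probe_id"])
    probe_idx = {p: i for i, p in enumerate(probe_ids)}
    gene_rows: dict[str, np.ndarray] = {}
    for gene, grp in probe_map.groupby("gene_id"):
        gene_rows[str(gene)] = np.array([probe_idx[p] for p in grp["probe_id"]])
    node_plans = []
    circuits: list[Circuit] = []
    events: dict[str, list] = {}
    pooled: dict[str, np.ndarray] = {}
    for graph in pathways:
        kept, _ = pathway_circuits(graph, max_paths_per_circuit)
        circuits.extend(kept)
        for c in kept:
            events[c.circuit_id] = circuit_events(c, graph)
        for node_id, spec in graph.nodes.items():
            genes = [g for g in spec.genes if g in gene_rows]
            if not genes:
                continue
            node_plans.append((node_id, spec.kind, genes))
            if spec.kind == "alternatives":
                pooled[node_id] = np.concatenate([gene_rows[g] for g in genes])
    return _CompiledPathways(
        probe_ids=probe_ids,
        gene_rows=gene_rows,
        node_plans=node_plans,
        circuits=circuits,
        events=events,
        node_gene_probe_rows=pooled,
    )


def circuit_activity_from_probe_probs(
    probe_probs: np.ndarray, plan: _CompiledPathways, q: float = GENE_PERCENTILE
) -> dict[str, np.ndarray]:
    """Circuit activity per sample from a probe x sample probability array."""
    gene_vals = {
        g: np.percentile(probe_probs[rows], q, axis=0) for g, rows in plan.gene_rows.items()
    }
    node_vals: dict[str, np.ndarray] = {}
    for node_id, kind, genes in plan.node_plans:
        if kind == "single":
            node_vals[node_id] = gene_vals[genes[0]]
        elif kind == "complex":
            node_vals[node_id] = np.min([gene_vals[g] for g in genes], axis=0)
        else:
            node_vals[node_id] = np.percentile(
                probe_probs[plan.node_gene_probe_rows[node_id]], q, axis=0
            )
    return {
        c.circuit_id: np.atleast_1d(
            np.asarray(union_probability(plan.events[c.circuit_id], node_vals))
        )
        if plan.events[c.circuit_id]
        else np.zeros(probe_probs.shape[1])
        for c in plan.circuits
    }


# ---------------------------------------------------------------------------
# null simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NullSimConfig:
    """Null-simulation design: identical probe activation probabilities + noise."""

    n_datasets: int = 100
    sample_sizes: tuple[int, ...] = (10, 20, 50, 100)
    base_probabilities: tuple[float, ...] = (0.1, 0.3, 0.5, 0.7, 0.9)
    noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_datasets < 1:
            raise ValueError("n_datasets must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass(frozen=True)
class NullDataset:
    sample_size: int
    base_probability: float
    replicate: int
    values: pd.DataFrame  # probes x samples, activation probabilities


def _iter_null_arrays(
    config: NullSimConfig, n_probes: int
) -> Iterator[tuple[int, float, int, np.ndarray]]:
    rng = np.random.default_rng(config.seed)
    for size in config.sample_sizes:
        for base in config.base_probabilities:
            noise = rng.normal(0.0, config.noise_sd, size=(config.n_datasets, n_probes, size))
            block = np.clip(base + noise, 0.0, 1.0)
            for d in range(config.n_datasets):
                yield size, base, d, block[d]


def simulate_null_probes(
    config: NullSimConfig, probe_ids: Sequence[str]
) -> list[NullDataset]:
    """Materialize the null datasets: every probe at one base probability + noise."""
    out = []
    for size, base, d, arr in _iter_null_arrays(config, len(probe_ids)):
        cols = [f"s{i}" for i in range(size)]
        out.append(
            NullDataset(
                sample_size=size,
                base_probability=base,
                replicate=d,
                values=pd.DataFrame(arr, index=list(probe_ids), columns=cols),
            )
        )
    return out


def run_null_experiment(
    config: NullSimConfig,
    pathways: Sequence[PathwayGraph] | None = None,
    probe_map: pd.DataFrame | None = None,
    alpha: float = 0.05,
    shift: float = 0.0,
    adjust: str = "none",
) -> pd.DataFrame:
    """False-positive-rate table of the two-halves null comparison.

    Each dataset is split into two equal halves (odd sizes drop the last
    sample) and every circuit of the fixture pathways is rank-sum tested;
    the reported cell value is the mean fraction of circuits called per
    (sample size, base probability).  With ``adjust="none"`` a circuit
    counts when its raw p-value is below ``alpha`` (the nominal level of
    the rank test); with ``adjust="fdr"`` when its within-pathway
    BH-adjusted p-value is, i.e. when the full methodology would declare it
    significant.  A nonzero ``shift`` is added to the second half's probe
    probabilities, turning the table into a detection-rate (power) table.
    """
    if adjust not in ("none", "fdr"):
        raise ValueError("adjust must be 'none' or 'fdr'")
    pathways = list(pathways) if pathways is not None else dag_toy_pathways()
    if probe_map is None:
        probe_map = make_probe_map(pathways)
    plan = compile_pathways(pathways, probe_map)
    if not plan.circuits:
        raise ValueError("fixture pathways yield no circuits")
    cells: dict[tuple[int, float], list[float]] = {}
    for size, base, _d, arr in _iter_null_arrays(config, len(plan.probe_ids)):
        half = size // 2
        if size % 2:
            logger.info("odd sample size %d: dropping one sample", size)
        if shift:
            arr = arr.copy()
            arr[:, half : 2 * half] = np.clip(arr[:, half : 2 * half] + shift, 0.0, 1.0)
        activity = circuit_activity_from_probe_probs(arr[:, : 2 * half], plan)
        pvals = np.array(
            [
                wilcoxon_circuit(vals[:half], vals[half : 2 * half])[0]
                for vals in activity.values()
            ]
        )
        if adjust == "fdr":
            pathway_of = [c.pathway_id for c in plan.circuits]
            pvals = adjust_fdr(pvals, groups=pathway_of)
        cells.setdefault((size, base), []).append(float(np.mean(pvals < alpha)))
    table = pd.DataFrame(
        index=pd.Index(sorted({s for s, _ in cells}), name="sample_size"),
        columns=pd.Index(sorted({b for _, b in cells}), name="base_probability"),
        dtype=float,
    )
    for (size, base), rates in cells.items():
        table.loc[size, base] = float(np.mean(rates))
    return table


# ---------------------------------------------------------------------------
# expression-level study generator
# ---------------------------------------------------------------------------

@dataclass
class StudyData:
    """Synthetic two-condition study with known differential circuits."""

    expression: pd.DataFrame         # probes x study samples (log-intensity scale)
    compendium: pd.DataFrame         # probes x reference samples
    probe_map: pd.DataFrame
    design: dict[str, str]           # sample -> condition (c1/c2)
    truth: set[str]                  # circuit ids genuinely shifted
    pathways: list[PathwayGraph]
    circuits: list[Circuit] = field(default_factory=list)
    shifted_genes: set[str] = field(default_factory=set)


def simulate_study(
    pathways: Sequence[PathwayGraph] | None = None,
    n_per_group: int = 20,
    differential_circuits: set[str] | None = None,
    effect: float = 0.4,
    seed: int = 0,
    n_reference: int = 200,
    probes_per_gene: int = PROBES_PER_GENE,
    base_activity: float = 0.5,
) -> StudyData:
    """Generate compendium + study expression with circuit-level ground truth.

    Reference samples draw each probe from the assumed two-state mixture
    (Normal(4,1) inactive / Normal(9,1) active, equal proportions).  Study
    samples carry a continuous latent activity per gene — Normal around the
    group mean, clipped to [0,1] — mapped linearly onto the expression scale;
    genes on the designated circuits get activity ``base + effect`` in
    condition 2.  Truth is the set of circuits containing any shifted gene.
    """
    pathways = list(pathways) if pathways is not None else [fig6_pathway()]
    rng = np.random.default_rng(seed)
    all_circuits: list[Circuit] = []
    for g in pathways:
        kept, _ = pathway_circuits(g)
        all_circuits.extend(kept)
    by_id = {c.circuit_id: c for c in all_circuits}
    if differential_circuits is None:
        differential_circuits = {"E->J"} if "E->J" in by_id else set()
    unknown = differential_circuits - set(by_id)
    if unknown:
        raise ValueError(f"differential circuits not enumerable: {sorted(unknown)}")

    node_specs = {nid: spec for g in pathways for nid, spec in g.nodes.items()}
    shifted_genes: set[str] = set()
    for cid in differential_circuits:
        for nid in by_id[cid].node_ids:
            shifted_genes.update(node_specs[nid].genes)
    truth = {c.circuit_id for c in all_circuits if set().union(
        *(node_specs[nid].genes for nid in c.node_ids)
    ) & shifted_genes}

    probe_map = make_probe_map(pathways, probes_per_gene)
    probes = list(probe_map["probe_id"])
    gene_of = dict(zip(probe_map["probe_id"], probe_map["gene_id"]))

    # reference compendium: hard two-state mixture per probe
    states = rng.random((len(probes), n_reference)) < 0.5
    comp = np.where(
        states,
        rng.normal(MU_ACTIVE, COMPONENT_SD, states.shape),
        rng.normal(MU_INACTIVE, COMPONENT_SD, states.shape),
    )
    compendium = pd.DataFrame(
        comp, index=pd.Index(probes, name="probe_id"),
        columns=[f"ref{i}" for i in range(n_reference)],
    )

    # study samples: graded latent activity per gene
    samples = [f"c1_{i}" for i in range(n_per_group)] + [
        f"c2_{i}" for i in range(n_per_group)
    ]
    design = {s: ("c1" if s.startswith("c1") else "c2") for s in samples}
    genes = sorted({gene_of[p] for p in probes})
    target = np.full((len(genes), 2 * n_per_group), base_activity)
    if base_activity + effect > 1.0 or base_activity + effect < 0.0:
        logger.warning("effect pushes activity outside [0,1]; clipping")
    for gi, gene in enumerate(genes):
        if gene in shifted_genes:
            target[gi, n_per_group:] = np.clip(base_activity + effect, 0.0, 1.0)
    activity = np.clip(
        rng.normal(target, STUDY_ACTIVITY_SD), 0.0, 1.0
    )
    gene_idx = {g: i for i, g in enumerate(genes)}
    expr = np.empty((len(probes), 2 * n_per_group))
    for pi, probe in enumerate(probes):
        a = activity[gene_idx[gene_of[probe]]]
        expr[pi] = MU_INACTIVE + a * (MU_ACTIVE - MU_INACTIVE) + rng.normal(
            0.0, STUDY_PROBE_SD, 2 * n_per_group
        )
    expression = pd.DataFrame(
        expr, index=pd.Index(probes, name="probe_id"), columns=samples
    )
    return StudyData(
        expression=expression,
        compendium=compendium,
        probe_map=probe_map,
        design=design,
        truth=truth,
        pathways=pathways,
        circuits=all_circuits,
        shifted_genes=shifted_genes,
    )
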