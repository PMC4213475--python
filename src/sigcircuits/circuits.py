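"""Signal transmission circuits: input/output nodes, path enumeration, loop removal.

A signal input node receives a stimulus (no incoming interactions, in-degree
0) and a signal output node is a terminal effector (out-degree 0).  A circuit
is one (input, output) pair together with every loop-free linear path
connecting them; it represents one elementary stimulus->response function of
the pathway.  Circuits touching directed cycles are discarded: feedback
cannot be represented in this static probabilistic model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import islice

import networkx as nx
import pandas as pd

from .pathway_io import PathwayGraph

logger = logging.getLogger("sigcircuits.circuits")

DEFAULT_MAX_PATHS = 10_000


@dataclass(frozen=True)
class LinearPath:
    """A simple directed path, with the sign of each traversed edge."""

    nodes: tuple[str, ...]
    signs: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.signs) != len(self.nodes) - 1:
            raise ValueError("signs must align with consecutive node pairs")
        if len(set(self.nodes)) != len(self.nodes):
            raise ValueError("path repeats a node (not simple)")


@dataclass
class Circuit:
    """All linear paths from one signal input node to one effector node."""

    circuit_id: str
    pathway_id: str
    input_node: str
    output_node: str
    paths: list[LinearPath] = field(default_factory=list)
    truncated: bool = False
    effector_annotation: str | None = None

    def __post_init__(self) -> None:
        if not self.paths:
            raise ValueError(f"circuit {self.circuit_id} has no paths")
        for p in self.paths:
            if p.nodes[0] != self.input_node or p.nodes[-1] != self.output_node:
                raise ValueError(
                    f"path {p.nodes} does not run {self.input_node}->{self.output_node}"
                )
        if len({p.nodes for p in self.paths}) != len(self.paths):
            raise ValueError(f"circuit {self.circuit_id} has duplicate paths")

    @property
    def node_ids(self) -> set[str]:
        out: set[str] = set()
        for p in self.paths:
            out.update(p.nodes)
        return out


def find_io_nodes(graph: PathwayGraph) -> tuple[set[str], set[str]]:
    """Signal input nodes (in-degree 0) and output nodes (out-degree 0).

    Isolated nodes (no interactions at all) belong to neither set.
    """
    g = graph.to_networkx()
    inputs = {
        n for n in g if g.in_degree(n) == 0 and g.out_degree(n) > 0
    }
    outputs = {
        n for n in g if g.out_degree(n) == 0 and g.in_degree(n) > 0
    }
    if g.number_of_nodes() and (not inputs or not outputs):
        logger.warning(
            "pathway %s has %d input and %d output nodes; no circuits can be formed",
            graph.pathway_id, len(inputs), len(outputs),
        )
    return inputs, outputs


def enumerate_circuits(
    graph: PathwayGraph, max_paths_per_circuit: int = DEFAULT_MAX_PATHS
) -> list[Circuit]:
    """One circuit per connected (input, output) pair, carrying all simple paths.

    Pairs with no path are omitted.  A circuit whose simple-path count
    exceeds ``max_paths_per_circuit`` keeps the first ``max_paths_per_circuit``
    paths and is flagged ``truncated``.
    """
    g = graph.to_networkx()
    inputs, outputs = find_io_nodes(graph)
    circuits: list[Circuit] = []
    for source in sorted(inputs):
        for target in sorted(outputs):
            gen = nx.all_simple_paths(g, source, target)
            paths = list(islice(gen, max_paths_per_circuit))
            if not paths:
                continue
            truncated = next(gen, None) is not None
            if truncated:
                logger.warning(
                    "circuit %s->%s exceeds %d paths; truncated",
                    source, target, max_paths_per_circuit,
                )
            linear = [
                LinearPath(
                    nodes=tuple(p),
                    signs=tuple(g.edges[u, v]["sign"] for u, v in zip(p, p[1:])),
                )
                for p in paths
            ]
            circuits.append(
                Circuit(
                    circuit_id=f"{source}->{target}",
                    pathway_id=graph.pathway_id,
                    input_node=source,
                    output_node=target,
                    paths=linear,
                    truncated=truncated,
                )
            )
    return circuits


def cycle_nodes(graph: PathwayGraph) -> set[str]:
    """Nodes lying on any directed cycle (non-trivial strongly connected component)."""
    g = graph.to_networkx()
    out: set[str] = set()
    for scc in nx.strongly_connected_components(g):
        if len(scc) > 1:
            out.update(scc)
    return out


def remove_looped_circuits(
    circuits: list[Circuit], graph: PathwayGraph
) -> tuple[list[Circuit], int]:
    """Drop circuits whose paths touch any node on a directed cycle."""
    looped = cycle_nodes(graph)
    kept = [c for c in circuits if not (c.node_ids & looped)]
    removed = len(circuits) - len(kept)
    if removed:
        logger.info(
            "pathway %s: removed %d circuit(s) touching loops", graph.pathway_id, removed
        )
    return kept, removed


def circuits_table(circuits: list[Circuit]) -> pd.DataFrame:
    """Tabular summary (circuit_id, input, output, n_paths, truncated)."""
    return pd.DataFrame(
        {
            "circuit_id": [c.circuit_id for c in circuits],
            "pathway_id": [c.pathway_id for c in circuits],
            "input": [c.input_node for c in circuits],
            "output": [c.output_node for c in circuits],
            "n_paths": [len(c.paths) for c in circuits],
            "truncated": [c.truncated for c in circuits],
        }
    )


def pathway_circuits(
    graph: PathwayGraph, max_paths_per_circuit: int = DEFAULT_MAX_PATHS
) -> tuple[list[Circuit], int]:
    """Enumerate circuits and drop loop-touching ones in one step."""
    return remove_looped_circuits(enumerate_circuits(graph, max_paths_per_circuit), graph)
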