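"""Signed directed pathway graphs: KGML parsing, a JSON dialect, GraphML export.

A pathway is modeled as a directed graph whose nodes are proteins (a single
protein, a set of alternative proteins, or a protein complex) and whose edges
are either activations or inhibitions.  KGML relation subtypes are collapsed
onto this two-sign alphabet; proteins linked by binding/association relations
or declared as a ``group`` entry are merged into one complex node that must be
simultaneously active to transmit signal.

The JSON dialect is a lightweight, download-free equivalent of KGML used for
fixtures and interchange::

    {
      "pathway_id": "toy",
      "nodes": [{"id": "A", "kind": "single", "genes": ["gA"]}, ...],
      "edges": [{"source": "A", "target": "B", "sign": "activation"}, ...]
    }

``kind`` is one of ``single`` (exactly one gene), ``alternatives`` (>=2
redundant genes, any one suffices) or ``complex`` (>=2 genes all required).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
from lxml import etree

logger = logging.getLogger("sigcircuits.pathway_io")

ACTIVATION = "activation"
INHIBITION = "inhibition"

#: KGML subtype labels read as inhibitions when present.
INHIBITION_LABELS = frozenset({"inhibition", "repression", "ubiquitination"})
#: KGML subtype labels read as activations (unless an inhibition label co-occurs).
ACTIVATION_LABELS = frozenset(
    {
        "activation",
        "phosphorylation",
        "dephosphorylation",
        "indirect",
        "indirect effect",
        "expression",
        "compound",
        "state change",
    }
)
#: Subtypes that merge their endpoints into a single complex node.
MERGE_LABELS = frozenset({"binding/association", "binding", "association"})

NODE_KINDS = ("single", "alternatives", "complex")


class PathwayError(ValueError):
    """Base class for pathway construction problems."""


class KGMLParseError(PathwayError):
    """Malformed KGML document."""


class StructuralError(PathwayError):
    """Well-formed document describing an inconsistent graph."""


class SchemaError(PathwayError):
    """JSON pathway document violating the dialect schema."""


@dataclass(frozen=True)
class NodeSpec:
    """One pathway node: a protein, alternative proteins, or a complex."""

    node_id: str
    kind: str
    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.kind not in NODE_KINDS:
            raise StructuralError(f"unknown node kind {self.kind!r} for {self.node_id!r}")
        if not self.genes:
            raise StructuralError(f"node {self.node_id!r} has no genes")
        if self.kind == "single" and len(self.genes) != 1:
            raise StructuralError(
                f"node {self.node_id!r} is 'single' but lists {len(self.genes)} genes"
            )
        if self.kind in ("alternatives", "complex") and len(self.genes) < 2:
            raise StructuralError(
                f"node {self.node_id!r} is {self.kind!r} but lists fewer than 2 genes"
            )


@dataclass
class PathwayGraph:
    """Signed directed graph of one signaling pathway."""

    pathway_id: str
    nodes: dict[str, NodeSpec] = field(default_factory=dict)
    edges: list[tuple[str, str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    # -- construction -----------------------------------------------------
    def validate(self) -> None:
        for source, target, sign in self.edges:
            if source not in self.nodes or target not in self.nodes:
                raise StructuralError(
                    f"edge {source!r}->{target!r} references a missing node"
                )
            if source == target:
                raise StructuralError(f"self-edge on node {source!r}")
            if sign not in (ACTIVATION, INHIBITION):
                raise StructuralError(f"unknown edge sign {sign!r}")

    # -- queries ----------------------------------------------------------
    @property
    def node_ids(self) -> list[str]:
        return list(self.nodes)

    def node(self, node_id: str) -> NodeSpec:
        return self.nodes[node_id]

    def edge_sign(self, source: str, target: str) -> str | None:
        for s, t, sign in self.edges:
            if s == source and t == target:
                return sign
        return None

    def inhibitors_of(self, target: str) -> list[str]:
        """Sources of inhibition edges pointing at ``target``."""
        return [s for s, t, sign in self.edges if t == target and sign == INHIBITION]

    def genes(self) -> set[str]:
        out: set[str] = set()
        for spec in self.nodes.values():
            out.update(spec.genes)
        return out

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph(pathway_id=self.pathway_id)
        for spec in self.nodes.values():
            g.add_node(spec.node_id, kind=spec.kind, genes=";".join(spec.genes))
        for source, target, sign in self.edges:
            g.add_edge(source, target, sign=sign)
        return g


def classify_relation(subtypes: Sequence[str]) -> str:
    """Map a list of KGML relation subtype labels to an edge sign.

    Inhibition-class labels (inhibition, repression, ubiquitination) win over
    any co-occurring activation-class label: a relation tagged both
    phosphorylation and inhibition is a phosphorylation that inhibits its
    target.  Unknown labels default to activation with a warning.
    """
    if not subtypes:
        raise ValueError("empty subtype list")
    labels = [s.strip().lower() for s in subtypes]
    for label in labels:
        if label not in INHIBITION_LABELS and label not in ACTIVATION_LABELS and label not in MERGE_LABELS:
            logger.warning("unknown relation subtype %r; treating as activation", label)
    if any(label in INHIBITION_LABELS for label in labels):
        return INHIBITION
    return ACTIVATION


def _dedupe_edges(edges: Iterable[tuple[str, str, str]]) -> list[tuple[str, str, str]]:
    """Collapse parallel edges; a conflicting pair resolves to inhibition."""
    seen: dict[tuple[str, str], str] = {}
    order: list[tuple[str, str]] = []
    for source, target, sign in edges:
        key = (source, target)
        if key not in seen:
            seen[key] = sign
            order.append(key)
        elif seen[key] != sign:
            seen[key] = INHIBITION
    return [(s, t, seen[(s, t)]) for s, t in order]


# ---------------------------------------------------------------------------
# KGML
# ---------------------------------------------------------------------------

_SKIPPED_ENTRY_TYPES = frozenset({"map", "maplink", "compound", "enzyme", "other", "reaction", "brite"})


class _UnionFind:
    def __init__(self) -> None:
        self.parent: dict[str, str] = {}

    def add(self, x: str) -> None:
        self.parent.setdefault(x, x)

    def find(self, x: str) -> str:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: str, b: str) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def parse_kgml(kgml_document: str | bytes, pathway_id: str | None = None) -> PathwayGraph:
    """Build a :class:`PathwayGraph` from a KGML (KEGG Markup Language) document.

    Entries of type ``gene`` become nodes (``single`` for one gene,
    ``alternatives`` for several).  ``group`` entries and endpoints of
    binding/association relations are merged into ``complex`` nodes.
    ``map`` entries (links to other pathways) are dropped with a warning, as
    are relations touching them; each pathway is modeled independently.
    """
    if isinstance(kgml_document, str):
        kgml_document = kgml_document.encode()
    try:
        root = etree.fromstring(kgml_document)
    except etree.XMLSyntaxError as exc:
        raise KGMLParseError(f"malformed KGML: {exc}") from exc
    if root.tag != "pathway":
        raise KGMLParseError(f"expected root element 'pathway', found {root.tag!r}")
    if pathway_id is None:
        raw = root.get("name") or root.get("title") or "pathway"
        pathway_id = raw.split(":")[-1]

    entry_genes: dict[str, tuple[str, ...]] = {}
    skipped: set[str] = set()
    groups: dict[str, list[str]] = {}
    for entry in root.iterfind("entry"):
        eid = entry.get("id")
        etype = entry.get("type", "gene")
        if eid is None:
            raise KGMLParseError("entry element without an 'id' attribute")
        if etype == "group":
            comps = [c.get("id") for c in entry.iterfind("component")]
            if not comps or any(c is None for c in comps):
                raise KGMLParseError(f"group entry {eid!r} without valid components")
            groups[eid] = [c for c in comps if c is not None]
        elif etype in ("gene", "ortholog"):
            names = (entry.get("name") or "").split()
            genes = tuple(n.split(":")[-1] for n in names if n and n != "undefined")
            if not genes:
                logger.warning("entry %s has no gene names; skipping", eid)
                skipped.add(eid)
                continue
            entry_genes[eid] = genes
        elif etype in _SKIPPED_ENTRY_TYPES:
            if etype in ("map", "maplink"):
                logger.warning("dropping cross-pathway entry %s (type=%s)", eid, etype)
            skipped.add(eid)
        else:
            logger.warning("dropping entry %s of unhandled type %r", eid, etype)
            skipped.add(eid)

    known = set(entry_genes) | set(groups) | skipped
    uf = _UnionFind()
    for eid in entry_genes:
        uf.add(eid)

    # group entries merge their components
    for gid, comps in groups.items():
        members = [c for c in comps if c in entry_genes]
        if not members:
            logger.warning("group %s has no gene components; dropped", gid)
            skipped.add(gid)
            continue
        for c in members[1:]:
            uf.union(members[0], c)
        groups[gid] = members

    raw_edges: list[tuple[str, str, str]] = []
    for relation in root.iterfind("relation"):
        e1, e2 = relation.get("entry1"), relation.get("entry2")
        if e1 is None or e2 is None:
            raise KGMLParseError("relation element missing entry1/entry2")
        for endpoint in (e1, e2):
            if endpoint not in known:
                raise StructuralError(
                    f"relation references unknown entry {endpoint!r}"
                )
        if e1 in skipped or e2 in skipped:
            logger.warning("dropping relation %s->%s touching a skipped entry", e1, e2)
            continue
        labels = [st.get("name", "") for st in relation.iterfind("subtype")]
        labels = [l for l in labels if l]
        if not labels:
            labels = ["activation"]
        if any(l.strip().lower() in MERGE_LABELS for l in labels):
            for a, b in ((e1, e2),):
                ra = groups[a][0] if a in groups else a
                rb = groups[b][0] if b in groups else b
                uf.union(ra, rb)
            continue
        sign = classify_relation(labels)
        raw_edges.append((e1, e2, sign))

    # resolve entries (and groups) to their merged representative
    def resolve(eid: str) -> str:
        if eid in groups:
            eid = groups[eid][0]
        return uf.find(eid)

    clusters: dict[str, list[str]] = {}
    for eid in entry_genes:
        clusters.setdefault(uf.find(eid), []).append(eid)

    nodes: dict[str, NodeSpec] = {}
    rep_to_node: dict[str, str] = {}
    for rep, members in clusters.items():
        members = sorted(members, key=lambda x: (len(x), x))
        if len(members) == 1:
            genes = entry_genes[members[0]]
            kind = "single" if len(genes) == 1 else "alternatives"
            node_id = f"{pathway_id}:{members[0]}"
        else:
            seen: list[str] = []
            for m in members:
                for g in entry_genes[m]:
                    if g not in seen:
                        seen.append(g)
            genes = tuple(seen)
            if len(genes) < 2:
                # complex collapsing to one distinct gene: keep it single
                kind = "single"
            else:
                kind = "complex"
            node_id = f"{pathway_id}:cx_" + "_".join(members)
        nodes[node_id] = NodeSpec(node_id=node_id, kind=kind, genes=genes)
        rep_to_node[rep] = node_id

    edges: list[tuple[str, str, str]] = []
    for e1, e2, sign in raw_edges:
        source = rep_to_node[resolve(e1)]
        target = rep_to_node[resolve(e2)]
        if source == target:
            logger.debug("dropping self-edge on %s after merging", source)
            continue
        edges.append((source, target, sign))

    return PathwayGraph(pathway_id=pathway_id, nodes=nodes, edges=_dedupe_edges(edges))


# ---------------------------------------------------------------------------
# JSON dialect
# ---------------------------------------------------------------------------

def parse_pathway_json(json_document: str | bytes | Mapping) -> PathwayGraph:
    """Read a pathway from the JSON dialect (see module docstring)."""
    if isinstance(json_document, (str, bytes)):
        try:
            doc = json.loads(json_document)
        except json.JSONDecodeError as exc:
            raise SchemaError(f"invalid JSON: {exc}") from exc
    else:
        doc = dict(json_document)
    if not isinstance(doc, dict):
        raise SchemaError("$: document must be an object")
    pid = doc.get("pathway_id")
    if not isinstance(pid, str) or not pid:
        raise SchemaError("$.pathway_id: must be a non-empty string")
    raw_nodes = doc.get("nodes")
    if not isinstance(raw_nodes, list) or not raw_nodes:
        raise SchemaError("$.nodes: must be a non-empty list")
    nodes: dict[str, NodeSpec] = {}
    for i, nd in enumerate(raw_nodes):
        if not isinstance(nd, dict):
            raise SchemaError(f"$.nodes[{i}]: must be an object")
        nid = nd.get("id")
        if not isinstance(nid, str) or not nid:
            raise SchemaError(f"$.nodes[{i}].id: must be a non-empty string")
        if nid in nodes:
            raise SchemaError(f"$.nodes[{i}].id: duplicate node id {nid!r}")
        kind = nd.get("kind", "single")
        if kind not in NODE_KINDS:
            raise SchemaError(f"$.nodes[{i}].kind: must be one of {NODE_KINDS}")
        genes = nd.get("genes")
        if not isinstance(genes, list) or not genes or not all(
            isinstance(g, str) and g for g in genes
        ):
            raise SchemaError(f"$.nodes[{i}].genes: must be a non-empty list of strings")
        try:
            nodes[nid] = NodeSpec(node_id=nid, kind=kind, genes=tuple(genes))
        except PathwayError as exc:
            raise SchemaError(f"$.nodes[{i}]: {exc}") from exc
    raw_edges = doc.get("edges", [])
    if not isinstance(raw_edges, list):
        raise SchemaError("$.edges: must be a list")
    edges: list[tuple[str, str, str]] = []
    for i, ed in enumerate(raw_edges):
        if not isinstance(ed, dict):
            raise SchemaError(f"$.edges[{i}]: must be an object")
        source, target = ed.get("source"), ed.get("target")
        sign = ed.get("sign", ACTIVATION)
        if source not in nodes:
            raise SchemaError(f"$.edges[{i}].source: unknown node {source!r}")
        if target not in nodes:
            raise SchemaError(f"$.edges[{i}].target: unknown node {target!r}")
        if sign not in (ACTIVATION, INHIBITION):
            raise SchemaError(f"$.edges[{i}].sign: must be activation or inhibition")
        edges.append((source, target, sign))
    try:
        return PathwayGraph(pathway_id=pid, nodes=nodes, edges=_dedupe_edges(edges))
    except PathwayError as exc:
        raise SchemaError(str(exc)) from exc


def write_pathway_json(graph: PathwayGraph, indent: int | None = 1) -> str:
    """Serialize a pathway to the JSON dialect (inverse of parse_pathway_json)."""
    doc = {
        "pathway_id": graph.pathway_id,
        "nodes": [
            {"id": spec.node_id, "kind": spec.kind, "genes": list(spec.genes)}
            for spec in graph.nodes.values()
        ],
        "edges": [
            {"source": s, "target": t, "sign": sign} for s, t, sign in graph.edges
        ],
    }
    return json.dumps(doc, indent=indent)


def write_graphml(graph: PathwayGraph) -> str:
    """Serialize a pathway as GraphML with node kind/genes and edge sign attributes."""
    return "\n".join(nx.generate_graphml(graph.to_networkx()))


def load_pathway(path: str) -> PathwayGraph:
    """Read a pathway file, dispatching on extension (.xml/.kgml vs .json)."""
    with open(path, "rb") as fh:
        data = fh.read()
    if path.endswith((".xml", ".kgml")):
        return parse_kgml(data)
    if path.endswith(".json"):
        return parse_pathway_json(data)
    # sniff
    stripped = data.lstrip()
    if stripped.startswith(b"<"):
        return parse_kgml(data)
    return parse_pathway_json(data)
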