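"""Typed evidence-carrying knowledge graph compiled from BEL documents.

Each curated statement becomes one edge, so two statements asserting the same
triple under different citations remain distinct edges (evidence-level
multigraph semantics).  Complex nodes additionally induce ``hasComponent``
edges to their component nodes; these are tagged ``induced=True`` and are by
default excluded from per-node evidence counts but included in headline edge
totals (the ``include_induced`` flag on :func:`stats` exposes both
conventions).
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

from .bel_core import (
    AnnotationSet,
    BelDocument,
    BelStatement,
    BelTerm,
    parse_term,
    serialize_term,
)

__all__ = [
    "KnowledgeGraph",
    "GraphStats",
    "compile_documents",
    "merge",
    "stats",
    "evidence_count",
    "to_node_link",
    "from_node_link",
    "write_json",
    "read_json",
    "write_graphml",
    "node_table",
    "edge_table",
]

HAS_COMPONENT = "hasComponent"

EdgeKey = tuple[str, str, str, str, str]


@dataclass
class KnowledgeGraph:
    """A typed multigraph over canonically keyed BEL terms."""

    graph: nx.MultiDiGraph = field(default_factory=nx.MultiDiGraph)
    provenance: list[str] = field(default_factory=list)

    # -- construction -------------------------------------------------------

    def add_term(self, term: BelTerm) -> str:
        """Insert a term (and, recursively, complex components) as nodes."""
        key = term.key
        # strip the activity modifier: act(p(X)) and p(X) are one node
        bare = term
        if term.activity:
            from dataclasses import replace

            bare = replace(term, activity=False)
            key = bare.key
        existing = self.graph.nodes.get(key)
        if existing is not None:
            if existing["node_type"] != bare.function:
                raise ValueError(
                    f"node key collision with differing type: {key} "
                    f"({existing['node_type']} vs {bare.function})"
                )
            return key
        self.graph.add_node(key, term=bare, node_type=bare.function)
        for component in bare.components:
            child_key = self.add_term(component)
            self._add_edge(
                key,
                HAS_COMPONENT,
                child_key,
                citation="NA",
                evidence="",
                annotations=None,
                induced=True,
            )
        return key

    def _add_edge(
        self,
        u: str,
        relation: str,
        v: str,
        citation: str,
        evidence: str,
        annotations: AnnotationSet | None,
        induced: bool,
    ) -> bool:
        dedup: EdgeKey = (u, relation, v, citation, evidence)
        if dedup in self._edge_index():
            return False
        self.graph.add_edge(
            u,
            v,
            relation=relation,
            citation=citation,
            evidence=evidence,
            annotations=annotations,
            induced=induced,
        )
        self._edge_index().add(dedup)
        return True

    def _edge_index(self) -> set[EdgeKey]:
        idx = self.graph.graph.get("_edge_index")
        if idx is None:
            idx = {
                (u, d["relation"], v, d["citation"], d["evidence"])
                for u, v, d in self.graph.edges(data=True)
            }
            self.graph.graph["_edge_index"] = idx
        return idx

    def add_statement(self, statement: BelStatement) -> bool:
        u = self.add_term(statement.subject)
        v = self.add_term(statement.object)
        return self._add_edge(
            u,
            statement.relation,
            v,
            citation=statement.citation,
            evidence=statement.evidence,
            annotations=statement.annotations,
            induced=False,
        )

    # -- queries -------------------------------------------------------------

    @property
    def node_keys(self) -> set[str]:
        return set(self.graph.nodes)

    def term(self, key: str) -> BelTerm:
        return self.graph.nodes[key]["term"]

    def edge_records(self, include_induced: bool = True):
        for u, v, d in self.graph.edges(data=True):
            if not include_induced and d["induced"]:
                continue
            yield u, v, d

    def edge_multiset(self) -> Counter:
        """Edge identity multiset used for graph equality."""
        return Counter(
            (u, d["relation"], v, d["citation"], d["evidence"], d["induced"])
            for u, v, d in self.graph.edges(data=True)
        )

    def equals(self, other: "KnowledgeGraph") -> bool:
        """Node-key-set plus edge-multiset equality; provenance is ignored."""
        return (
            self.node_keys == other.node_keys
            and self.edge_multiset() == other.edge_multiset()
        )


@dataclass
class GraphStats:
    n_nodes: int
    n_edges: int
    n_by_type: dict[str, int]
    n_citations: int

    def __post_init__(self) -> None:
        if sum(self.n_by_type.values()) != self.n_nodes:
            raise ValueError("n_by_type must sum to n_nodes")

    @property
    def n_proteins(self) -> int:
        return self.n_by_type.get("protein", 0)


def compile_documents(
    docs: list[BelDocument], provenance: list[str] | None = None
) -> KnowledgeGraph:
    """Compile parsed, normalized BEL documents into one knowledge graph.

    Statements are sorted by their full identity before insertion, so the
    result is invariant under statement and document order.
    """
    from .bel_core import _statement_sort_key

    statements = [s for doc in docs for s in doc.statements]
    statements.sort(key=_statement_sort_key)
    kg = KnowledgeGraph()
    kg.provenance = list(provenance or [])
    if not kg.provenance:
        kg.provenance = [doc.header.name for doc in docs if doc.header.name]
    for statement in statements:
        kg.add_statement(statement)
    return kg


def merge(graphs: list[KnowledgeGraph]) -> KnowledgeGraph:
    """Union of graphs by canonical node key with evidence-level edge dedup.

    Edges are deduplicated on (subject, relation, object, citation,
    evidence); a node-key collision with differing node types raises.
    """
    out = KnowledgeGraph()
    for g in graphs:
        out.provenance.extend(g.provenance)
        for key in sorted(g.graph.nodes):
            out.add_term(g.term(key))
        edges = sorted(
            g.graph.edges(data=True),
            key=lambda e: (
                e[0],
                e[2]["relation"],
                e[1],
                e[2]["citation"],
                e[2]["evidence"],
            ),
        )
        for u, v, d in edges:
            out._add_edge(
                u,
                d["relation"],
                v,
                citation=d["citation"],
                evidence=d["evidence"],
                annotations=d["annotations"],
                induced=d["induced"],
            )
    return out


def stats(kg: KnowledgeGraph, include_induced: bool = True) -> GraphStats:
    by_type = Counter(d["node_type"] for _, d in kg.graph.nodes(data=True))
    n_edges = sum(1 for _ in kg.edge_records(include_induced=include_induced))
    citations = {
        d["citation"]
        for _, _, d in kg.edge_records(include_induced=False)
        if d["citation"] != "NA"
    }
    return GraphStats(
        n_nodes=kg.graph.number_of_nodes(),
        n_edges=n_edges,
        n_by_type=dict(sorted(by_type.items())),
        n_citations=len(citations),
    )


def evidence_count(kg: KnowledgeGraph, node_key: str) -> int:
    """Number of statement edges (either direction) incident to a node.

    Induced ``hasComponent`` edges do not count; a self-loop counts once.
    This is the node-abundance measure used for overlay node sizing.
    """
    if node_key not in kg.graph:
        raise KeyError(f"unknown node key: {node_key}")
    return sum(
        1
        for u, v, d in kg.graph.edges(data=True)
        if not d["induced"] and (u == node_key or v == node_key)
    )


# ---------------------------------------------------------------------------
# serialization


def _term_to_dict(term: BelTerm) -> dict:
    return {"bel": serialize_term(term)}


def to_node_link(kg: KnowledgeGraph) -> dict:
    """Canonical node-link dictionary (sorted nodes and edges)."""
    nodes = [
        {
            "key": key,
            "node_type": d["node_type"],
            "bel": serialize_term(d["term"]),
        }
        for key, d in sorted(kg.graph.nodes(data=True))
    ]
    edges = []
    for u, v, d in kg.graph.edges(data=True):
        ann = d["annotations"]
        edges.append(
            {
                "subject": u,
                "relation": d["relation"],
                "object": v,
                "citation": d["citation"],
                "evidence": d["evidence"],
                "induced": d["induced"],
                "annotations": _annotations_to_dict(ann),
            }
        )
    edges.sort(
        key=lambda e: (
            e["subject"],
            e["relation"],
            e["object"],
            e["citation"],
            e["evidence"],
        )
    )
    return {"nodes": nodes, "edges": edges, "provenance": list(kg.provenance)}


def _annotations_to_dict(ann: AnnotationSet | None) -> dict | None:
    if ann is None or ann.is_empty():
        return None
    out = {
        k: v
        for k, v in {
            "cell_type": ann.cell_type,
            "species": ann.species,
            "setting": ann.setting,
            "dose_value": ann.dose_value,
            "dose_unit": ann.dose_unit,
            "dose_qualifier": ann.dose_qualifier,
            "route": ann.route,
            "kd_value": ann.kd_value,
            "kd_unit": ann.kd_unit,
        }.items()
        if v is not None
    }
    if ann.extras:
        out["extras"] = dict(sorted(ann.extras.items()))
    return out


def _annotations_from_dict(data: dict | None) -> AnnotationSet | None:
    if data is None:
        return None
    extras = data.pop("extras", {})
    return AnnotationSet(extras=dict(extras), **data)


def from_node_link(data: dict) -> KnowledgeGraph:
    kg = KnowledgeGraph(provenance=list(data.get("provenance", [])))
    for node in data["nodes"]:
        kg.add_term(parse_term(node["bel"]))
    for edge in data["edges"]:
        if edge["induced"]:
            continue  # re-induced by add_term
        kg._add_edge(
            edge["subject"],
            edge["relation"],
            edge["object"],
            citation=edge["citation"],
            evidence=edge["evidence"],
            annotations=_annotations_from_dict(edge.get("annotations")),
            induced=False,
        )
    return kg


def write_json(kg: KnowledgeGraph, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(to_node_link(kg), fh, indent=1, sort_keys=True, ensure_ascii=False)
        fh.write("\n")


def read_json(path) -> KnowledgeGraph:
    with open(path, encoding="utf-8") as fh:
        return from_node_link(json.load(fh))


def write_graphml(kg: KnowledgeGraph, path) -> None:
    flat = nx.MultiDiGraph()
    for key, d in kg.graph.nodes(data=True):
        flat.add_node(key, node_type=d["node_type"], bel=serialize_term(d["term"]))
    for u, v, d in kg.graph.edges(data=True):
        ann = _annotations_to_dict(d["annotations"])
        flat.add_edge(
            u,
            v,
            relation=d["relation"],
            citation=d["citation"],
            evidence=d["evidence"],
            induced=d["induced"],
            annotations=json.dumps(ann, sort_keys=True) if ann else "",
        )
    nx.write_graphml(flat, path)


def node_table(kg: KnowledgeGraph) -> pd.DataFrame:
    data = to_node_link(kg)
    return pd.DataFrame(data["nodes"], columns=["key", "node_type", "bel"])


def edge_table(kg: KnowledgeGraph) -> pd.DataFrame:
    data = to_node_link(kg)
    rows = [
        {k: v for k, v in edge.items() if k != "annotations"}
        for edge in data["edges"]
    ]
    return pd.DataFrame(
        rows,
        columns=["subject", "relation", "object", "citation", "evidence", "induced"],
    )
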