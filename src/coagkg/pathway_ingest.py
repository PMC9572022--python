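"""Harmonized pathway-network ingestion and combination.

Pathway content from KEGG, Reactome and WikiPathways is consumed as flat
harmonized exports rather than native KGML/GPML/BioPAX: a TSV edge list
(``source  interaction  target  [source_class  target_class]``) or a GMT
membership file (one pathway per line: accession, description, members).
This keeps the analysis independent of database schema versions.  Protein
nodes are keyed by upper-case HGNC symbol; metabolite and process nodes keep
their case-folded common name so they can be matched against knowledge-graph
abundance/process nodes (fibrin, collagen, TXA2, ...).
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

__all__ = [
    "PathwayNetwork",
    "SymbolMap",
    "load_pathway",
    "load_tsv_edgelist",
    "load_gmt",
    "normalize_identifiers",
    "combine",
    "infer_source_db",
]

ENTITY_CLASSES = ("protein", "metabolite", "process")


def infer_source_db(accession: str) -> str:
    """Guess the source database from an accession's shape."""
    acc = accession.upper()
    if acc.startswith("R-HSA-"):
        return "Reactome"
    if acc.startswith("WP"):
        return "WikiPathways"
    if acc.startswith("HSA"):
        return "KEGG"
    return "unknown"


def _canonical_node_id(name: str, entity_class: str) -> str:
    if entity_class == "protein":
        if name.startswith("unmapped:"):
            return "unmapped:" + name[len("unmapped:"):].upper()
        return name.upper()
    return name.casefold()


@dataclass
class PathwayNetwork:
    """One or more database pathways as a harmonized interaction network."""

    pathway_ids: list[tuple[str, str]] = field(default_factory=list)
    #: node id -> (entity_class, xrefs)
    nodes: dict[str, tuple[str, frozenset[str]]] = field(default_factory=dict)
    #: (source, interaction type, target)
    edges: set[tuple[str, str, str]] = field(default_factory=set)
    #: node id -> accessions of the pathways it belongs to
    membership: dict[str, set[str]] = field(default_factory=dict)

    def add_node(
        self,
        name: str,
        entity_class: str = "protein",
        xrefs: frozenset[str] = frozenset(),
        accession: str | None = None,
    ) -> str:
        if entity_class not in ENTITY_CLASSES:
            raise ValueError(f"unknown entity class {entity_class!r}")
        node_id = _canonical_node_id(name, entity_class)
        cls, old_xrefs = self.nodes.get(node_id, (entity_class, frozenset()))
        if cls != entity_class:
            raise ValueError(
                f"node {node_id!r} declared as both {cls} and {entity_class}"
            )
        self.nodes[node_id] = (entity_class, old_xrefs | xrefs)
        members = self.membership.setdefault(node_id, set())
        if accession is not None:
            members.add(accession)
        return node_id

    def add_edge(self, source: str, interaction: str, target: str) -> None:
        for endpoint in (source, target):
            if endpoint not in self.nodes:
                raise ValueError(f"edge endpoint {endpoint!r} has no node")
        self.edges.add((source, interaction, target))

    def protein_symbols(self) -> set[str]:
        return {n for n, (cls, _) in self.nodes.items() if cls == "protein"}

    def named_entities(self) -> set[str]:
        return {n for n, (cls, _) in self.nodes.items() if cls != "protein"}


@dataclass
class SymbolMap:
    """(namespace, source id) -> HGNC symbol lookup table."""

    rows: dict[tuple[str, str], str] = field(default_factory=dict)

    @classmethod
    def from_tsv(cls, path) -> "SymbolMap":
        df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
        required = {"namespace", "id", "symbol"}
        if not required.issubset(df.columns):
            raise ValueError(f"symbol map requires columns {sorted(required)}")
        if df.duplicated(subset=["namespace", "id"]).any():
            raise ValueError("duplicate (namespace, id) keys in symbol map")
        if df["symbol"].isna().any() or (df["symbol"] == "").any():
            raise ValueError("empty symbols in symbol map")
        rows = {
            (ns.upper(), i): s.upper()
            for ns, i, s in zip(df["namespace"], df["id"], df["symbol"])
        }
        return cls(rows=rows)

    def lookup(self, identifier: str) -> str | None:
        """Resolve ``NS:ID`` or a bare id (searched across namespaces)."""
        if ":" in identifier:
            ns, _, raw = identifier.partition(":")
            return self.rows.get((ns.upper(), raw))
        matches = {s for (ns, i), s in self.rows.items() if i == identifier}
        if len(matches) == 1:
            return matches.pop()
        return None


def load_pathway(path, format: str | None = None, accession: str | None = None) -> PathwayNetwork:
    """Load one harmonized pathway export (``tsv_edgelist`` or ``gmt``).

    The format is inferred from the file suffix when not given.  The pathway
    accession defaults to the file stem for TSV files; GMT lines carry their
    own accessions.
    """
    path = Path(path)
    if format is None:
        format = "gmt" if path.suffix.lower() == ".gmt" else "tsv_edgelist"
    if format == "tsv_edgelist":
        return load_tsv_edgelist(path, accession=accession)
    if format == "gmt":
        return load_gmt(path)
    raise ValueError(f"unknown pathway format {format!r}")


def load_tsv_edgelist(path, accession: str | None = None) -> PathwayNetwork:
    path = Path(path)
    if accession is None:
        accession = path.stem
    net = PathwayNetwork(pathway_ids=[(infer_source_db(accession), accession)])
    with open(path, encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        n_rows = 0
        for line_no, row in enumerate(reader, start=1):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if row[0].startswith("#") or (line_no == 1 and row[0] == "source"):
                continue
            if len(row) not in (3, 5):
                raise ValueError(
                    f"{path}:{line_no}: expected 3 or 5 tab-separated fields, "
                    f"got {len(row)}"
                )
            source, interaction, target = (f.strip() for f in row[:3])
            if not source or not target:
                raise ValueError(f"{path}:{line_no}: empty endpoint")
            source_class = row[3].strip() if len(row) == 5 else "protein"
            target_class = row[4].strip() if len(row) == 5 else "protein"
            s = net.add_node(source, source_class, accession=accession)
            t = net.add_node(target, target_class, accession=accession)
            net.add_edge(s, interaction.strip(), t)
            n_rows += 1
    if n_rows == 0:
        warnings.warn(f"empty pathway file: {path}", stacklevel=2)
    return net


def load_gmt(path) -> PathwayNetwork:
    """Load a GMT gene-set file: membership only, no interactions."""
    path = Path(path)
    net = PathwayNetwork()
    n_sets = 0
    with open(path, encoding="utf-8") as fh:
        for line_no, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{line_no}: GMT line needs accession, description "
                    "and at least one member"
                )
            accession = fields[0].strip()
            if not accession:
                raise ValueError(f"{path}:{line_no}: empty accession")
            net.pathway_ids.append((infer_source_db(accession), accession))
            for member in fields[2:]:
                member = member.strip()
                if member:
                    net.add_node(member, "protein", accession=accession)
            n_sets += 1
    if n_sets == 0:
        warnings.warn(f"empty GMT file: {path}", stacklevel=2)
    return net


def normalize_identifiers(net: PathwayNetwork, symbol_map: SymbolMap) -> PathwayNetwork:
    """Re-key protein nodes to HGNC symbols via a mapping table.

    Unmapped identifiers that do not already look like symbols are kept under
    an ``unmapped:`` prefix so they stay visible downstream.  Nodes that map
    to the same symbol coalesce; edges are rewired, and edges collapsing onto
    a single node are dropped unless the self-loop existed in the source.
    """
    mapping: dict[str, str] = {}
    for node_id, (cls, _) in net.nodes.items():
        if cls != "protein":
            mapping[node_id] = node_id
            continue
        symbol = symbol_map.lookup(node_id)
        if symbol is not None:
            mapping[node_id] = symbol
        elif ":" in node_id:
            mapping[node_id] = f"unmapped:{node_id}"
        else:
            mapping[node_id] = node_id  # already a plain symbol
    out = PathwayNetwork(pathway_ids=list(net.pathway_ids))
    for node_id, (cls, xrefs) in net.nodes.items():
        new_id = mapping[node_id]
        extra = frozenset({node_id}) if new_id != node_id else frozenset()
        out.add_node(new_id, cls, xrefs=xrefs | extra)
        out.membership.setdefault(new_id, set()).update(net.membership.get(node_id, set()))
    for source, interaction, target in net.edges:
        s, t = mapping[source], mapping[target]
        if s == t and source != target:
            continue  # coalescence must not create self-loops
        out.add_edge(s, interaction, t)
    return out


def combine(nets: list[PathwayNetwork]) -> PathwayNetwork:
    """Union of pathway networks on node ids and (source, type, target) edges."""
    out = PathwayNetwork()
    for net in nets:
        out.pathway_ids.extend(net.pathway_ids)
        for node_id, (cls, xrefs) in net.nodes.items():
            out.add_node(node_id, cls, xrefs=xrefs)
            out.membership.setdefault(node_id, set()).update(
                net.membership.get(node_id, set())
            )
        out.edges |= net.edges
    return out
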