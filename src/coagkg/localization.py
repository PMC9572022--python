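"""Subcellular stratification of proteins from GO cellular-component terms.

Proteins are screened into three coarse compartments — extracellular,
membrane (plasma-membrane/transmembrane-associated) and intracellular —
from GAF 2.2 annotations, mirroring a QuickGO-style location screen.  The
classification is multi-label: a protein annotated to both the plasma
membrane and the cytosol carries both the ``membrane`` and ``intracellular``
labels, so per-compartment totals may exceed the number of classified
proteins.

The default GO-term-to-compartment table is flat (exact term match).  An
optional mode propagates labels through ``is_a``/``part_of`` ancestors given
a GO OBO file (via :mod:`obonet`); it is off by default so results do not
depend on an ontology snapshot.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

__all__ = [
    "COMPARTMENTS",
    "CompartmentMapping",
    "LocalizationTable",
    "load_gaf_table",
    "load_gaf",
    "classify",
    "build_table",
    "partition",
    "expand_mapping_with_ancestors",
]

COMPARTMENTS = ("extracellular", "membrane", "intracellular")

_GO_ID_RE = re.compile(r"GO:\d{7}")

#: default flat GO CC term -> compartment assignment
DEFAULT_CC_MAPPING = {
    "GO:0005576": "extracellular",  # extracellular region
    "GO:0005615": "extracellular",  # extracellular space
    "GO:0031012": "extracellular",  # extracellular matrix
    "GO:0016020": "membrane",       # membrane
    "GO:0005886": "membrane",       # plasma membrane
    "GO:0009897": "membrane",       # external side of plasma membrane
    "GO:0009986": "membrane",       # cell surface
    "GO:0005622": "intracellular",  # intracellular anatomical structure
    "GO:0005737": "intracellular",  # cytoplasm
    "GO:0005829": "intracellular",  # cytosol
    "GO:0005634": "intracellular",  # nucleus
}


@dataclass
class CompartmentMapping:
    """GO CC term -> compartment rows, loadable from an editable TSV."""

    rows: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_CC_MAPPING))

    def __post_init__(self) -> None:
        for go_id, compartment in self.rows.items():
            if not _GO_ID_RE.fullmatch(go_id):
                raise ValueError(f"invalid GO id {go_id!r}")
            if compartment not in COMPARTMENTS:
                raise ValueError(f"unknown compartment {compartment!r}")

    @classmethod
    def from_tsv(cls, path) -> "CompartmentMapping":
        rows: dict[str, str] = {}
        with open(path, encoding="utf-8") as fh:
            for line_no, raw in enumerate(fh, start=1):
                line = raw.strip()
                if not line or line.startswith("#") or line.startswith("go_id"):
                    continue
                fields = line.split("\t")
                if len(fields) < 2:
                    raise ValueError(f"{path}:{line_no}: expected go_id<TAB>compartment")
                rows[fields[0].strip()] = fields[1].strip()
        return cls(rows=rows)


@dataclass
class LocalizationTable:
    """Per-protein compartment labels plus the set left unassigned."""

    labels: dict[str, frozenset[str]] = field(default_factory=dict)
    unassigned: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        overlap = set(self.labels) & self.unassigned
        if overlap:
            raise ValueError(f"symbols both labelled and unassigned: {sorted(overlap)}")
        for symbol, labels in self.labels.items():
            if not labels:
                raise ValueError(f"empty label set for classified symbol {symbol}")

    @property
    def classified(self) -> set[str]:
        return set(self.labels)

    def in_compartment(self, compartment: str) -> set[str]:
        if compartment not in COMPARTMENTS:
            raise ValueError(f"unknown compartment {compartment!r}")
        return {s for s, labels in self.labels.items() if compartment in labels}


# ---------------------------------------------------------------------------
# GAF reading

_GAF_MIN_COLUMNS = 15  # GAF 2.x core columns; 2.2 files carry 17


def load_gaf_table(path) -> pd.DataFrame:
    """Read a GAF 2.2 file into a (symbol, go_id, qualifier, evidence, aspect) frame.

    Comment lines (``!``) are skipped; malformed rows raise with their line
    number.  All aspects are retained here — :func:`load_gaf` filters to
    cellular component.
    """
    records = []
    with open(path, encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh, delimiter="\t", quoting=csv.QUOTE_NONE)
        for line_no, row in enumerate(reader, start=1):
            if not row or row[0].startswith("!"):
                continue
            if len(row) < _GAF_MIN_COLUMNS:
                raise ValueError(
                    f"{path}:{line_no}: GAF row has {len(row)} columns, "
                    f"expected >= {_GAF_MIN_COLUMNS}"
                )
            go_id = row[4].strip()
            if not _GO_ID_RE.fullmatch(go_id):
                raise ValueError(f"{path}:{line_no}: malformed GO id {go_id!r}")
            records.append(
                {
                    "symbol": row[2].strip().upper(),
                    "qualifier": row[3].strip(),
                    "go_id": go_id,
                    "evidence": row[6].strip(),
                    "aspect": row[8].strip(),
                }
            )
    return pd.DataFrame(
        records, columns=["symbol", "qualifier", "go_id", "evidence", "aspect"]
    )


def load_gaf(path, exclude_evidence: tuple[str, ...] = ()) -> dict[str, set[str]]:
    """Symbol -> set of GO CC ids from a GAF 2.2 file.

    Only aspect ``C`` rows contribute; ``NOT``-qualified rows are excluded.
    ``exclude_evidence`` drops rows by evidence code (e.g. ``("IEA",)``); the
    default keeps all evidence.
    """
    table = load_gaf_table(path)
    mask = (
        (table["aspect"] == "C")
        & ~table["qualifier"].str.contains(r"\bNOT\b", regex=True)
    )
    if exclude_evidence:
        mask &= ~table["evidence"].isin(exclude_evidence)
    out: dict[str, set[str]] = {}
    for symbol, go_id in zip(table.loc[mask, "symbol"], table.loc[mask, "go_id"]):
        out.setdefault(symbol, set()).add(go_id)
    return out


# ---------------------------------------------------------------------------
# classification


def classify(
    symbol: str,
    annotations: dict[str, set[str]],
    mapping: CompartmentMapping | None = None,
) -> frozenset[str]:
    """Compartment labels for one symbol: the union over its mapped CC terms.

    Returns an empty frozenset when the symbol has no CC term or none of its
    terms is in the mapping (the caller records it as unassigned).
    """
    mapping = mapping or CompartmentMapping()
    terms = annotations.get(symbol, set())
    return frozenset(
        mapping.rows[t] for t in terms if t in mapping.rows
    )


def build_table(
    symbols: set[str],
    annotations: dict[str, set[str]],
    mapping: CompartmentMapping | None = None,
) -> LocalizationTable:
    """Classify a symbol set into a :class:`LocalizationTable`."""
    mapping = mapping or CompartmentMapping()
    labels: dict[str, frozenset[str]] = {}
    unassigned: set[str] = set()
    for symbol in symbols:
        compartments = classify(symbol, annotations, mapping)
        if compartments:
            labels[symbol] = compartments
        else:
            unassigned.add(symbol)
    return LocalizationTable(labels=labels, unassigned=unassigned)


def partition(symbols: set[str], table: LocalizationTable) -> dict[str, set[str]]:
    """Per-compartment symbol sets; a multi-label symbol appears in several."""
    return {
        compartment: {
            s
            for s in symbols
            if s in table.labels and compartment in table.labels[s]
        }
        for compartment in COMPARTMENTS
    }


def expand_mapping_with_ancestors(
    mapping: CompartmentMapping, obo_path
) -> CompartmentMapping:
    """Extend a flat mapping so descendants inherit their ancestors' compartment.

    Requires an OBO ontology file; traversal follows ``is_a`` and ``part_of``
    edges (child -> parent).  A term reaching mapped ancestors in several
    compartments keeps the label of the nearest one (ties broken by
    compartment order: extracellular, membrane, intracellular).
    """
    import networkx as nx
    import obonet

    graph = obonet.read_obo(Path(obo_path))
    rows = dict(mapping.rows)
    allowed = {"is_a", "part_of"}
    for term in graph.nodes:
        if term in rows or not _GO_ID_RE.fullmatch(term):
            continue
        # BFS toward ancestors; obonet edges point child -> parent
        best: tuple[int, int] | None = None
        best_compartment = None
        for target, length in nx.single_source_shortest_path_length(
            _restricted_view(graph, allowed), term
        ).items():
            if target in mapping.rows and length > 0:
                rank = COMPARTMENTS.index(mapping.rows[target])
                cand = (length, rank)
                if best is None or cand < best:
                    best = cand
                    best_compartment = mapping.rows[target]
        if best_compartment is not None:
            rows[term] = best_compartment
    return CompartmentMapping(rows=rows)


def _restricted_view(graph, allowed_keys: set[str]):
    import networkx as nx

    def edge_ok(u, v, k):
        return k in allowed_keys

    return nx.subgraph_view(graph, filter_edge=edge_ok)
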