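"""Superimposition of the knowledge graph with pathway networks.

The crosstalk analysis overlays the curated heme knowledge graph on a
database-derived pathway network and partitions the entities of the union
into *common* nodes (curated heme effects that sit inside the pathway),
*kg-only* nodes and *pathway-only* nodes (knowledge gaps: pathway members
with no curated heme relation).  Proteins are matched by HGNC symbol after
alias resolution — the literature freely mixes common names and gene
symbols (APC = PROC, thrombin = F2, tissue factor = F3) — and non-protein
entities (fibrin, collagen, thromboxane A2) by case-folded name.  Complexes
contribute their protein components, so a curated heme-FVIII complex makes
F8 overlap-eligible.

Node sizes reflect curation abundance (1 + number of supporting statements)
and a hypergeometric upper-tail test quantifies whether the observed overlap
exceeds chance for a given protein universe.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from scipy.stats import hypergeom

from .config import load_aliases
from .kg_model import KnowledgeGraph, evidence_count
from .localization import COMPARTMENTS, LocalizationTable
from .pathway_ingest import PathwayNetwork

__all__ = [
    "CrosstalkResult",
    "GapReport",
    "superimpose",
    "overlap_test",
    "gap_report",
    "export_report",
    "kg_overlap_entities",
    "pathway_overlap_entities",
]

LITERATURE_STATUSES = (
    "not_screened",
    "screened_negative",
    "screened_positive_external_celltype",
)


@dataclass
class CrosstalkResult:
    """Per-compartment partition of overlay entities with overlap statistic."""

    compartment: str  # one of COMPARTMENTS or "all"
    common: set[str]
    kg_only: set[str]
    pathway_only: set[str]
    node_sizes: dict[str, float]
    universe_size: int
    overlap_p: float | None = None
    #: pathway accessions per entity (for gap reporting)
    pathway_membership: dict[str, tuple[str, ...]] = field(default_factory=dict)
    #: compartment labels per entity where known
    compartments: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.common & self.kg_only or self.common & self.pathway_only:
            raise ValueError("membership classes must be disjoint")
        if self.kg_only & self.pathway_only:
            raise ValueError("membership classes must be disjoint")
        if self.overlap_p is not None and not (0.0 <= self.overlap_p <= 1.0):
            raise ValueError("overlap_p must be a probability")
        for symbol, size in self.node_sizes.items():
            if size <= 0:
                raise ValueError(f"non-positive node size for {symbol}")

    @property
    def kg_size(self) -> int:
        return len(self.common) + len(self.kg_only)

    @property
    def pathway_size(self) -> int:
        return len(self.common) + len(self.pathway_only)

    def all_symbols(self) -> set[str]:
        return self.common | self.kg_only | self.pathway_only


#: rows of (symbol, pathways, literature_status)
GapReport = pd.DataFrame


def _resolve(name: str, aliases: dict[str, str]) -> tuple[str, bool]:
    """Resolve an entity name through the alias table.

    Returns the canonical identifier and whether it is a protein symbol
    (upper-case HGNC) as opposed to a case-folded common name.
    """
    canonical = aliases.get(name.casefold())
    if canonical is not None:
        return canonical, canonical.isupper()
    return name, False


def kg_overlap_entities(
    kg: KnowledgeGraph, aliases: dict[str, str] | None = None
) -> tuple[set[str], set[str], dict[str, set[str]]]:
    """Extract the overlap-eligible entities of a knowledge graph.

    Returns (protein symbols, non-protein names, entity -> node keys).
    Protein nodes contribute their upper-cased HGNC symbol; complexes
    contribute every protein component; abundance/process/pathology nodes
    contribute their case-folded name, promoted to a protein symbol when the
    alias table equates the name with one (fibrinogen -> FGA).
    """
    aliases = load_aliases() if aliases is None else aliases
    proteins: set[str] = set()
    named: set[str] = set()
    sources: dict[str, set[str]] = {}

    def record(entity: str, key: str) -> None:
        sources.setdefault(entity, set()).add(key)

    for key, data in kg.graph.nodes(data=True):
        term = data["term"]
        if term.function == "protein":
            symbol = term.name.upper()
            resolved = aliases.get(symbol.casefold(), symbol)
            proteins.add(resolved)
            record(resolved, key)
        elif term.function in ("abundance", "bioProcess", "pathology"):
            resolved, is_protein = _resolve(term.name, aliases)
            if is_protein:
                proteins.add(resolved)
            else:
                named.add(resolved.casefold())
                resolved = resolved.casefold()
            record(resolved, key)
        # complex components are separate nodes already (induced), so the
        # protein branch above covers them; complex nodes themselves and
        # gene/rna/mirna/reaction nodes are not overlap-eligible
    return proteins, named, sources


def pathway_overlap_entities(
    net: PathwayNetwork, aliases: dict[str, str] | None = None
) -> tuple[set[str], set[str]]:
    """(protein symbols, non-protein names) of a pathway network."""
    aliases = load_aliases() if aliases is None else aliases
    proteins: set[str] = set()
    named: set[str] = set()
    for node_id, (cls, _) in net.nodes.items():
        if cls == "protein":
            proteins.add(aliases.get(node_id.casefold(), node_id))
        else:
            resolved, is_protein = _resolve(node_id, aliases)
            if is_protein:
                proteins.add(resolved)
            else:
                named.add(resolved.casefold())
    return proteins, named


def _resolved_membership(
    net: PathwayNetwork, aliases: dict[str, str]
) -> dict[str, set[str]]:
    out: dict[str, set[str]] = {}
    for node_id, accessions in net.membership.items():
        cls = net.nodes[node_id][0]
        if cls == "protein":
            entity = aliases.get(node_id.casefold(), node_id)
        else:
            entity, is_protein = _resolve(node_id, aliases)
            if not is_protein:
                entity = entity.casefold()
        out.setdefault(entity, set()).update(accessions)
    return out


def superimpose(
    kg: KnowledgeGraph,
    net: PathwayNetwork,
    loc: LocalizationTable | None = None,
    compartment: str | None = None,
    aliases: dict[str, str] | None = None,
    universe_size: int | None = None,
    size_range: tuple[float, float] | None = None,
) -> CrosstalkResult:
    """Overlay a knowledge graph with a pathway network.

    When ``compartment`` is given, protein sets on both sides are restricted
    to proteins carrying that compartment label in ``loc`` (which is then
    required); non-protein named entities are compartment-free and pass
    through.  ``universe_size`` sets the hypergeometric universe; it
    defaults to the size of the restricted union, in which case the test is
    conditional on the observed entity pool.
    """
    if compartment is not None:
        if loc is None:
            raise ValueError("compartment restriction requires a LocalizationTable")
        if compartment not in COMPARTMENTS:
            raise ValueError(f"unknown compartment {compartment!r}")
    aliases = load_aliases() if aliases is None else aliases

    kg_prot, kg_named, kg_sources = kg_overlap_entities(kg, aliases)
    pw_prot, pw_named = pathway_overlap_entities(net, aliases)

    if compartment is not None:
        in_comp = loc.in_compartment(compartment)
        kg_prot = kg_prot & in_comp
        pw_prot = pw_prot & in_comp

    kg_set = kg_prot | kg_named
    pw_set = pw_prot | pw_named
    common = kg_set & pw_set
    kg_only = kg_set - pw_set
    pathway_only = pw_set - kg_set

    # node sizing: 1 + curated-statement count, floor 1 for pathway-only
    sizes: dict[str, float] = {}
    for entity in kg_set | pw_set:
        evidence = sum(
            evidence_count(kg, key) for key in kg_sources.get(entity, ())
        )
        sizes[entity] = 1.0 + float(evidence)
    if size_range is not None:
        lo, hi = size_range
        if not (0 < lo <= hi):
            raise ValueError("size_range must satisfy 0 < lo <= hi")
        values = sizes.values()
        vmin, vmax = min(values, default=1.0), max(values, default=1.0)
        span = vmax - vmin
        sizes = {
            s: lo if span == 0 else lo + (v - vmin) * (hi - lo) / span
            for s, v in sizes.items()
        }

    universe = universe_size if universe_size is not None else len(kg_set | pw_set)
    membership = _resolved_membership(net, aliases)
    labels = {}
    if loc is not None:
        for entity in kg_set | pw_set:
            if entity in loc.labels:
                labels[entity] = tuple(sorted(loc.labels[entity]))

    result = CrosstalkResult(
        compartment=compartment or "all",
        common=common,
        kg_only=kg_only,
        pathway_only=pathway_only,
        node_sizes=sizes,
        universe_size=universe,
        pathway_membership={
            s: tuple(sorted(accs)) for s, accs in membership.items()
        },
        compartments=labels,
    )
    # with the default union universe the observed overlap is the smallest
    # feasible one and the tail probability degenerates to 1, so the test is
    # only reported for an explicitly supplied universe
    if universe_size is not None:
        result.overlap_p = overlap_test(result, universe_size)
    return result


def overlap_test(result: CrosstalkResult, universe_size: int) -> float:
    """Upper-tail hypergeometric probability of the observed overlap.

    With ``K`` knowledge-graph entities marked in a universe of ``M``
    entities and a pathway draw of size ``N``, returns
    ``P(X >= |common|)`` for ``X ~ Hypergeometric(M, K, N)``.
    """
    k = len(result.common)
    big_k = result.kg_size
    n = result.pathway_size
    m = universe_size
    if m < 0 or big_k > m or n > m:
        raise ValueError(
            f"infeasible counts: universe={m}, kg={big_k}, pathway={n}"
        )
    if k > min(big_k, n) or k < max(0, big_k + n - m):
        raise ValueError(f"infeasible overlap {k} for kg={big_k}, pathway={n}, universe={m}")
    if k == 0:
        return 1.0
    return float(hypergeom.sf(k - 1, m, big_k, n))


def gap_report(
    result: CrosstalkResult,
    screened: dict[str, str] | pd.DataFrame | None = None,
) -> GapReport:
    """Knowledge-gap table: pathway members absent from the knowledge graph.

    ``screened`` optionally attaches curated literature-screening statuses
    (a symbol -> status mapping or a two-column frame); screened-positive
    entries outside the pathway-only set are appended so manually recovered
    relations stay visible.  Rows are sorted by pathway count (desc), then
    symbol.
    """
    status_map: dict[str, str] = {}
    if screened is not None:
        if isinstance(screened, pd.DataFrame):
            screened = dict(zip(screened["symbol"], screened["literature_status"]))
        for symbol, status in screened.items():
            if status not in LITERATURE_STATUSES:
                raise ValueError(f"unknown literature status {status!r}")
            status_map[symbol] = status

    symbols = set(result.pathway_only)
    symbols |= {
        s
        for s, status in status_map.items()
        if status == "screened_positive_external_celltype"
    }
    rows = []
    for symbol in symbols:
        pathways = result.pathway_membership.get(symbol, ())
        rows.append(
            {
                "symbol": symbol,
                "pathways": ",".join(pathways),
                "n_pathways": len(pathways),
                "literature_status": status_map.get(symbol, "not_screened"),
            }
        )
    frame = pd.DataFrame(
        rows, columns=["symbol", "pathways", "n_pathways", "literature_status"]
    )
    if not frame.empty:
        frame = frame.sort_values(
            ["n_pathways", "symbol"], ascending=[False, True]
        ).reset_index(drop=True)
    return frame


def _membership_class(result: CrosstalkResult, symbol: str) -> str:
    if symbol in result.common:
        return "common"
    if symbol in result.kg_only:
        return "kg_only"
    return "pathway_only"


def overlap_table(result: CrosstalkResult) -> pd.DataFrame:
    rows = [
        {
            "symbol": symbol,
            "membership": _membership_class(result, symbol),
            "compartment": ";".join(result.compartments.get(symbol, ())),
            "size": result.node_sizes.get(symbol, 1.0),
            "pathways": ",".join(result.pathway_membership.get(symbol, ())),
        }
        for symbol in sorted(result.all_symbols())
    ]
    return pd.DataFrame(
        rows, columns=["symbol", "membership", "compartment", "size", "pathways"]
    )


def export_report(
    result: CrosstalkResult,
    outdir,
    screened: dict[str, str] | pd.DataFrame | None = None,
) -> dict[str, Path]:
    """Write overlap.tsv, gaps.tsv and overlay.json for one result.

    Output is byte-deterministic: rows and JSON keys are sorted and floats
    are rendered with a fixed format.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "overlap": outdir / "overlap.tsv",
        "gaps": outdir / "gaps.tsv",
        "overlay": outdir / "overlay.json",
    }
    table = overlap_table(result)
    table.to_csv(paths["overlap"], sep="\t", index=False, float_format="%.4f")
    gap_report(result, screened).to_csv(paths["gaps"], sep="\t", index=False)
    overlay = {
        "compartment": result.compartment,
        "universe_size": result.universe_size,
        "overlap_p": result.overlap_p,
        "nodes": [
            {
                "id": symbol,
                "membership": _membership_class(result, symbol),
                "size": round(result.node_sizes.get(symbol, 1.0), 6),
                "compartments": list(result.compartments.get(symbol, ())),
                "pathways": list(result.pathway_membership.get(symbol, ())),
            }
            for symbol in sorted(result.all_symbols())
        ],
    }
    with open(paths["overlay"], "w", encoding="utf-8") as fh:
        json.dump(overlay, fh, indent=1, sort_keys=True, ensure_ascii=False)
        fh.write("\n")
    return paths
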