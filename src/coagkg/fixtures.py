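"""Bundled "paper-mini" fixture: a synthetic hand-encoded mini corpus.

The fixture condenses the reported heme effects on the blood coagulation
cascade and platelet activation into ~30 BEL statements (heme-FVIII and
heme-APC binding with their K_D values, heme-driven tissue-factor and VWF
induction, GPVI/Syk/PLCγ2/Akt platelet signaling, ...) together with small
harmonized exports of the intrinsic (R-HSA-140837), extrinsic
(R-HSA-140834) and common (R-HSA-140875) fibrin-clot-formation pathways and
the platelet-activation pathway (HSA04611), a GAF file with compartment
annotations, and a curated literature-screening status table.  Everything is
synthetic text authored for offline testing; no database export is bundled.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .bel_core import BelDocument, normalize_document, parse_document
from .config import data_path, load_cc_mapping
from .kg_model import KnowledgeGraph, compile_documents
from .localization import LocalizationTable, build_table, load_gaf
from .pathway_ingest import PathwayNetwork, combine, load_pathway

__all__ = ["PaperMini", "paper_mini_dir", "load_paper_mini", "PAPER_MINI_PATHWAYS"]

#: accession -> cascade branch of the bundled pathway exports
PAPER_MINI_PATHWAYS = {
    "R-HSA-140837": "intrinsic",
    "R-HSA-140834": "extrinsic",
    "R-HSA-140875": "common",
    "HSA04611": "platelet_activation",
}


@dataclass
class PaperMini:
    document: BelDocument
    kg: KnowledgeGraph
    pathways: dict[str, PathwayNetwork]
    combined: PathwayNetwork
    localization: LocalizationTable
    screened: pd.DataFrame
    n_excluded: int


def paper_mini_dir() -> Path:
    return data_path("paper_mini")


def load_paper_mini() -> PaperMini:
    """Parse, normalize and compile the bundled fixture end to end."""
    root = paper_mini_dir()
    document = parse_document(
        (root / "heme_thromb_mini.bel").read_text(encoding="utf-8")
    )
    if document.errors:
        raise RuntimeError(f"fixture should parse cleanly: {document.errors}")
    document, n_excluded = normalize_document(document)
    kg = compile_documents([document])
    pathways = {
        accession: load_pathway(root / f"{accession}.tsv", accession=accession)
        for accession in PAPER_MINI_PATHWAYS
    }
    combined = combine(list(pathways.values()))
    annotations = load_gaf(root / "mini.gaf")
    symbols = set(annotations)
    localization = build_table(symbols, annotations, load_cc_mapping())
    screened = pd.read_csv(root / "screened.tsv", sep="\t", comment="#")
    return PaperMini(
        document=document,
        kg=kg,
        pathways=pathways,
        combined=combined,
        localization=localization,
        screened=screened,
        n_excluded=n_excluded,
    )
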