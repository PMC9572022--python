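"""Synthetic corpora, pathway exports and GO annotations with planted truth.

The generator emulates the statistical shape of a curated heme-coagulation
corpus: a heme-centric star-plus-pathway topology (heme or a heme-protein
complex is the subject of most statements), experimental-context annotations
filled at a configurable rate, pathway exports sharing a planted fraction of
their proteins with the corpus vocabulary, and a GAF file realizing planted
compartment labels through the default GO CC mapping.  Every planted count
(protein totals, per-pathway overlap, per-compartment sizes) is recorded in
a :class:`GroundTruth` so each pipeline stage can be checked exactly.

Entity names are drawn from a bundled coagulation vocabulary (F2, F3, F8,
VWF, PROC, KLKB1, GP6, SYK, ...) before falling back to synthetic symbols,
so generated fixtures read like real curation.  Each stage consumes its own
seeded stream derived from ``SimConfig.seed``, so adding or re-running a
stage never perturbs the output of another.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field
from pathlib import Path

from .bel_core import (
    RELATIONS,
    AnnotationSet,
    BelDocument,
    BelStatement,
    BelTerm,
    DocumentHeader,
    serialize_document,
)
from .localization import COMPARTMENTS, CompartmentMapping

__all__ = [
    "SimConfig",
    "GroundTruth",
    "SyntheticDataset",
    "COAGULATION_VOCABULARY",
    "generate_corpus",
    "generate_pathways",
    "generate_gaf",
    "generate_symbol_map",
    "generate_all",
    "write_dataset",
]

#: coagulation-flavored protein vocabulary used before synthetic fallbacks
COAGULATION_VOCABULARY = (
    "F2", "F3", "F5", "F7", "F8", "F9", "F10", "F11", "F12", "F13A1",
    "FGA", "FGB", "FGG", "VWF", "PROC", "PROS1", "KLKB1", "KNG1",
    "SERPINC1", "SERPINE1", "SERPING1", "THBD", "TFPI", "PLG", "PLAT",
    "PLAU", "GP6", "GP5", "GP9", "GP1BA", "ITGA2B", "ITGB3", "SYK",
    "AKT1", "NOS3", "PLCG2", "PRKCA", "PIK3CA", "SRC", "MAPK1", "MAPK3",
    "BTK", "LCP2", "RASGRP1", "RAP1A", "PTGS1", "TBXAS1", "FCER1G",
    "FCGR2A", "TLR4", "CLEC1B", "MYH9", "MMP9", "SELE", "SELP", "ICAM1",
    "VCAM1", "C3", "HP", "HPX",
)

_PROCESS_NAMES = (
    "blood coagulation",
    "platelet activation",
    "platelet aggregation",
    "fibrinolysis",
    "hemostasis",
)

_CELL_TYPES = ("endothelial cell", "platelet", "neutrophil", "monocyte")

_HEME = BelTerm(function="abundance", namespace="CHEBI", name="heme")


@dataclass
class SimConfig:
    """Study conditions for one synthetic dataset.

    Defaults mirror the scale of the curated corpus this package models:
    47 proteins over 426 statements, six pathways sharing roughly a third of
    their members with the corpus, and compartment weights reproducing the
    extracellular-heavy split of plasma-protein curation.
    """

    n_proteins: int = 47
    n_statements: int = 426
    relation_weights: tuple[float, ...] = (0.45, 0.10, 0.20, 0.10, 0.10, 0.05)
    p_complex: float = 0.2
    heme_fraction: float = 0.8
    annotation_fill: float = 0.5
    n_pathways: int = 6
    pathway_size: tuple[int, int] = (10, 30)
    overlap_fraction: float = 0.3
    compartment_weights: tuple[float, float, float] = (0.44, 0.20, 0.36)
    multilabel_p: float = 0.06
    #: exact per-compartment label counts (e, m, i); overrides the weights
    compartment_counts: tuple[int, int, int] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_proteins <= 0:
            raise ValueError("n_proteins must be positive")
        if self.n_statements < 0:
            raise ValueError("n_statements must be non-negative")
        if len(self.relation_weights) != len(RELATIONS):
            raise ValueError("relation_weights must cover the six relations")
        for name in ("p_complex", "heme_fraction", "annotation_fill",
                     "overlap_fraction", "multilabel_p"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        for weights in (self.relation_weights, self.compartment_weights):
            if any(w < 0 for w in weights):
                raise ValueError("weights must be non-negative")
            if abs(sum(weights) - 1.0) > 1e-9:
                raise ValueError("weight vectors must sum to 1")
        lo, hi = self.pathway_size
        if not (0 < lo <= hi):
            raise ValueError("pathway_size range must satisfy 0 < lo <= hi")
        if self.n_pathways < 0:
            raise ValueError("n_pathways must be non-negative")
        if self.compartment_counts is not None:
            e, m, i = self.compartment_counts
            if min(e, m, i) < 0 or e + m + i < self.n_proteins:
                raise ValueError(
                    "compartment_counts must be non-negative and sum to at "
                    "least n_proteins"
                )
            if e + m + i > 3 * self.n_proteins:
                raise ValueError("compartment_counts exceed three labels per protein")


@dataclass
class GroundTruth:
    """Planted facts recorded while generating a dataset."""

    proteins: list[str] = field(default_factory=list)
    processes: list[str] = field(default_factory=list)
    statements: list[BelStatement] = field(default_factory=list)
    #: protein -> planted compartment labels
    compartments: dict[str, frozenset[str]] = field(default_factory=dict)
    #: accession -> pathway facts (members, shared set, per-compartment overlap)
    pathways: dict[str, dict] = field(default_factory=dict)

    def per_compartment_counts(self) -> tuple[int, int, int]:
        return tuple(
            sum(1 for labels in self.compartments.values() if c in labels)
            for c in COMPARTMENTS
        )


@dataclass
class SyntheticDataset:
    documents: list[BelDocument]
    bel_text: str
    pathway_files: dict[str, str]
    gaf_text: str
    symbol_map_text: str
    truth: GroundTruth


def _vocabulary(n: int) -> list[str]:
    vocab = list(COAGULATION_VOCABULARY[:n])
    for i in range(len(vocab), n):
        vocab.append(f"SYN{i:03d}")
    return vocab


def _assign_compartments(cfg: SimConfig, vocab: list[str], rng: random.Random):
    labels: dict[str, set[str]] = {p: set() for p in vocab}
    if cfg.compartment_counts is not None:
        remaining = dict(zip(COMPARTMENTS, cfg.compartment_counts))
        for protein in vocab:
            compartment = max(COMPARTMENTS, key=lambda c: remaining[c])
            if remaining[compartment] == 0:
                raise ValueError("compartment_counts infeasible")
            labels[protein].add(compartment)
            remaining[compartment] -= 1
        for compartment in COMPARTMENTS:
            while remaining[compartment] > 0:
                candidates = [p for p in vocab if compartment not in labels[p]]
                if not candidates:
                    raise ValueError("compartment_counts infeasible")
                labels[rng.choice(candidates)].add(compartment)
                remaining[compartment] -= 1
    else:
        for protein in vocab:
            primary = rng.choices(COMPARTMENTS, weights=cfg.compartment_weights)[0]
            labels[protein].add(primary)
            if rng.random() < cfg.multilabel_p:
                others = [c for c in COMPARTMENTS if c != primary]
                labels[protein].add(rng.choice(others))
    return {p: frozenset(s) for p, s in labels.items()}


def _random_annotations(cfg: SimConfig, rng: random.Random, is_complex: bool) -> AnnotationSet:
    fill = cfg.annotation_fill
    kwargs: dict = {}
    if rng.random() < fill:
        kwargs["cell_type"] = rng.choice(_CELL_TYPES)
    if rng.random() < fill:
        kwargs["species"] = rng.choice(("9606", "10090"))
    if rng.random() < fill:
        kwargs["setting"] = rng.choice(("in_vitro", "in_vivo", "ex_vivo"))
    if rng.random() < fill:
        kwargs["dose_value"] = float(rng.choice((5, 10, 25, 50, 100)))
        kwargs["dose_unit"] = "µM" if kwargs.get("setting") != "in_vivo" else "µmol/kg"
        kwargs["dose_qualifier"] = "up_to" if rng.random() < 0.5 else "exact"
    if rng.random() < fill:
        kwargs["route"] = rng.choice(("incubation", "intravenous", "retroorbital"))
    if is_complex and rng.random() < fill:
        kwargs["kd_value"] = round(rng.uniform(1.0, 500.0), 1)
        kwargs["kd_unit"] = rng.choice(("nM", "µM"))
    return AnnotationSet(**kwargs)


def generate_corpus(cfg: SimConfig) -> tuple[list[BelDocument], GroundTruth]:
    """Generate a BEL corpus whose compiled graph has exactly the planted
    protein vocabulary (every protein appears in at least one statement when
    ``n_statements >= n_proteins``)."""
    rng = random.Random(cfg.seed * 1000003 + 1)
    vocab = _vocabulary(cfg.n_proteins)
    truth = GroundTruth()
    truth.compartments = _assign_compartments(cfg, vocab, rng)

    header = DocumentHeader(
        name="synthetic-heme-corpus",
        version="1.0",
        namespaces={"HGNC": "synthetic", "CHEBI": "synthetic", "GO": "synthetic"},
    )
    statements: list[BelStatement] = []
    used: set[str] = set()
    processes_used: set[str] = set()
    for i in range(cfg.n_statements):
        # coverage pass: the first n_proteins statements target each protein
        if i < cfg.n_proteins:
            target = vocab[i]
        else:
            target = rng.choice(vocab)
        obj: BelTerm
        if i >= cfg.n_proteins and rng.random() < 0.1:
            process = rng.choice(_PROCESS_NAMES)
            processes_used.add(process)
            obj = BelTerm(function="bioProcess", namespace="GO", name=process)
        else:
            obj = BelTerm(function="protein", namespace="HGNC", name=target)
            used.add(target)
        is_complex = False
        if rng.random() < cfg.heme_fraction:
            if rng.random() < cfg.p_complex:
                partner = rng.choice(vocab)
                used.add(partner)
                subject = BelTerm(
                    function="complex",
                    components=(
                        _HEME,
                        BelTerm(function="protein", namespace="HGNC", name=partner),
                    ),
                )
                is_complex = True
            else:
                subject = _HEME
        else:
            source = rng.choice(vocab)
            used.add(source)
            subject = BelTerm(function="protein", namespace="HGNC", name=source)
        relation = rng.choices(RELATIONS, weights=cfg.relation_weights)[0]
        statements.append(
            BelStatement(
                subject=subject,
                relation=relation,
                object=obj,
                citation=str(30000000 + i),
                evidence=f"synthetic evidence {i}",
                annotations=_random_annotations(cfg, rng, is_complex),
            )
        )
    doc = BelDocument(statements=statements, header=header)
    doc.line_counts = (len(statements), 0, 0)
    truth.proteins = sorted(used) if cfg.n_statements else []
    truth.processes = sorted(processes_used)
    truth.statements = list(statements)
    # drop compartment entries for proteins that never made it into a statement
    truth.compartments = {
        p: labels for p, labels in truth.compartments.items() if p in used
    }
    return [doc], truth


_DB_CYCLE = ("Reactome", "KEGG", "WikiPathways")
_INTERACTIONS = ("activation", "inhibition", "binding")


def _accession(db: str, index: int) -> str:
    if db == "Reactome":
        return f"R-HSA-9{index:05d}"
    if db == "KEGG":
        return f"HSA9{index:04d}"
    return f"WP9{index:03d}"


def generate_pathways(
    cfg: SimConfig, truth: GroundTruth
) -> tuple[dict[str, str], GroundTruth]:
    """Emit pathway exports each sharing ``ceil(overlap_fraction * size)``
    proteins with the corpus vocabulary; the planted overlap is recorded
    globally and per compartment.  Formats alternate between the TSV edge
    list and GMT so both readers are exercised end to end."""
    rng = random.Random(cfg.seed * 1000003 + 2)
    vocab = sorted(truth.proteins)
    files: dict[str, str] = {}
    for index in range(cfg.n_pathways):
        db = _DB_CYCLE[index % len(_DB_CYCLE)]
        accession = _accession(db, index)
        size = rng.randint(*cfg.pathway_size)
        n_shared = math.ceil(cfg.overlap_fraction * size)
        if n_shared > len(vocab):
            raise ValueError(
                f"planted overlap {n_shared} exceeds corpus vocabulary "
                f"({len(vocab)} proteins)"
            )
        shared = sorted(rng.sample(vocab, n_shared))
        novel = [f"PW{index:02d}G{j:03d}" for j in range(size - n_shared)]
        members = shared + novel
        rng.shuffle(members)
        use_gmt = index % 2 == 1
        if use_gmt:
            line = "\t".join([accession, f"synthetic pathway {index}"] + members)
            files[f"{accession}.gmt"] = line + "\n"
            n_edges = 0
        else:
            rows = []
            for a, b in zip(members, members[1:]):
                rows.append(f"{a}\t{rng.choice(_INTERACTIONS)}\t{b}\tprotein\tprotein")
            extra = max(0, size // 4)
            for _ in range(extra):
                a, b = rng.sample(members, 2)
                rows.append(f"{a}\t{rng.choice(_INTERACTIONS)}\t{b}\tprotein\tprotein")
            seen: set[str] = set()
            unique_rows = [r for r in rows if not (r in seen or seen.add(r))]
            files[f"{accession}.tsv"] = (
                "source\tinteraction\ttarget\tsource_class\ttarget_class\n"
                + "\n".join(unique_rows)
                + "\n"
            )
            n_edges = len(unique_rows)
        truth.pathways[accession] = {
            "db": db,
            "format": "gmt" if use_gmt else "tsv_edgelist",
            "members": set(members),
            "shared": set(shared),
            "n_nodes": size,
            "n_edges": n_edges,
            "per_compartment": {
                c: {p for p in shared if c in truth.compartments.get(p, frozenset())}
                for c in COMPARTMENTS
            },
        }
    return files, truth


def generate_gaf(cfg: SimConfig, truth: GroundTruth) -> str:
    """GAF 2.2 text realizing every planted compartment label through the
    default GO CC mapping; a few molecular-function rows are mixed in to
    exercise aspect filtering."""
    rng = random.Random(cfg.seed * 1000003 + 3)
    mapping = CompartmentMapping()
    by_compartment: dict[str, list[str]] = {c: [] for c in COMPARTMENTS}
    for go_id, compartment in mapping.rows.items():
        by_compartment[compartment].append(go_id)
    for terms in by_compartment.values():
        terms.sort()
    lines = ["!gaf-version: 2.2"]
    for i, protein in enumerate(sorted(truth.compartments)):
        for compartment in sorted(truth.compartments[protein]):
            go_id = rng.choice(by_compartment[compartment])
            lines.append(_gaf_row(protein, go_id, aspect="C"))
        if i % 5 == 0:  # non-CC noise row, must be ignored downstream
            lines.append(_gaf_row(protein, "GO:0003824", aspect="F"))
    return "\n".join(lines) + "\n"


def _gaf_row(symbol: str, go_id: str, aspect: str) -> str:
    qualifier = "located_in" if aspect == "C" else "enables"
    return "\t".join(
        [
            "HGNC",            # DB
            symbol,            # DB object id
            symbol,            # DB object symbol
            qualifier,         # qualifier
            go_id,             # GO id
            "PMID:30000000",   # reference
            "IDA",             # evidence code
            "",                # with/from
            aspect,            # aspect
            symbol,            # name
            "",                # synonym
            "protein",         # type
            "taxon:9606",      # taxon
            "20220101",        # date
            "synthetic",       # assigned by
            "",                # annotation extension
            "",                # gene product form
        ]
    )


def generate_symbol_map(truth: GroundTruth) -> str:
    """HGNC + synthetic-UniProt rows covering the corpus vocabulary."""
    lines = ["namespace\tid\tsymbol"]
    for i, protein in enumerate(sorted(truth.proteins)):
        lines.append(f"HGNC\t{protein}\t{protein}")
        lines.append(f"UNIPROT\tP9{i:04d}\t{protein}")
    return "\n".join(lines) + "\n"


def generate_all(cfg: SimConfig) -> SyntheticDataset:
    """Run every generator stage and bundle files plus ground truth."""
    documents, truth = generate_corpus(cfg)
    pathway_files, truth = generate_pathways(cfg, truth)
    gaf_text = generate_gaf(cfg, truth)
    symbol_map_text = generate_symbol_map(truth)
    bel_text = "".join(serialize_document(doc) for doc in documents)
    return SyntheticDataset(
        documents=documents,
        bel_text=bel_text,
        pathway_files=pathway_files,
        gaf_text=gaf_text,
        symbol_map_text=symbol_map_text,
        truth=truth,
    )


def write_dataset(dataset: SyntheticDataset, outdir) -> dict[str, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    paths["corpus"] = outdir / "corpus.bel"
    paths["corpus"].write_text(dataset.bel_text, encoding="utf-8")
    for name, text in dataset.pathway_files.items():
        paths[name] = outdir / name
        paths[name].write_text(text, encoding="utf-8")
    paths["gaf"] = outdir / "annotations.gaf"
    paths["gaf"].write_text(dataset.gaf_text, encoding="utf-8")
    paths["symbol_map"] = outdir / "symbol_map.tsv"
    paths["symbol_map"].write_text(dataset.symbol_map_text, encoding="utf-8")
    return paths
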