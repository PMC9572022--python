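# Methods

`coagkg` models how a curated knowledge graph of heme effects on the blood
coagulation system can be compared, compartment by compartment, with the
pathway content of KEGG, Reactome and WikiPathways. This note documents the
model, the tunable parameters, the synthetic-data conditions the test suite
runs under, and the numerical/design choices that were genuinely open.

## Knowledge model

Curated knowledge is held as BEL statements: `subject relation object`
triples over nine entity functions (protein, gene, RNA, miRNA, abundance,
complex, biological process, pathology, reaction) and six relations
(increases, directlyIncreases, decreases, directlyDecreases, association,
regulates), each carrying a citation, evidence text and experimental-context
annotations (cell type, species, in-vitro/in-vivo/ex-vivo setting, heme dose
with an `up to` qualifier, administration route, and the heme-binding
K_D where measured). The grammar subset and its normalization rules are in
`docs/bel_subset.md`.

The compiled knowledge graph is an evidence-level multigraph: one edge per
curated statement, so the same triple asserted under two citations remains
two edges, and the edge-deduplication key is the full
(subject, relation, object, citation, evidence) tuple. This convention is
what makes edge totals commensurate with statement counts when graphs are
merged. Complex nodes additionally induce `hasComponent` edges to their
component nodes, tagged `induced=True`; `stats(include_induced=...)`
reports edge totals under either convention, and induced edges never count
toward a node's evidence abundance. Compilation sorts statements by their
full identity before insertion, making the graph invariant under statement
and document order; merging unions node sets by canonical key and
deduplicates edges by the five-tuple, concatenating provenance.

## Pathway ingestion

Pathway content is consumed as harmonized flat exports — a TSV edge list
(`source, interaction, target[, source_class, target_class]`) or a GMT
membership file — rather than native KGML/GPML/BioPAX. The analysis needs
only membership and coarse interactions, and a flat exchange format makes
results independent of database schema versions. Protein nodes are keyed by
upper-case HGNC symbol (a `SymbolMap` TSV translates UniProt/KEGG ids;
unmapped ids are kept under an `unmapped:` prefix rather than dropped);
metabolite and process nodes keep their case-folded common name. Interaction
type strings do not participate in overlap identity.

## Compartment stratification

Proteins are classified into extracellular / membrane / intracellular from
GAF 2.2 cellular-component annotations (aspect `C`, `NOT` rows excluded,
evidence codes retained and filterable). The default mapping is a flat
eleven-term table (`src/coagkg/data/cc_map.tsv`): extracellular region and
space and ECM → extracellular; membrane, plasma membrane, its external side
and cell surface → membrane; intracellular, cytoplasm, cytosol, nucleus →
intracellular. Classification is multi-label with no precedence: a protein
annotated to both plasma membrane and cytosol carries both labels, so
per-compartment totals may exceed the classified-protein count. This is the
reading consistent with curated corpora in this domain, where the three
compartment totals can sum to more than the protein total. An optional mode
propagates labels through `is_a`/`part_of` ancestors given an OBO file
(via `obonet`); it is off by default so results do not silently track
ontology releases.

## Superimposition and the overlap statistic

`superimpose` intersects the knowledge graph's overlap-eligible entities
with a pathway network's: proteins by HGNC symbol after alias resolution,
non-proteins by case-folded name. The alias table
(`src/coagkg/data/aliases.tsv`) encodes the common-name/symbol mixture of
the coagulation literature (APC = PROC, thrombin = F2, tissue factor = F3,
fibrinogen = FGA, GPVI = GP6, TXA2 = thromboxane A2, ...); it is a curated,
editable config, scoped to this domain. Complexes contribute their protein
components, so a curated heme–FVIII complex makes F8 overlap-eligible. With
a compartment given, both protein sets are restricted to proteins carrying
that label; named non-protein entities have no GO CC annotation and pass
through unrestricted.

Node sizes encode curation abundance: `1 + evidence_count` (statement edges
incident to the node, either direction, induced edges excluded), with the
floor of 1 for zero-evidence pathway-only nodes, optionally rescaled
linearly to a display range.

The overlap statistic is the upper-tail hypergeometric probability
P(X ≥ |common|) of drawing the pathway's entity set from a universe of M
entities of which the knowledge graph marks K. The universe is an explicit
parameter: with the default "union" universe the observed overlap is the
smallest feasible value and the tail probability is identically 1, so the
test is only reported when a universe is supplied (e.g. the 246-protein
merged-graph universe used in `scripts/acceptance.py`). Infeasible count
combinations raise rather than returning a clamped value.

Gap reports list pathway-only entities with their pathway membership,
sorted by membership count then symbol. Literature-screening status
(screened-negative, or screened-positive in another cell type) is a curated
input TSV, not computed — it is the product of manual literature screening,
which is out of scope for automation here.

## Synthetic data: what it emulates and what it does not

The generator plants a heme-centric star-plus-pathway topology: heme (or a
heme–protein complex) is the subject of `heme_fraction` of statements,
objects cover the protein vocabulary (the first `n_proteins` statements
target each protein once, guaranteeing the planted protein count),
annotations are filled independently at rate `annotation_fill`, pathway
exports share `ceil(overlap_fraction × size)` proteins with the corpus, and
a GAF realizes each protein's planted compartment labels through the default
mapping. Defaults mirror the reference corpus scale this package models:
47 proteins, 426 statements, six pathways of 10–30 members sharing ~30% of
their proteins, compartment weights (0.44, 0.20, 0.36) with a 6%
second-label rate; `compartment_counts` can instead plant exact
per-compartment totals such as (22, 10, 18). Each stage draws from its own
stream derived deterministically from the seed, so regenerating one stage
never perturbs another; identical configs produce byte-identical files.

What the generator does **not** emulate: citation reuse across statements
(every synthetic statement gets a distinct PMID-like citation, so edge
deduplication is never exercised by chance), correlated annotations (dose
and setting are drawn independently), biological plausibility of individual
triples, and the long-tailed degree distribution of real curation. Passing
the planted-recovery suite therefore demonstrates that the pipeline's
bookkeeping is exact — counts, intersections and labels survive
serialization round-trips — not that the method is robust to noisy or
inconsistent curation, which is a property of curation practice rather than
of this code.

## Numerical and design choices

- **Canonical node identity** embeds the BEL function, the namespace and
  the case-folded name (components sorted for complexes). Heme synonym
  normalization is what unifies `TEXT`/`CHEBI` heme entries; a
  namespace-less key was rejected because it would merge unrelated
  free-text entities.
- **Tie-breaks and determinism**: statements sort by full identity before
  compilation; exports sort rows and JSON keys and fix float formatting, so
  repeated exports are byte-identical.
- **Degenerate inputs**: empty documents compile to the empty graph; empty
  pathway files load with a warning; overlap of an empty common set returns
  p = 1; `compartment` without a localization table, infeasible
  hypergeometric counts, and overlap fractions exceeding the vocabulary all
  raise.
- **Problem sizes in tests**: the oracle suites run 1,000 random overlay
  instances over a 20-symbol vocabulary, exhaustive hypergeometric
  enumeration for every universe up to 12, and 50-seed end-to-end planted
  recovery at 12 proteins / 50 statements / 3 pathways — sizes chosen so the
  whole suite exercises every code path while staying comfortably
  interactive.

## Known limitations

- Full BEL 2.1 (modifications, fusions, translocations, nested statements)
  is out of scope; the parser rejects such content explicitly.
- The flat CC mapping treats only eleven anchor terms; annotations given as
  finer-grained descendants require the optional OBO ancestor mode.
- The alias table is domain-scoped and hand-curated; applying the package
  outside hemostasis requires extending it.
- Reproducing published corpus-level statistics requires the public
  curation deposit; the bundled fixture is a synthetic condensation for
  offline testing, not a copy of the deposit.
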