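"""Parser, serializer and entity-normalization behaviour."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from coagkg.bel_core import (
    EXCLUDED,
    AnnotationSet,
    BelParseError,
    BelTerm,
    normalize_document,
    normalize_entity,
    parse_document,
    parse_statement,
    parse_term,
    serialize_document,
    serialize_term,
)
from coagkg.synthetic_data import SimConfig, generate_corpus


class TestTermParsing:
    def test_simple_abundance(self):
        term = parse_term("a(CHEBI:heme)")
        assert (term.function, term.namespace, term.name) == ("abundance", "CHEBI", "heme")

    def test_quoted_name_with_spaces(self):
        term = parse_term('bp(GO:"blood coagulation")')
        assert term.function == "bioProcess"
        assert term.name == "blood coagulation"

    def test_activity_modifier(self):
        term = parse_term("act(p(HGNC:PROC))")
        assert term.activity and term.function == "protein"

    def test_nested_complex(self):
        term = parse_term("complex(a(CHEBI:heme), complex(p(HGNC:F8), p(HGNC:VWF)))")
        assert term.function == "complex"
        assert {c.function for c in term.components} == {"abundance", "complex"}

    def test_component_order_irrelevant_for_key(self):
        a = parse_term("complex(p(HGNC:F8), p(HGNC:VWF))")
        b = parse_term("complex(p(HGNC:VWF), p(HGNC:F8))")
        assert a.key == b.key and a == b

    def test_key_case_insensitive(self):
        assert parse_term("p(HGNC:f8)").key == parse_term("p(HGNC:F8)").key

    @pytest.mark.parametrize(
        "text",
        ["p(HGNC:F8", "p(HGNC:)", "frob(HGNC:F8)", 'a(CHEBI:"heme)', "complex(p(HGNC:F8))"],
    )
    def test_malformed_terms_rejected(self, text):
        with pytest.raises((BelParseError, ValueError)):
            parse_term(text)


_LEAF = st.builds(
    BelTerm,
    function=st.sampled_from(["protein", "gene", "rna", "mirna", "abundance", "bioProcess", "pathology"]),
    namespace=st.sampled_from(["HGNC", "CHEBI", "GO", "MESH", "TEXT"]),
    name=st.text(
        alphabet=st.characters(codec="utf-8", exclude_characters='\\"\n\r\t'),
        min_size=1,
        max_size=12,
    ).filter(lambda s: s.strip() == s and s),
)

_TERMS = st.recursive(
    _LEAF,
    lambda children: st.builds(
        BelTerm,
        function=st.just("complex"),
        components=st.lists(children, min_size=2, max_size=3).map(tuple),
    ),
    max_leaves=6,
)


class TestRoundTrip:
    @settings(derandomize=True, max_examples=300)
    @given(term=_TERMS)
    def test_term_round_trip(self, term):
        assert parse_term(serialize_term(term)) == term

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_document_round_trip_over_generated_corpora(self, seed):
        docs, _ = generate_corpus(SimConfig(n_proteins=10, n_statements=120, seed=seed))
        text = serialize_document(docs[0])
        reparsed = parse_document(text)
        assert not reparsed.errors
        assert reparsed.same_statements(docs[0])
        # parse-serialize-parse is a fixed point
        again = parse_document(serialize_document(reparsed))
        assert again.same_statements(reparsed)

    def test_serialization_is_byte_stable(self):
        docs, _ = generate_corpus(SimConfig(n_proteins=20, n_statements=500, seed=3))
        assert serialize_document(docs[0]) == serialize_document(docs[0])


class TestStatementParsing:
    def test_relation_and_annotation_capture(self):
        text = (
            'SET Setting = "in vitro"\n'
            'p(HGNC:F8) -| bp(GO:"blood coagulation")\n'
        )
        doc = parse_document(text)
        [statement] = doc.statements
        assert statement.relation == "decreases"
        assert statement.annotations.setting == "in_vitro"

    def test_complex_subject_with_activity_object(self):
        statement = parse_statement(
            "complex(a(CHEBI:heme), p(HGNC:PROC)) =| act(p(HGNC:PROC))"
        )
        assert statement.relation == "directlyDecreases"
        assert statement.subject.function == "complex"
        assert len(statement.subject.components) == 2
        assert statement.object.activity

    def test_nested_statement_rejected(self):
        with pytest.raises(BelParseError, match="nested"):
            parse_statement("a(CHEBI:heme) -> (p(HGNC:F3) -> bp(GO:hemostasis))")

    def test_dose_upper_bound_parsing(self):
        doc = parse_document('SET Dose = "up to 100 µM"\na(CHEBI:heme) -> p(HGNC:VWF)')
        ann = doc.statements[0].annotations
        assert (ann.dose_qualifier, ann.dose_value, ann.dose_unit) == ("up_to", 100.0, "µM")

    def test_unparseable_dose_kept_verbatim_and_flagged(self):
        doc = parse_document(
            'SET Dose = "a smidgen"\na(CHEBI:heme) -> p(HGNC:VWF)'
        )
        assert doc.statements[0].annotations.extras["Dose"] == "a smidgen"
        assert any("dose" in w.message.lower() for w in doc.warnings)

    def test_unknown_annotation_key_preserved_with_warning(self):
        doc = parse_document('SET Vendor = "acme"\na(CHEBI:heme) -> p(HGNC:VWF)')
        assert doc.statements[0].annotations.extras["Vendor"] == "acme"
        assert len(doc.warnings) == 1

    def test_parse_errors_name_line(self):
        doc = parse_document("a(CHEBI:heme) -> p(HGNC:VWF)\nnot a statement\n")
        assert len(doc.statements) == 1
        [error] = doc.errors
        assert error.line_number == 2

    def test_strict_mode_raises(self):
        with pytest.raises(BelParseError, match="line 1"):
            parse_document("garbage line", strict=True)

    def test_line_accounting_conserves_input(self, small_dataset):
        text = small_dataset.bel_text + "\nbroken line\n# comment\n"
        doc = parse_document(text)
        n_statements, n_errors, n_other = doc.line_counts
        assert n_statements + n_errors + n_other == len(text.splitlines())
        assert n_statements == len(doc.statements)
        assert n_errors == 1


class TestNormalization:
    @pytest.mark.parametrize("name", ["hemin", "Hematin", "HEME"])
    def test_heme_synonyms_unify(self, name):
        term = BelTerm(function="abundance", namespace="TEXT", name=name)
        normalized = normalize_entity(term)
        assert (normalized.namespace, normalized.name) == ("CHEBI", "heme")

    @pytest.mark.parametrize("name", ["heme arginate", "Heme-Albumin"])
    def test_formulations_excluded(self, name):
        term = BelTerm(function="abundance", namespace="TEXT", name=name)
        assert normalize_entity(term) is EXCLUDED

    def test_identity_for_other_terms(self):
        term = BelTerm(function="protein", namespace="HGNC", name="F8")
        assert normalize_entity(term) == term

    def test_idempotent(self):
        term = BelTerm(function="abundance", namespace="TEXT", name="hemin")
        once = normalize_entity(term)
        assert normalize_entity(once) == once

    def test_document_normalization_drops_blocklisted_statements(self):
        text = (
            'a(TEXT:hemin) -> p(HGNC:VWF)\n'
            'a(TEXT:"heme arginate") -> p(HGNC:VWF)\n'
            'complex(a(TEXT:"heme-albumin"), p(HGNC:ALB)) -> p(HGNC:VWF)\n'
        )
        doc, n_excluded = normalize_document(parse_document(text))
        assert n_excluded == 2
        [kept] = doc.statements
        assert kept.subject.name == "heme" and kept.subject.namespace == "CHEBI"


class TestAnnotationInvariants:
    def test_dose_requires_unit(self):
        with pytest.raises(ValueError):
            AnnotationSet(dose_value=10.0)

    def test_kd_positive(self):
        with pytest.raises(ValueError):
            AnnotationSet(kd_value=-1.0, kd_unit="nM")
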