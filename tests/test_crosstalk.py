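"""Superimposition, overlap statistics, gap reporting and export."""

import itertools
import math
import random

import pytest

from coagkg.bel_core import parse_statement
from coagkg.crosstalk import (
    CrosstalkResult,
    export_report,
    gap_report,
    overlap_test,
    superimpose,
)
from coagkg.kg_model import KnowledgeGraph
from coagkg.pathway_ingest import PathwayNetwork


def _kg_from_symbols(symbols, named=()):
    kg = KnowledgeGraph()
    for i, symbol in enumerate(symbols):
        kg.add_statement(
            parse_statement(
                f"a(CHEBI:heme) -> p(HGNC:{symbol})", citation=str(100 + i)
            )
        )
    for i, name in enumerate(named):
        kg.add_statement(
            parse_statement(
                f'a(CHEBI:heme) -> a(TEXT:"{name}")', citation=str(500 + i)
            )
        )
    return kg


def _net_from_symbols(symbols, named=(), accession="R-HSA-1"):
    net = PathwayNetwork(pathway_ids=[("Reactome", accession)])
    for symbol in symbols:
        net.add_node(symbol, "protein", accession=accession)
    for name in named:
        net.add_node(name, "metabolite", accession=accession)
    return net


class TestSuperimpose:
    def test_disjoint_networks_share_nothing(self):
        result = superimpose(_kg_from_symbols(["F8"]), _net_from_symbols(["F10"]))
        assert result.common == set()
        assert result.kg_only == {"F8", "heme"}
        assert result.pathway_only == {"F10"}

    def test_partition_property(self):
        kg = _kg_from_symbols(["F8", "VWF"], named=["fibrin"])
        net = _net_from_symbols(["F8", "F10"], named=["fibrin"])
        result = superimpose(kg, net)
        union = result.all_symbols()
        assert result.common | result.kg_only | result.pathway_only == union
        assert not result.common & result.kg_only
        assert not result.common & result.pathway_only
        assert not result.kg_only & result.pathway_only

    def test_complex_components_are_overlap_eligible(self):
        kg = KnowledgeGraph()
        kg.add_statement(
            parse_statement(
                "complex(a(CHEBI:heme), p(HGNC:PROC)) =| act(p(HGNC:PROC))",
                citation="1",
            )
        )
        result = superimpose(kg, _net_from_symbols(["PROC", "F5"]))
        assert "PROC" in result.common

    def test_alias_matching_unifies_common_names(self):
        # curated "fibrinogen" abundance should meet the pathway's FGA
        kg = _kg_from_symbols([], named=["fibrinogen"])
        result = superimpose(kg, _net_from_symbols(["FGA"]))
        assert result.common == {"FGA"}

    def test_compartment_restriction_requires_table(self):
        with pytest.raises(ValueError, match="LocalizationTable"):
            superimpose(
                _kg_from_symbols(["F8"]),
                _net_from_symbols(["F8"]),
                compartment="extracellular",
            )

    def test_node_sizes_reflect_evidence(self):
        kg = KnowledgeGraph()
        for citation in ("1", "2", "3"):
            kg.add_statement(
                parse_statement("a(CHEBI:heme) -> p(HGNC:VWF)", citation=citation)
            )
        result = superimpose(kg, _net_from_symbols(["VWF", "F10"]))
        assert result.node_sizes["VWF"] == 4.0  # 1 + three statements
        assert result.node_sizes["F10"] == 1.0  # zero-evidence floor

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_brute_force_intersection(self, seed):
        rng = random.Random(seed)
        vocabulary = [f"G{i}" for i in range(12)]
        kg_symbols = rng.sample(vocabulary, rng.randint(0, 8))
        net_symbols = rng.sample(vocabulary, rng.randint(1, 8))
        result = superimpose(
            _kg_from_symbols(kg_symbols), _net_from_symbols(net_symbols)
        )
        expected_common = set(kg_symbols) & set(net_symbols)
        assert result.common == expected_common


def _enumerated_upper_tail(m, big_k, n, k):
    """Exhaustive-enumeration oracle: P(overlap >= k) drawing n from m."""
    universe = list(range(m))
    marked = set(universe[:big_k])
    total = 0
    hits = 0
    for draw in itertools.combinations(universe, n):
        total += 1
        if len(marked & set(draw)) >= k:
            hits += 1
    return hits / total if total else 1.0


class TestOverlapTest:
    def _result(self, common, kg_only, pathway_only):
        return CrosstalkResult(
            compartment="all",
            common={f"C{i}" for i in range(common)},
            kg_only={f"K{i}" for i in range(kg_only)},
            pathway_only={f"P{i}" for i in range(pathway_only)},
            node_sizes={},
            universe_size=0,
        )

    def test_zero_overlap_is_certain(self):
        assert overlap_test(self._result(0, 3, 3), 10) == 1.0

    def test_exact_small_case(self):
        # all five pathway members land on the five marked: 1 / C(10,5)
        p = overlap_test(self._result(5, 0, 0), 10)
        assert math.isclose(p, 1 / 252, rel_tol=0, abs_tol=1e-15)

    def test_monotone_in_overlap(self):
        previous = 1.1
        for k in range(0, 5):
            p = overlap_test(self._result(k, 4 - k + 2, 4 - k), 30)
            assert p <= previous + 1e-12
            previous = p

    def test_infeasible_counts_rejected(self):
        with pytest.raises(ValueError, match="infeasible"):
            overlap_test(self._result(2, 5, 5), 5)

    def test_matches_enumeration_on_small_universes(self):
        for m in range(1, 9):
            for big_k in range(0, m + 1):
                for n in range(0, m + 1):
                    k = min(big_k, n)
                    if k < max(0, big_k + n - m):
                        continue
                    result = self._result(k, big_k - k, n - k)
                    expected = _enumerated_upper_tail(m, big_k, n, k)
                    assert abs(overlap_test(result, m) - expected) < 1e-12


class TestGapReport:
    def test_empty(self):
        result = CrosstalkResult(
            compartment="all", common={"A"}, kg_only=set(), pathway_only=set(),
            node_sizes={}, universe_size=1,
        )
        assert gap_report(result).empty

    def test_gap_targets_listed(self):
        kg = _kg_from_symbols(["F3"])
        net = _net_from_symbols(["F3", "F10", "F11"])
        report = gap_report(superimpose(kg, net))
        assert list(report["symbol"]) == ["F10", "F11"]
        assert set(report["literature_status"]) == {"not_screened"}

    def test_screened_status_attached(self):
        kg = _kg_from_symbols(["F3"])
        net = _net_from_symbols(["F3", "F10"])
        report = gap_report(
            superimpose(kg, net),
            screened={"F10": "screened_negative", "SRC": "screened_positive_external_celltype"},
        )
        status = dict(zip(report["symbol"], report["literature_status"]))
        assert status["F10"] == "screened_negative"
        # screened-positive entries are appended even outside pathway_only
        assert status["SRC"] == "screened_positive_external_celltype"

    def test_sorted_by_pathway_count_then_symbol(self):
        net_a = _net_from_symbols(["F10", "F11"], accession="R-HSA-1")
        net_b = _net_from_symbols(["F11"], accession="R-HSA-2")
        from coagkg.pathway_ingest import combine

        report = gap_report(superimpose(_kg_from_symbols([]), combine([net_a, net_b])))
        assert list(report["symbol"]) == ["F11", "F10"]

    def test_planted_gap_count(self, small_dataset, tmp_path):
        from coagkg.kg_model import compile_documents
        from coagkg.pathway_ingest import load_pathway

        kg = compile_documents(small_dataset.documents)
        for name, text in small_dataset.pathway_files.items():
            path = tmp_path / name
            path.write_text(text)
            net = load_pathway(path, accession=path.stem)
            info = small_dataset.truth.pathways[path.stem]
            report = gap_report(superimpose(kg, net))
            planted_gaps = info["members"] - info["shared"]
            assert set(report["symbol"]) == planted_gaps


class TestExport:
    def test_row_conservation_and_determinism(self, tmp_path):
        kg = _kg_from_symbols(["F8", "VWF"], named=["fibrin"])
        net = _net_from_symbols(["F8", "F10"], named=["fibrin"])
        result = superimpose(kg, net)
        first = export_report(result, tmp_path / "run1")
        second = export_report(result, tmp_path / "run2")
        overlap_rows = (tmp_path / "run1" / "overlap.tsv").read_text().splitlines()
        assert len(overlap_rows) - 1 == len(result.all_symbols())
        for name in ("overlap", "gaps", "overlay"):
            assert first[name].read_bytes() == second[name].read_bytes()

    def test_empty_result_yields_header_only(self, tmp_path):
        result = CrosstalkResult(
            compartment="all", common=set(), kg_only=set(), pathway_only=set(),
            node_sizes={}, universe_size=0,
        )
        paths = export_report(result, tmp_path)
        assert paths["overlap"].read_text().splitlines() == [
            "symbol\tmembership\tcompartment\tsize\tpathways"
        ]
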