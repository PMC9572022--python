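"""Pathway export loading, identifier normalization and combination."""

import pytest

from coagkg.pathway_ingest import (
    PathwayNetwork,
    SymbolMap,
    combine,
    infer_source_db,
    load_gmt,
    load_pathway,
    load_tsv_edgelist,
    normalize_identifiers,
)


class TestLoaders:
    def test_minimal_edgelist(self, tmp_path):
        path = tmp_path / "mini.tsv"
        path.write_text("A\tinteracts\tB\nB\tactivates\tC\n")
        net = load_tsv_edgelist(path)
        assert len(net.nodes) == 3
        assert net.edges == {("A", "interacts", "B"), ("B", "activates", "C")}

    def test_entity_classes_from_five_column_rows(self, tmp_path):
        path = tmp_path / "p.tsv"
        path.write_text(
            "source\tinteraction\ttarget\tsource_class\ttarget_class\n"
            "FGA\tconversion\tfibrin\tprotein\tmetabolite\n"
        )
        net = load_tsv_edgelist(path)
        assert net.nodes["FGA"][0] == "protein"
        assert net.nodes["fibrin"][0] == "metabolite"

    def test_gmt_membership_only(self, tmp_path):
        path = tmp_path / "sets.gmt"
        path.write_text("R-HSA-140834\textrinsic\tF3\tF7\n")
        net = load_gmt(path)
        assert set(net.nodes) == {"F3", "F7"}
        assert net.edges == set()
        assert net.membership["F3"] == {"R-HSA-140834"}
        assert net.pathway_ids == [("Reactome", "R-HSA-140834")]

    def test_malformed_row_reports_line(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("A\tinteracts\tB\nA\tB\n")
        with pytest.raises(ValueError, match=":2"):
            load_tsv_edgelist(path)

    def test_empty_file_warns(self, tmp_path):
        path = tmp_path / "empty.tsv"
        path.write_text("")
        with pytest.warns(UserWarning, match="empty"):
            net = load_pathway(path, format="tsv_edgelist")
        assert not net.nodes

    def test_planted_sizes_recovered(self, small_dataset, tmp_path):
        for name, text in small_dataset.pathway_files.items():
            path = tmp_path / name
            path.write_text(text)
            accession = path.stem
            net = load_pathway(path, accession=accession)
            info = small_dataset.truth.pathways[accession]
            assert set(net.nodes) == info["members"]
            assert len(net.edges) == info["n_edges"]

    @pytest.mark.parametrize(
        "accession,db",
        [("R-HSA-140837", "Reactome"), ("HSA04611", "KEGG"), ("WP272", "WikiPathways")],
    )
    def test_source_db_inference(self, accession, db):
        assert infer_source_db(accession) == db


class TestNormalizeIdentifiers:
    @pytest.fixture()
    def symbol_map(self, tmp_path):
        path = tmp_path / "map.tsv"
        path.write_text(
            "namespace\tid\tsymbol\n"
            "UNIPROT\tP00451\tF8\n"
            "UNIPROT\tP04275\tVWF\n"
            "KEGG\thsa:2147\tF2\n"
        )
        return SymbolMap.from_tsv(path)

    def test_uniprot_lookup(self, symbol_map):
        assert symbol_map.lookup("UNIPROT:P00451") == "F8"
        assert symbol_map.lookup("P00451") == "F8"

    def test_identity_map_leaves_network_unchanged(self, symbol_map):
        net = PathwayNetwork()
        net.add_node("F8")
        net.add_node("VWF")
        net.add_edge("F8", "binding", "VWF")
        out = normalize_identifiers(net, symbol_map)
        assert set(out.nodes) == {"F8", "VWF"}
        assert out.edges == net.edges

    def test_coalescing_nodes_rewires_without_self_loops(self, tmp_path):
        path = tmp_path / "map.tsv"
        path.write_text(
            "namespace\tid\tsymbol\nUNIPROT\tQ1\tF8\nUNIPROT\tQ2\tF8\n"
        )
        symbol_map = SymbolMap.from_tsv(path)
        net = PathwayNetwork()
        net.add_node("UNIPROT:Q1")
        net.add_node("UNIPROT:Q2")
        net.add_node("VWF")
        net.add_edge("UNIPROT:Q1", "binding", "UNIPROT:Q2")
        net.add_edge("UNIPROT:Q2", "binding", "VWF")
        out = normalize_identifiers(net, symbol_map)
        assert set(out.nodes) == {"F8", "VWF"}
        assert out.edges == {("F8", "binding", "VWF")}

    def test_unmapped_ids_prefixed(self, symbol_map):
        net = PathwayNetwork()
        net.add_node("UNIPROT:P99999")
        out = normalize_identifiers(net, symbol_map)
        assert set(out.nodes) == {"unmapped:UNIPROT:P99999"}

    def test_duplicate_map_keys_rejected(self, tmp_path):
        path = tmp_path / "dup.tsv"
        path.write_text("namespace\tid\tsymbol\nU\tX\tA\nU\tX\tB\n")
        with pytest.raises(ValueError, match="duplicate"):
            SymbolMap.from_tsv(path)


class TestCombine:
    def _net(self, nodes, edges=(), accession="R-HSA-1"):
        net = PathwayNetwork(pathway_ids=[("Reactome", accession)])
        for n in nodes:
            net.add_node(n, accession=accession)
        for e in edges:
            net.add_edge(*e)
        return net

    def test_single_identity(self):
        net = self._net(["A", "B"], [("A", "binding", "B")])
        out = combine([net])
        assert set(out.nodes) == set(net.nodes) and out.edges == net.edges

    def test_disjoint_sizes_add(self):
        a = self._net(["A", "B"], [("A", "binding", "B")], "R-HSA-1")
        b = self._net(["C", "D"], [("C", "binding", "D")], "R-HSA-2")
        out = combine([a, b])
        assert len(out.nodes) == 4 and len(out.edges) == 2

    def test_order_invariant_and_associative(self):
        a = self._net(["A", "B"], [("A", "binding", "B")], "R-HSA-1")
        b = self._net(["B", "C"], [("B", "binding", "C")], "R-HSA-2")
        c = self._net(["C", "A"], [("C", "binding", "A")], "R-HSA-3")
        left = combine([combine([a, b]), c])
        right = combine([a, combine([b, c])])
        flipped = combine([c, b, a])
        for out in (right, flipped):
            assert set(left.nodes) == set(out.nodes)
            assert left.edges == out.edges

    def test_planted_union_size(self, small_dataset, tmp_path):
        nets = []
        for name, text in small_dataset.pathway_files.items():
            path = tmp_path / name
            path.write_text(text)
            nets.append(load_pathway(path, accession=path.stem))
        out = combine(nets)
        expected = set().union(
            *(info["members"] for info in small_dataset.truth.pathways.values())
        )
        assert set(out.nodes) == expected
        # every edge endpoint resolvable after combine
        for s, _, t in out.edges:
            assert s in out.nodes and t in out.nodes
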