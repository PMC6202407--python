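"""Tests for interaction parsing, DEG selection and network construction."""

import json

import pandas as pd
import pytest

import degnet
from degnet.errors import DomainError, FormatError
from degnet.enrichment import GeneSet


@pytest.fixture()
def sif(tmp_path):
    path = tmp_path / "edges.sif"
    path.write_text(
        "A\tactivation\tB\tKEGG\n"
        "B\trepression\tC\n"
        "C\tindirect_activation\tA\n"
        "A\tppi\tD\tBioGRID\n"
        "D\tppi\tA\tIntAct\n"       # same undirected edge, other orientation
        "E\tppi\tD\n"
        "A\tactivation\tB\tKEGG\n"  # exact duplicate
    )
    return path


class TestReadInteractions:
    def test_parse_types_and_dedup(self, sif):
        records = degnet.read_interactions(sif)
        keys = {(r.source, r.target, r.interaction) for r in records}
        assert ("A", "B", "activation") in keys
        assert ("C", "A", "indirect_activation") in keys
        # one undirected A-D ppi regardless of orientation and repetition
        assert ("A", "D", "ppi") in keys and ("D", "A", "ppi") not in keys
        assert len(records) == 5

    def test_space_separated_sif_accepted(self, tmp_path):
        path = tmp_path / "sp.sif"
        path.write_text("A activation B\n")
        (rec,) = degnet.read_interactions(path)
        assert (rec.source, rec.interaction, rec.target) == \
            ("A", "activation", "B")

    def test_unknown_type_reports_line(self, tmp_path):
        path = tmp_path / "bad.sif"
        path.write_text("A\tactivation\tB\nA\tbinds\tB\n")
        with pytest.raises(FormatError, match=":2:"):
            degnet.read_interactions(path)

    def test_short_line_rejected(self, tmp_path):
        path = tmp_path / "short.sif"
        path.write_text("A\tactivation\n")
        with pytest.raises(FormatError, match=":1:"):
            degnet.read_interactions(path)


class TestBuildNetwork:
    def test_induced_subgraph_semantics(self, sif):
        records = degnet.read_interactions(sif)
        net = degnet.build_network(["A", "B"], records)
        assert net.nodes == ["A", "B"]
        assert net.edges == [("A", "B", "activation")]

    def test_isolated_nodes_retained(self, sif):
        records = degnet.read_interactions(sif)
        net = degnet.build_network(["A", "B", "Z"], records)
        assert "Z" in net.nodes

    def test_enumerated_fixture_oracle(self, sif):
        records = degnet.read_interactions(sif)
        genes = ["A", "B", "C", "D"]
        net = degnet.build_network(genes, records)
        expected = {(r.source, r.target, r.interaction) for r in records
                    if r.source in genes and r.target in genes}
        assert set(net.edges) == expected
        # induced-subgraph property: no edge endpoint outside the gene list
        assert all(u in genes and v in genes for u, v, _ in net.edges)

    def test_node_annotations(self, sif, design2):
        m, _ = degnet.simulate_dataset(50, design2, seed=0)
        m = m.rename(index={m.index[0]: "A", m.index[1]: "B"})
        stats = {"test": degnet.run_contrast(
            m, design2, degnet.Contrast("test", "MEF"))}
        net = degnet.build_network(
            ["A", "B"], degnet.read_interactions(sif), stats,
            pathway_of={"A": "Wnt signaling pathway"})
        attrs = net.graph.nodes["A"]
        assert attrs["log2fc_test"] == pytest.approx(
            stats["test"].loc["A", "log2fc"])
        assert attrs["pathway"] == "Wnt signaling pathway"

    def test_empty_gene_list_rejected(self):
        with pytest.raises(DomainError):
            degnet.build_network([], [])


class TestExport:
    @pytest.fixture()
    def model(self, sif):
        records = degnet.read_interactions(sif)
        return degnet.build_network(["A", "B", "C", "D", "E"], records)

    def test_graphml_round_trip_identity(self, model, tmp_path):
        path = tmp_path / "net.graphml"
        degnet.export_network(model, path)
        back = degnet.import_graphml(path)
        assert set(back.nodes) == set(model.nodes)
        assert set(back.edges) == set(model.edges)
        for u, v, k in model.edges:
            assert (back.graph.edges[u, v, k]["interaction"]
                    == model.graph.edges[u, v, k]["interaction"])

    def test_graphml_byte_deterministic(self, model, sif, tmp_path):
        p1, p2 = tmp_path / "a.graphml", tmp_path / "b.graphml"
        degnet.export_network(model, p1)
        rebuilt = degnet.build_network(
            ["E", "D", "C", "B", "A"], degnet.read_interactions(sif))
        degnet.export_network(rebuilt, p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_sif_line_count_equals_edges(self, model, tmp_path):
        path = tmp_path / "net.sif"
        degnet.export_network(model, path)
        lines = path.read_text().strip().splitlines()
        assert len(lines) == len(model.edges)

    def test_json_round_trip_and_schema(self, model, tmp_path):
        path = tmp_path / "net.json"
        degnet.export_network(model, path)
        obj = json.loads(path.read_text())
        degnet.validate_network_json(obj)  # raises on violation
        back = degnet.network_from_json(obj)
        assert set(back.nodes) == set(model.nodes)
        assert set(back.edges) == set(model.edges)

    def test_unknown_format_rejected(self, model, tmp_path):
        with pytest.raises(FormatError):
            degnet.export_network(model, tmp_path / "net.xyz")

    def test_invalid_json_rejected(self):
        with pytest.raises(FormatError):
            degnet.validate_network_json(
                {"nodes": [{"id": "A"}],
                 "edges": [{"source": "A", "target": "Q",
                            "interaction": "ppi"}]})


class TestSelectProcessDegs:
    def test_set_algebra_oracle(self):
        genes = [f"g{i}" for i in range(12)]
        patterns = pd.DataFrame({"group": ["G1"] * 12},
                                index=pd.Index(genes, name="gene"))
        cellcycle = GeneSet("cell cycle", "", frozenset(
            g.upper() for g in genes[:6]))
        collection = degnet.GeneSetCollection((cellcycle,))
        enrichment = pd.DataFrame({"term_id": ["cell cycle"],
                                   "ease_p": [0.01], "enriched": [True]})
        membership = pd.DataFrame({
            "gene": genes[3:9],
            "pathway": ["Wnt signaling pathway"] * 3 + ["unlisted"] * 3,
        })
        out = degnet.select_process_degs(patterns, enrichment, collection,
                                         ["cell cycle"], membership)
        # conjunctive rule by hand: DE & in process (0-5) & in Wnt (3-5)
        assert out == ["g3", "g4", "g5"]

    def test_missing_process_term_rejected(self):
        patterns = pd.DataFrame({"group": []},
                                index=pd.Index([], name="gene"))
        with pytest.raises(DomainError):
            degnet.select_process_degs(
                patterns, pd.DataFrame({"term_id": []}),
                degnet.GeneSetCollection(()), ["nope"],
                pd.DataFrame({"gene": [], "pathway": []}))
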