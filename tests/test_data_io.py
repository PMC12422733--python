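import numpy as np
import pandas as pd
import pytest

import teconet as tc
from teconet.data_io import (
    read_edges,
    validate_annotation,
    validate_ortholog_map,
    write_count_matrix,
    write_evidence_pairs,
)
from teconet.network import BipartiteNetwork


def _write(tmp_path, name, text):
    path = tmp_path / name
    path.write_text(text)
    return path


COUNTS = "feature_id\ts1\ts2\ngeneA\t1\t2\nAluY\t0\t5\nL1MA6\t7\t3\n"
META = (
    "sample_id\tspecies\tindividual\tgroup\tcondition\n"
    "s1\thuman\ti1\tcortex\tcontrol\n"
    "s2\thuman\ti2\tcortex\tcontrol\n"
)


class TestReadCountMatrix:
    def test_round_trip_preserves_content_and_order(self, tmp_path):
        m = tc.read_count_matrix(
            _write(tmp_path, "c.tsv", COUNTS), _write(tmp_path, "m.tsv", META)
        )
        assert m.shape == (3, 2)
        assert m.feature_ids == ["geneA", "AluY", "L1MA6"]
        write_count_matrix(m, tmp_path / "out.tsv", tmp_path / "outm.tsv")
        again = tc.read_count_matrix(tmp_path / "out.tsv", tmp_path / "outm.tsv")
        pd.testing.assert_frame_equal(m.counts, again.counts)

    def test_duplicate_feature_id_is_named_in_error(self, tmp_path):
        bad = COUNTS + "AluY\t1\t1\n"
        with pytest.raises(ValueError, match="AluY"):
            tc.read_count_matrix(
                _write(tmp_path, "c.tsv", bad), _write(tmp_path, "m.tsv", META)
            )

    @pytest.mark.parametrize("cell", ["-1", "2.5", "NA"])
    def test_bad_cell_raises_with_location(self, tmp_path, cell):
        bad = COUNTS.replace("geneA\t1\t2", f"geneA\t1\t{cell}")
        with pytest.raises(ValueError, match="geneA"):
            tc.read_count_matrix(
                _write(tmp_path, "c.tsv", bad), _write(tmp_path, "m.tsv", META)
            )

    def test_sample_missing_from_metadata(self, tmp_path):
        meta = META.replace("s2\thuman\ti2\tcortex\tcontrol\n", "")
        with pytest.raises(ValueError, match="s2"):
            tc.read_count_matrix(
                _write(tmp_path, "c.tsv", COUNTS),
                _write(tmp_path, "m.tsv", meta),
            )


def _ann(**overrides):
    base = dict(
        kind=["gene", "TE"],
        te_class=["", "SINE"],
        is_krab_znf=[True, False],
        length_bp=[2000, 300],
        age_mya=[50.0, 10.0],
    )
    base.update(overrides)
    return pd.DataFrame(base, index=pd.Index(["ZNF91", "AluY"], name="feature_id"))


class TestAnnotation:
    def test_valid_table_passes(self):
        ann = validate_annotation(_ann())
        assert ann.loc["AluY", "te_class"] == "SINE"

    def test_gene_with_te_class_rejected(self):
        with pytest.raises(ValueError, match="ZNF91"):
            validate_annotation(_ann(te_class=["SINE", "SINE"]))

    def test_te_flagged_krab_znf_rejected(self):
        with pytest.raises(ValueError, match="AluY"):
            validate_annotation(_ann(is_krab_znf=[True, True]))

    def test_bad_length_and_age(self):
        with pytest.raises(ValueError, match="length_bp"):
            validate_annotation(_ann(length_bp=[0, 300]))
        with pytest.raises(ValueError, match="age_mya"):
            validate_annotation(_ann(age_mya=[-1.0, 10.0]))

    def test_missing_age_permitted(self):
        ann = validate_annotation(_ann(age_mya=[np.nan, 10.0]))
        assert np.isnan(ann.loc["ZNF91", "age_mya"])


class TestOrthologMap:
    def test_one_to_one_enforced(self):
        om = pd.DataFrame(
            {
                "feature_id_a": ["g1", "g1"],
                "feature_id_b": ["h1", "h2"],
                "length_a_bp": [100, 100],
                "length_b_bp": [100, 100],
                "confidence": ["high", "high"],
            }
        )
        with pytest.raises(ValueError, match="g1"):
            validate_ortholog_map(om)

    def test_confidence_vocabulary(self):
        om = pd.DataFrame(
            {
                "feature_id_a": ["g1"],
                "feature_id_b": ["h1"],
                "length_a_bp": [100],
                "length_b_bp": [100],
                "confidence": ["maybe"],
            }
        )
        with pytest.raises(ValueError, match="confidence"):
            validate_ortholog_map(om)


class TestEvidencePairs:
    def test_round_trip(self, tmp_path):
        pairs = {("ZNF91", "AluY"), ("ZNF91", "L1MA6")}
        write_evidence_pairs(pairs, tmp_path / "e.tsv")
        assert tc.read_evidence_pairs(tmp_path / "e.tsv") == pairs

    def test_duplicates_rejected(self, tmp_path):
        (tmp_path / "e.tsv").write_text(
            "gene_id\tte_id\nZNF91\tAluY\nZNF91\tAluY\n"
        )
        with pytest.raises(ValueError, match="duplicate"):
            tc.read_evidence_pairs(tmp_path / "e.tsv")


class TestEdgeExport:
    def _network(self, n_edges):
        genes = {"ZNF91", "ZNF92"}
        tes = {"AluY", "L1MA6"}
        all_edges = [
            ("ZNF91", "AluY", {"r": 0.5, "padj": 0.001, "link_class": "P-Y"}),
            ("ZNF92", "L1MA6", {"r": -0.6, "padj": 0.002, "link_class": "N-O"}),
        ]
        return BipartiteNetwork(genes, tes, all_edges[:n_edges])

    def test_two_edge_network_round_trip(self, tmp_path):
        net = self._network(2)
        tc.write_edges(net, tmp_path / "edges.tsv", tmp_path / "net.graphml")
        back = read_edges(tmp_path / "edges.tsv")
        assert len(back) == 2
        assert set(zip(back["gene_id"], back["te_id"])) == {
            (g, t) for g, t, _ in net.edges()
        }
        import networkx as nx

        g = nx.read_graphml(tmp_path / "net.graphml")
        assert g.number_of_edges() == 2

    def test_empty_network(self, tmp_path):
        net = self._network(0)
        tc.write_edges(net, tmp_path / "edges.tsv", tmp_path / "net.graphml")
        back = read_edges(tmp_path / "edges.tsv")
        assert len(back) == 0
        import networkx as nx

        assert nx.read_graphml(tmp_path / "net.graphml").number_of_edges() == 0


class TestCountMatrix:
    def test_library_sizes_prefers_metadata(self, tiny_matrix):
        assert (
            tiny_matrix.library_sizes() == tiny_matrix.counts.sum(axis=0)
        ).all()
        meta = tiny_matrix.meta.copy()
        meta["lib_size"] = 1e6
        m = tc.CountMatrix(tiny_matrix.counts, meta)
        assert (m.library_sizes() == 1e6).all()

    def test_samples_where(self, tiny_matrix):
        assert tiny_matrix.samples_where(condition="case") == ["b1", "b2"]
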