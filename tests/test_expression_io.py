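import numpy as np
import pandas as pd
import pytest

from iescape import (
    ExpressionMatrix,
    collapse_probes,
    read_expression,
    read_gmt,
    write_expression,
    write_gmt,
)
from iescape.io import ExpressionFormatError, GeneSet, builtin_gene_sets


@pytest.fixture
def tiny(tmp_path):
    df = pd.DataFrame(
        {"A": [1.5, 2.25, -0.125], "B": [0.1, 7.0, 3.3]},
        index=["CD274", "LAG3", "PDCD1"],
    )
    return ExpressionMatrix(df), tmp_path


class TestMatrixRoundTrip:
    @pytest.mark.parametrize("fmt", ["gct", "tsv"])
    def test_write_read_identity(self, tiny, fmt):
        m, tmp = tiny
        p = tmp / f"m.{fmt}"
        write_expression(m, p, fmt=fmt)
        back = read_expression(p, fmt=fmt)
        assert back.gene_symbols == m.gene_symbols
        assert back.sample_ids == m.sample_ids
        np.testing.assert_array_equal(back.values, m.values)

    @pytest.mark.parametrize("fmt", ["gct", "tsv"])
    def test_double_round_trip_idempotent(self, tiny, fmt):
        m, tmp = tiny
        p1, p2 = tmp / f"a.{fmt}", tmp / f"b.{fmt}"
        write_expression(m, p1, fmt=fmt)
        write_expression(read_expression(p1, fmt=fmt), p2, fmt=fmt)
        assert p1.read_bytes() == p2.read_bytes()


class TestGctContract:
    def test_dims_mismatch_rejected(self, tmp_path):
        p = tmp_path / "bad.gct"
        rows = "\n".join(f"g{i}\tna\t1\t2" for i in range(3))
        p.write_text(f"#1.2\n2\t2\nName\tDescription\ts1\ts2\n{rows}\n")
        with pytest.raises(ExpressionFormatError, match="declared 2 data rows"):
            read_expression(p, fmt="gct")

    def test_missing_version_header(self, tmp_path):
        p = tmp_path / "bad.gct"
        p.write_text("2\t1\nName\tDescription\ts1\ng1\tna\t1\ng2\tna\t2\n")
        with pytest.raises(ExpressionFormatError, match="#1.2"):
            read_expression(p, fmt="gct")

    def test_non_numeric_cell_located(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("gene\ts1\ns1gene\t1.0\nCD8A\toops\n")
        with pytest.raises(ExpressionFormatError, match="row 2, column 1"):
            read_expression(p, fmt="tsv")


class TestDuplicateGenes:
    def _dup_tsv(self, tmp_path):
        p = tmp_path / "dup.tsv"
        # CD274 probe 1 mean 2.0, probe 2 mean 5.0
        p.write_text(
            "gene\ts1\ts2\nCD274\t1.0\t3.0\nCD274\t4.0\t6.0\nLAG3\t0.0\t1.0\n"
        )
        return p

    def test_rejected_without_flag(self, tmp_path):
        with pytest.raises(ValueError, match="duplicate gene symbols"):
            read_expression(self._dup_tsv(tmp_path), fmt="tsv")

    def test_max_mean_keeps_higher_mean_probe(self, tmp_path):
        m = read_expression(self._dup_tsv(tmp_path), fmt="tsv", collapse="max_mean")
        assert list(m.data.loc["CD274"]) == [4.0, 6.0]

    def test_mean_averages_probes(self, tmp_path):
        m = read_expression(self._dup_tsv(tmp_path), fmt="tsv", collapse="mean")
        assert list(m.data.loc["CD274"]) == [2.5, 4.5]


class TestCollapseProbes:
    def test_max_mean_keeps_most_intense_probe(self):
        m = ExpressionMatrix(
            pd.DataFrame({"s1": [4.0, 6.0, 0.0], "s2": [6.0, 8.0, 1.0]},
                         index=["p1", "p2", "p3"])
        )
        out = collapse_probes(
            m, {"p1": "G1", "p2": "G1", "p3": "G2"}, method="max_mean"
        )
        assert out.gene_symbols == ["G1", "G2"]
        assert list(out.data.loc["G1"]) == [6.0, 8.0]

    def test_mean_averages(self):
        m = ExpressionMatrix(
            pd.DataFrame({"s1": [2.0, 4.0, 0.0], "s2": [4.0, 6.0, 1.0]},
                         index=["p1", "p2", "p3"])
        )
        out = collapse_probes(
            m, {"p1": "G1", "p2": "G1", "p3": "G2"}, method="mean"
        )
        assert list(out.data.loc["G1"]) == [3.0, 5.0]

    @pytest.mark.parametrize("method", ["max_mean", "mean"])
    def test_one_probe_per_gene_is_renaming(self, method):
        m = ExpressionMatrix(
            pd.DataFrame({"s1": [1.0, 2.0], "s2": [3.0, 4.0]}, index=["p1", "p2"])
        )
        out = collapse_probes(m, {"p1": "GA", "p2": "GB"}, method=method)
        assert out.gene_symbols == ["GA", "GB"]
        np.testing.assert_array_equal(out.values, m.values)

    def test_gene_count_equals_distinct_mapped_symbols(self):
        rng = np.random.default_rng(0)
        probes = [f"p{i}" for i in range(20)]
        mapping = {p: f"G{i % 7}" for i, p in enumerate(probes)}
        m = ExpressionMatrix(
            pd.DataFrame(rng.normal(size=(20, 3)), index=probes,
                         columns=["a", "b", "c"])
        )
        out = collapse_probes(m, mapping)
        assert out.n_genes == 7

    def test_mean_commutes_with_sample_subsetting(self):
        rng = np.random.default_rng(1)
        probes = [f"p{i}" for i in range(12)]
        mapping = {p: f"G{i % 4}" for i, p in enumerate(probes)}
        m = ExpressionMatrix(
            pd.DataFrame(rng.normal(size=(12, 4)), index=probes,
                         columns=list("abcd"))
        )
        collapsed_then_subset = collapse_probes(m, mapping, "mean").subset_samples(
            ["b", "d"]
        )
        subset_then_collapsed = collapse_probes(
            m.subset_samples(["b", "d"]), mapping, "mean"
        )
        pd.testing.assert_frame_equal(
            collapsed_then_subset.data, subset_then_collapsed.data
        )

    def test_empty_mapping_and_all_unmapped(self):
        m = ExpressionMatrix(
            pd.DataFrame({"s1": [1.0, 2.0]}, index=["p1", "p2"])
        )
        with pytest.raises(ValueError, match="empty"):
            collapse_probes(m, {})
        with pytest.raises(ValueError, match="no probe"):
            collapse_probes(m, {"other": "G1"})


class TestGmt:
    def test_direct_parse(self, tmp_path):
        p = tmp_path / "s.gmt"
        p.write_text("IEGS33\tdesc\tCTLA4\tPDCD1\tLAG3\n")
        sets = read_gmt(p)
        assert len(sets) == 1
        assert sets[0].name == "IEGS33"
        assert sets[0].genes == {"CTLA4", "PDCD1", "LAG3"}

    def test_duplicate_gene_counted_once(self, tmp_path, caplog):
        p = tmp_path / "s.gmt"
        p.write_text("SET\tdesc\tCD274\tCD274\tLAG3\n")
        with caplog.at_level("WARNING", logger="iescape"):
            sets = read_gmt(p)
        assert len(sets[0]) == 2
        assert "duplicate" in caplog.text

    def test_empty_file_warns(self, tmp_path, caplog):
        p = tmp_path / "empty.gmt"
        p.write_text("")
        with caplog.at_level("WARNING", logger="iescape"):
            assert read_gmt(p) == []
        assert "no gene sets" in caplog.text

    def test_short_line_names_line_number(self, tmp_path):
        p = tmp_path / "s.gmt"
        p.write_text("OK\tdesc\tCD4\nBROKEN\tdesc\n")
        with pytest.raises(ExpressionFormatError, match="line 2"):
            read_gmt(p)

    def test_round_trip(self, tmp_path):
        sets = [GeneSet("A", frozenset(["x", "y"])), GeneSet("B", frozenset(["z"]))]
        p = tmp_path / "rt.gmt"
        write_gmt(sets, p)
        back = {s.name: s.genes for s in read_gmt(p)}
        assert back == {"A": {"x", "y"}, "B": {"z"}}


def test_builtin_sets_have_published_anchor_genes():
    sets = builtin_gene_sets()
    assert {"CTLA4", "PDCD1", "LAG3", "CD274"} <= sets["IEGS33"].genes
    assert {"IL2", "CD28", "ZAP70", "LCK"} <= sets["TCELL_ACTIVATION"].genes


class TestExpressionMatrixInvariants:
    def test_rejects_nan(self):
        with pytest.raises(ValueError, match="non-finite"):
            ExpressionMatrix(
                pd.DataFrame({"s": [1.0, np.nan]}, index=["a", "b"])
            )

    def test_rejects_single_gene(self):
        with pytest.raises(ValueError, match=">=2 genes"):
            ExpressionMatrix(pd.DataFrame({"s": [1.0]}, index=["a"]))

    def test_rejects_duplicate_samples(self):
        df = pd.DataFrame([[1.0, 2.0], [3.0, 4.0]], index=["a", "b"],
                          columns=["s", "s"])
        with pytest.raises(ValueError, match="duplicate sample"):
            ExpressionMatrix(df)
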