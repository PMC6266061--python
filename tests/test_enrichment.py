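import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from iescape import (
    ExpressionMatrix,
    GeneSet,
    minmax_normalize,
    random_null,
    score_axes,
    ses_score,
)
from oracles import ses_running_sum


class TestSesWorkedExamples:
    def test_five_gene_example(self, ranked_matrix):
        """Set {g1, g3} on 5 strictly ranked genes: the running sum takes
        values (1/2, 1/6, 2/3, 1/3, 0), so the score is 5/3."""
        ses = ses_score(ranked_matrix, GeneSet("x", frozenset(["g1", "g3"])), 0.0)
        assert ses.scores.iloc[0] == pytest.approx(5 / 3, abs=1e-12)

    def test_two_gene_example(self):
        m = ExpressionMatrix(pd.DataFrame({"s": [2.0, 1.0]}, index=["g1", "g2"]))
        ses = ses_score(m, GeneSet("x", frozenset(["g1"])), 0.0)
        assert ses.scores.iloc[0] == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("exponent", [0.0, 0.25, 1.0])
    def test_constant_shift_invariance(self, random_matrix, exponent):
        """Scores are rank-based: adding a constant to one sample's column
        changes nothing."""
        gs = GeneSet("t", frozenset(["G000", "G007", "G033"]))
        before = ses_score(random_matrix, gs, exponent).scores
        shifted = random_matrix.data.copy()
        shifted["s3"] += 42.0
        after = ses_score(ExpressionMatrix(shifted), gs, exponent).scores
        pd.testing.assert_series_equal(before, after)


class TestSesOracle:
    @given(data=st.data())
    @settings(max_examples=120, deadline=None, derandomize=True)
    def test_exponent_zero_matches_running_sum_enumeration(self, data):
        """Exponent-0 SES equals the literal running-sum walk on random
        small instances (<= 8 genes, set size <= 4, tie-free)."""
        n_genes = data.draw(st.integers(3, 8))
        set_size = data.draw(st.integers(1, min(4, n_genes - 1)))
        values = data.draw(
            st.lists(
                st.floats(-10, 10, allow_nan=False),
                min_size=n_genes, max_size=n_genes, unique=True,
            )
        )
        genes = [f"g{i}" for i in range(n_genes)]
        members = set(genes[:set_size])
        m = ExpressionMatrix(pd.DataFrame({"s": values}, index=genes))
        got = ses_score(m, GeneSet("x", frozenset(members)), 0.0).scores.iloc[0]
        expected = ses_running_sum(dict(zip(genes, values)), members)
        assert got == pytest.approx(expected, abs=1e-9)

    def test_per_sample_locality(self, random_matrix):
        """Editing sample B's column never changes sample A's score."""
        gs = GeneSet("t", frozenset(["G001", "G020"]))
        before = ses_score(random_matrix, gs, 0.25).scores
        edited = random_matrix.data.copy()
        edited["s7"] = edited["s7"].to_numpy()[::-1]
        after = ses_score(ExpressionMatrix(edited), gs, 0.25).scores
        pd.testing.assert_series_equal(before.drop("s7"), after.drop("s7"))

    @pytest.mark.parametrize("exponent", [0.0, 0.25])
    def test_monotone_spiking_never_decreases_score(self, random_matrix, exponent):
        gs = GeneSet("t", frozenset(["G002", "G011", "G040"]))
        base = ses_score(random_matrix, gs, exponent).scores["s0"]
        spiked = random_matrix.data.copy()
        spiked.loc[list(gs.genes), "s0"] += 5.0
        after = ses_score(ExpressionMatrix(spiked), gs, exponent).scores["s0"]
        assert after >= base

    def test_error_on_no_overlap_and_full_cover(self, ranked_matrix):
        with pytest.raises(ValueError, match="no gene"):
            ses_score(ranked_matrix, GeneSet("x", frozenset(["ABSENT"])))
        with pytest.raises(ValueError, match="every matrix gene"):
            ses_score(
                ranked_matrix,
                GeneSet("x", frozenset(["g1", "g2", "g3", "g4", "g5"])),
            )


class TestRandomNull:
    def test_seeded_determinism(self, random_matrix):
        a = random_null(random_matrix, 5, n_draws=50, seed=3)
        b = random_null(random_matrix, 5, n_draws=50, seed=3)
        assert a.pooled_threshold == b.pooled_threshold
        pd.testing.assert_series_equal(a.per_sample_threshold, b.per_sample_threshold)

    def test_single_draw_equals_that_sets_score(self, random_matrix):
        """With n_draws=1 the threshold is just the drawn set's SES."""
        null = random_null(random_matrix, 4, n_draws=1, seed=9, weight_exponent=0.25)
        rng = np.random.default_rng(9)
        drawn = [random_matrix.gene_symbols[i]
                 for i in rng.choice(random_matrix.n_genes, 4, replace=False)]
        direct = ses_score(random_matrix, GeneSet("d", frozenset(drawn)), 0.25)
        assert null.pooled_threshold == pytest.approx(direct.scores.mean())
        np.testing.assert_allclose(
            null.per_sample_threshold.to_numpy(), direct.scores.to_numpy()
        )

    def test_exchangeable_matrix_null_matches_fixed_set(self):
        """On an i.i.d. matrix any fixed set is a typical null draw, so the
        pooled null mean approximates that set's pooled mean SES."""
        rng = np.random.default_rng(21)
        genes = [f"G{i:03d}" for i in range(200)]
        m = ExpressionMatrix(
            pd.DataFrame(rng.normal(0, 1, (200, 20)), index=genes,
                         columns=[f"s{i}" for i in range(20)])
        )
        fixed = GeneSet("fixed", frozenset(genes[5:38]))  # 33 genes
        fixed_mean = ses_score(m, fixed, 0.25).scores.mean()
        null = random_null(m, 33, n_draws=1000, seed=4)
        spread = null.per_sample_threshold.std()
        assert null.pooled_threshold == pytest.approx(fixed_mean, abs=3 * max(spread, 1.0))

    def test_set_size_bounds(self, random_matrix):
        with pytest.raises(ValueError):
            random_null(random_matrix, random_matrix.n_genes, 10, 0)
        with pytest.raises(ValueError):
            random_null(random_matrix, 3, 0, 0)


class TestScoreAxes:
    def test_spiked_sample_scores_highest(self, random_matrix, iegs_like_set):
        spiked = random_matrix.data.copy()
        spiked.loc[list(iegs_like_set.genes), "s2"] += 6.0
        axes = score_axes(
            ExpressionMatrix(spiked), iegs_like_set,
            GeneSet("other", frozenset(["G030", "G031"])),
            thresholds=(0.0, 0.0),
        )
        assert axes.ses_iegs33["s2"] == axes.ses_iegs33.max()
        assert (axes.ses_iegs33.drop("s2") < axes.ses_iegs33["s2"]).all()

    def test_explicit_thresholds_pass_through(self, random_matrix, iegs_like_set):
        axes = score_axes(
            random_matrix, iegs_like_set,
            GeneSet("o", frozenset(["G050"])), thresholds=(0.0, 0.0),
        )
        assert (axes.thr_iegs33, axes.thr_tact) == (0.0, 0.0)

    def test_sample_permutation_permutes_scores(self, random_matrix, iegs_like_set):
        perm = ["s5", "s2", "s0", "s1", "s7", "s3", "s6", "s4"]
        axes = score_axes(random_matrix, iegs_like_set,
                          GeneSet("o", frozenset(["G050", "G051"])),
                          thresholds=(0.0, 0.0))
        axes_p = score_axes(random_matrix.subset_samples(perm), iegs_like_set,
                            GeneSet("o", frozenset(["G050", "G051"])),
                            thresholds=(0.0, 0.0))
        pd.testing.assert_series_equal(
            axes.ses_iegs33.loc[perm], axes_p.ses_iegs33
        )


def test_minmax_normalize_range_and_constant_error():
    s = pd.Series([2.0, 4.0, 3.0])
    out = minmax_normalize(s)
    assert out.min() == 0.0 and out.max() == 1.0
    with pytest.raises(ValueError):
        minmax_normalize(pd.Series([1.0, 1.0]))
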