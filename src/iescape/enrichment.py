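"""Per-sample gene-set enrichment scores (SES) and null calibration.

The sample enrichment score is a single-sample GSEA statistic: within each
sample, genes are ranked by descending expression (ties broken by ascending
symbol so runs are reproducible); a running sum walks down the ranked list,
rising by a normalized rank weight at each in-set gene and falling by
1/(G - m) at each out-of-set gene; the SES is the sum of the running-sum
values over all G ranks (the area under the walk).  With weight exponent 0
every in-set gene contributes equally (1/m) and the score depends on ranks
only, so it is invariant under any strictly monotone per-sample transform
of expression.

High/low calibration uses random gene sets of matched size: on a given
platform the expected SES of a random set is not zero, and differs between
platforms, so the decision threshold is estimated from seeded random draws
on the cohort being staged rather than fixed a priori.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, GeneSet

__all__ = ["SESVector", "NullCalibration", "AxisScores", "ses_score",
           "random_null", "score_axes", "minmax_normalize"]


@dataclass(frozen=True)
class SESVector:
    """Per-sample enrichment scores for one gene set."""

    gene_set_name: str
    scores: pd.Series  # index = sample ids
    weight_exponent: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.scores.to_numpy()).all():
            raise ValueError("non-finite SES")


@dataclass(frozen=True)
class NullCalibration:
    """Random-gene-set SES reference for one set size on one cohort."""

    set_size: int
    n_draws: int
    seed: int
    per_sample_threshold: pd.Series
    pooled_threshold: float

    def __post_init__(self) -> None:
        if self.n_draws < 1:
            raise ValueError("n_draws must be >= 1")
        if not np.isfinite(self.per_sample_threshold.to_numpy()).all():
            raise ValueError("non-finite per-sample thresholds")
        if not np.isfinite(self.pooled_threshold):
            raise ValueError("non-finite pooled threshold")


@dataclass(frozen=True)
class AxisScores:
    """The two staging axes: per-sample (SES_IEGS33, SES_Tact) plus the
    thresholds that will define the quadrants."""

    ses_iegs33: pd.Series
    ses_tact: pd.Series
    thr_iegs33: float
    thr_tact: float

    def __post_init__(self) -> None:
        if list(self.ses_iegs33.index) != list(self.ses_tact.index):
            raise ValueError("axis score sample ids disagree")
        for v in (self.thr_iegs33, self.thr_tact):
            if not np.isfinite(v):
                raise ValueError("non-finite threshold")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.ses_iegs33.index)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"ses_iegs33": self.ses_iegs33, "ses_tact": self.ses_tact}
        )


# ---------------------------------------------------------------------------
# Rank machinery
# ---------------------------------------------------------------------------


def _rank_weights(matrix: ExpressionMatrix) -> tuple[np.ndarray, pd.Index]:
    """Per (gene, sample) descending-rank weight r = G - position + 1.

    The gene with the highest expression in a sample gets weight G, the
    lowest gets 1.  Ties broken by ascending symbol order.
    """
    df = matrix.data
    genes = df.index.to_numpy()
    sym_order = np.argsort(genes, kind="stable")  # ascending symbol
    sym_rank = np.empty(len(genes), dtype=np.int64)
    sym_rank[sym_order] = np.arange(len(genes))
    values = df.to_numpy()
    G, S = values.shape
    weights = np.empty((G, S), dtype=float)
    for j in range(S):
        # sort by (-expression, symbol): lexsort keys in reverse priority
        order = np.lexsort((sym_rank, -values[:, j]))
        weights[order, j] = np.arange(G, 0, -1)
    return weights, df.index


def _ses_from_weights(
    weights: np.ndarray, in_set: np.ndarray, exponent: float
) -> np.ndarray:
    """Closed-form SES for precomputed rank weights.

    The sum over ranks k of the running sum equals
    sum_k increment_k * (G - k + 1); with r = G - k + 1 the hit term is
    sum_hits r^(a+1) / sum_hits r^a and the miss term is
    sum_misses r / (G - m).  ``in_set`` may be a boolean matrix
    (draws x genes) to score many sets at once.
    """
    G = weights.shape[0]
    in_set = np.atleast_2d(in_set).astype(float)  # draws x genes
    m = in_set.sum(axis=1)  # per draw
    if np.any(m == 0) or np.any(m == G):
        raise ValueError("gene set must hit >=1 and < all matrix genes")
    wa = weights**exponent if exponent != 0 else np.ones_like(weights)
    wa1 = wa * weights
    hit_num = in_set @ wa1  # draws x samples
    hit_den = in_set @ wa
    total_r = G * (G + 1) / 2.0
    miss_sum = total_r - (in_set @ weights)
    ses = hit_num / hit_den - miss_sum / (G - m)[:, None]
    return ses


def _membership(genes: pd.Index, gene_set: GeneSet) -> np.ndarray:
    mask = np.asarray(genes.isin(gene_set.genes))
    if not mask.any():
        missing = sorted(gene_set.genes)
        raise ValueError(
            f"no gene of set {gene_set.name!r} is in the matrix; "
            f"missing: {missing[:10]}{'...' if len(missing) > 10 else ''}"
        )
    if mask.all():
        raise ValueError(
            f"gene set {gene_set.name!r} covers every matrix gene; "
            "the miss term is undefined"
        )
    return mask


# ---------------------------------------------------------------------------
# Public operations
# ---------------------------------------------------------------------------


def ses_score(
    matrix: ExpressionMatrix, gene_set: GeneSet, weight_exponent: float = 0.25
) -> SESVector:
    """Single-sample enrichment score of ``gene_set`` in every sample.

    Parameters
    ----------
    matrix
        Log2 expression, genes x samples.
    gene_set
        Must share at least one gene with the matrix and must not cover
        all of it.
    weight_exponent
        Exponent on the descending rank weight of each in-set gene
        (0 = unweighted ranks; 0.25 = default weighting).
    """
    weights, genes = _rank_weights(matrix)
    mask = _membership(genes, gene_set)
    ses = _ses_from_weights(weights, mask, weight_exponent)[0]
    return SESVector(
        gene_set.name,
        pd.Series(ses, index=matrix.data.columns, name=gene_set.name),
        weight_exponent,
    )


def random_null(
    matrix: ExpressionMatrix,
    set_size: int,
    n_draws: int = 1000,
    seed: int = 0,
    weight_exponent: float = 0.25,
) -> NullCalibration:
    """SES null reference from seeded uniform random gene sets.

    Draws ``n_draws`` sets of ``set_size`` genes without replacement,
    scores each on every sample, and summarizes: ``per_sample_threshold``
    is the mean null SES per sample, ``pooled_threshold`` the grand mean.
    """
    G = matrix.n_genes
    if not 1 <= set_size < G:
        raise ValueError(f"set_size must be in [1, {G - 1}], got {set_size}")
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    rng = np.random.default_rng(seed)
    weights, _ = _rank_weights(matrix)
    member = np.zeros((n_draws, G), dtype=float)
    for d in range(n_draws):
        member[d, rng.choice(G, size=set_size, replace=False)] = 1.0
    ses = _ses_from_weights(weights, member, weight_exponent)  # draws x samples
    per_sample = pd.Series(ses.mean(axis=0), index=matrix.data.columns)
    return NullCalibration(
        set_size=set_size,
        n_draws=n_draws,
        seed=seed,
        per_sample_threshold=per_sample,
        pooled_threshold=float(ses.mean()),
    )


def score_axes(
    matrix: ExpressionMatrix,
    iegs: GeneSet,
    tact: GeneSet,
    thresholds: tuple[float, float] | None = None,
    n_draws: int = 1000,
    seed: int = 0,
    weight_exponent: float = 0.25,
) -> AxisScores:
    """Score both staging axes and fix the high/low thresholds.

    If ``thresholds`` is None, each axis threshold is the pooled mean SES
    of ``n_draws`` random gene sets matched to that axis's effective set
    size on this cohort (platform-specific null calibration).
    """
    ses_i = ses_score(matrix, iegs, weight_exponent)
    ses_t = ses_score(matrix, tact, weight_exponent)
    if thresholds is not None:
        thr_i, thr_t = float(thresholds[0]), float(thresholds[1])
    else:
        genes = matrix.data.index
        size_i = int(genes.isin(iegs.genes).sum())
        size_t = int(genes.isin(tact.genes).sum())
        thr_i = random_null(
            matrix, size_i, n_draws, seed, weight_exponent
        ).pooled_threshold
        thr_t = random_null(
            matrix, size_t, n_draws, seed + 1, weight_exponent
        ).pooled_threshold
    return AxisScores(ses_i.scores, ses_t.scores, thr_i, thr_t)


def minmax_normalize(scores: pd.Series) -> pd.Series:
    """Optional cross-cohort min-max rescaling of SES to [0, 1]."""
    lo, hi = scores.min(), scores.max()
    if hi == lo:
        raise ValueError("constant scores cannot be min-max normalized")
    return (scores - lo) / (hi - lo)
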