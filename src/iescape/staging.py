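"""Immune-escape staging from the two enrichment axes.

Each tumor is placed in one of four immune-escape (IE) stages from its
(IEGS33, T-cell activation) enrichment-score pair relative to the cohort
thresholds:

    stage 1  IEGS33 low,  T-activation low   (non-immunogenic)
    stage 2  IEGS33 low,  T-activation high  (immunogenic, not escaped)
    stage 3  IEGS33 high, T-activation high  (immunogenic, escaped)
    stage 4  IEGS33 high, T-activation low   (fully escaped)

"High" means strictly greater than the threshold; scores exactly on a
threshold count as low.  The module also summarizes stage composition per
diagnostic group, tests per-gene differential expression of a signature
between two groups, and offers a small hierarchical-clustering utility
for heatmap-style ordering of samples.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import average, leaves_list
from scipy.spatial.distance import pdist

from .enrichment import AxisScores
from .io import ExpressionMatrix, GeneSet

__all__ = ["StageAssignment", "assign_stage", "stage_summary",
           "differential_genes", "cluster_samples", "STAGE_OF_FLAGS"]

#: (iegs_high, tact_high) -> stage
STAGE_OF_FLAGS: dict[tuple[bool, bool], int] = {
    (False, False): 1,
    (False, True): 2,
    (True, True): 3,
    (True, False): 4,
}


@dataclass(frozen=True)
class StageAssignment:
    """Per-sample IE stage with the underlying high/low flags."""

    table: pd.DataFrame  # columns: ses_iegs33, ses_tact, iegs_high, tact_high, stage, group

    def __post_init__(self) -> None:
        required = {"ses_iegs33", "ses_tact", "iegs_high", "tact_high", "stage"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"stage table missing columns {sorted(missing)}")
        stages = self.table["stage"]
        expected = [
            STAGE_OF_FLAGS[(bool(i), bool(t))]
            for i, t in zip(self.table["iegs_high"], self.table["tact_high"])
        ]
        if list(stages) != expected:
            raise ValueError("stage column inconsistent with high/low flags")

    @property
    def stages(self) -> pd.Series:
        return self.table["stage"]


def assign_stage(
    scores: AxisScores, groups: pd.Series | Sequence[str] | None = None
) -> StageAssignment:
    """Map each sample's score pair to an IE stage (total function).

    ``groups`` optionally attaches a diagnostic label (e.g. cHL,
    non-GCB DLBCL) used by :func:`stage_summary`.
    """
    df = scores.to_frame()
    iegs_high = df["ses_iegs33"] > scores.thr_iegs33  # strict: ties are low
    tact_high = df["ses_tact"] > scores.thr_tact
    stage = [
        STAGE_OF_FLAGS[(bool(i), bool(t))] for i, t in zip(iegs_high, tact_high)
    ]
    out = df.assign(iegs_high=iegs_high, tact_high=tact_high, stage=stage)
    if groups is not None:
        g = pd.Series(list(groups), index=df.index) if not isinstance(
            groups, pd.Series
        ) else groups.reindex(df.index)
        if g.isna().any():
            raise ValueError("group label missing for some samples")
        out["group"] = g.astype(str)
    else:
        out["group"] = "all"
    return StageAssignment(out)


def stage_summary(assignment: StageAssignment) -> pd.DataFrame:
    """Counts and within-group percentages per (group, stage).

    Returns a tidy frame with one row per group x stage (stages 1-4 always
    present); within each group the percentages sum to 100.
    """
    tab = assignment.table
    if tab.empty:
        raise ValueError("no samples to summarize")
    rows = []
    for group, sub in tab.groupby("group", sort=True):
        n = len(sub)
        counts = sub["stage"].value_counts()
        for stage in (1, 2, 3, 4):
            c = int(counts.get(stage, 0))
            rows.append(
                {"group": group, "stage": stage, "count": c,
                 "percent": 100.0 * c / n}
            )
    return pd.DataFrame(rows)


def differential_genes(
    matrix: ExpressionMatrix,
    labels: pd.Series | Sequence[str],
    gene_set: GeneSet,
    test: Literal["mann_whitney", "t_test"] = "mann_whitney",
    alpha: float = 0.05,
    adjust: Literal["none", "bh"] = "none",
) -> pd.DataFrame:
    """Per-gene two-group comparison restricted to a signature's genes.

    One row per in-matrix signature gene: statistic, two-sided p,
    ``direction`` (+1 if group-1 mean exceeds group-2 mean), and a
    ``significant`` flag at ``alpha``.  A gene constant in both groups is
    reported with statistic 0 and p = 1.  ``adjust="bh"`` applies
    Benjamini-Hochberg across the reported genes.
    """
    labels = pd.Series(list(labels), index=matrix.data.columns) if not isinstance(
        labels, pd.Series
    ) else labels.reindex(matrix.data.columns)
    uniq = sorted(labels.dropna().unique())
    if len(uniq) != 2:
        raise ValueError(f"need exactly 2 groups, got {uniq}")
    m1 = (labels == uniq[0]).to_numpy()
    m2 = (labels == uniq[1]).to_numpy()
    if m1.sum() < 2 or m2.sum() < 2:
        raise ValueError("each group needs >=2 samples")
    present = [g for g in matrix.data.index if g in gene_set.genes]
    if not present:
        raise ValueError(f"no gene of {gene_set.name!r} in the matrix")
    rows = []
    for gene in present:
        x = matrix.data.loc[gene].to_numpy()
        a, b = x[m1], x[m2]
        if np.ptp(a) == 0 and np.ptp(b) == 0 and a[0] == b[0]:
            stat, p = 0.0, 1.0
        elif test == "t_test":
            stat, p = stats.ttest_ind(a, b, equal_var=True)
        elif test == "mann_whitney":
            stat, p = stats.mannwhitneyu(a, b, alternative="two-sided")
        else:
            raise ValueError(f"unknown test {test!r}")
        rows.append(
            {"gene": gene, "statistic": float(stat), "p": float(p),
             "direction": int(np.sign(a.mean() - b.mean()))}
        )
    out = pd.DataFrame(rows)
    if adjust == "bh":
        out["p_adj"] = _benjamini_hochberg(out["p"].to_numpy())
        out["significant"] = out["p_adj"] < alpha
    else:
        out["significant"] = out["p"] < alpha
    return out


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    n = len(p)
    order = np.argsort(p)
    adj = np.empty(n)
    running = 1.0
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * n / rank)
        adj[i] = running
    return adj


def cluster_samples(
    matrix: ExpressionMatrix, gene_set: GeneSet | None = None
) -> list[str]:
    """Average-linkage hierarchical ordering of samples on z-scored rows.

    Utility for heatmap-style displays of signature expression; returns
    the sample ids in dendrogram leaf order (layout is not part of the
    analysis surface).
    """
    df = matrix.data
    if gene_set is not None:
        keep = df.index.isin(gene_set.genes)
        if not keep.any():
            raise ValueError("no signature gene in the matrix")
        df = df.loc[keep]
    x = df.to_numpy()
    sd = x.std(axis=1, ddof=0)
    sd[sd == 0] = 1.0
    z = (x - x.mean(axis=1, keepdims=True)) / sd[:, None]
    link = average(pdist(z.T, metric="euclidean"))
    return [df.columns[i] for i in leaves_list(link)]
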