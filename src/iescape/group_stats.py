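"""Group comparisons, rater agreement, and the Hans cell-of-origin rule.

The comparison tests mirror standard biomarker-cohort practice: unpaired
two-sided Student t-test or Mann-Whitney U for two groups (the choice
between them — normal vs non-normal data — is an analytic decision left
to the caller; an optional Shapiro-Wilk advisory is logged rather than
silently switching tests), and one-way ANOVA for several groups.

Manual-versus-automated scoring concordance uses the intraclass
correlation for a two-way model with absolute agreement, single rater —
ICC(A,1) — computed from the two-way ANOVA mean squares, so systematic
bias between raters lowers the coefficient.

The Hans algorithm assigns diffuse large B-cell lymphoma to germinal
center B-cell (GCB) versus non-GCB cell of origin from three
immunostains: CD10+ is GCB; CD10-/BCL6- is non-GCB; CD10-/BCL6+ splits
on MUM1 (MUM1- GCB, MUM1+ non-GCB).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger("iescape")

__all__ = ["CooCall", "compare_groups", "icc_absolute_agreement",
           "hans_classify", "HANS_POSITIVITY_CUTOFF"]

#: Percent-positive threshold conventionally used for the Hans stains.
HANS_POSITIVITY_CUTOFF = 30.0


def compare_groups(
    values: Sequence[float] | pd.Series,
    labels: Sequence[str],
    test: Literal["t_test", "mann_whitney", "anova"] = "mann_whitney",
    normality_advisory: bool = False,
) -> tuple[float, float]:
    """Two-sided group comparison: returns (statistic, p).

    ``t_test`` is classic unpaired Student (pooled variance);
    ``mann_whitney`` uses exact enumeration when both groups have <= 8
    values and no ties, otherwise the tie-corrected normal approximation;
    ``anova`` is one-way over 2+ groups.
    """
    values = np.asarray(list(values), dtype=float)
    labels = pd.Series(list(labels))
    if len(values) != len(labels):
        raise ValueError("values/labels length mismatch")
    groups = [values[(labels == g).to_numpy()] for g in labels.unique()]
    if any(len(g) < 2 for g in groups):
        raise ValueError("each group needs >= 2 values")
    if test in ("t_test", "mann_whitney") and len(groups) != 2:
        raise ValueError(f"{test} requires exactly 2 groups, got {len(groups)}")
    if test == "anova" and len(groups) < 2:
        raise ValueError("anova requires >= 2 groups")
    if normality_advisory:
        for name, g in zip(labels.unique(), groups):
            if len(g) >= 3 and np.ptp(g) > 0:
                _, p_sw = stats.shapiro(g)
                if p_sw < 0.05:
                    logger.info(
                        "group %r deviates from normality (Shapiro-Wilk p=%.3g)",
                        name, p_sw,
                    )
    if test == "t_test":
        stat, p = stats.ttest_ind(groups[0], groups[1], equal_var=True)
        if np.isnan(stat):  # both groups constant and equal
            stat, p = 0.0, 1.0
    elif test == "mann_whitney":
        a, b = groups
        ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
        method = "exact" if (len(a) <= 8 and len(b) <= 8 and not ties) else "asymptotic"
        stat, p = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    elif test == "anova":
        stat, p = stats.f_oneway(*groups)
        if np.isnan(stat):
            stat, p = 0.0, 1.0
    else:
        raise ValueError(f"unknown test {test!r}")
    return float(stat), float(min(p, 1.0))


def icc_absolute_agreement(ratings: pd.DataFrame | np.ndarray) -> float:
    """ICC(A,1): two-way model, absolute agreement, single rater.

    ``ratings`` is subjects x raters.  From the two-way ANOVA mean squares
    (MS_R subjects, MS_C raters, MS_E residual; n subjects, k raters):

        ICC(A,1) = (MS_R - MS_E) /
                   (MS_R + (k-1) MS_E + k (MS_C - MS_E) / n)
    """
    X = np.asarray(ratings, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("ratings must be >=2 subjects x >=2 raters")
    if not np.isfinite(X).all():
        raise ValueError("non-finite rating")
    n, k = X.shape
    grand = X.mean()
    row_means = X.mean(axis=1)
    col_means = X.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((X - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    if ss_total == 0:
        raise ValueError("zero total variance: ICC undefined")
    ms_r = ss_rows / (n - 1)
    ms_c = ss_cols / (k - 1)
    ms_e = ss_err / ((n - 1) * (k - 1))
    denom = ms_r + (k - 1) * ms_e + k * (ms_c - ms_e) / n
    if denom == 0:
        raise ValueError("degenerate mean squares: ICC undefined")
    return float((ms_r - ms_e) / denom)


@dataclass(frozen=True)
class CooCall:
    """Hans cell-of-origin call from the three immunostain flags."""

    cd10_pos: bool
    bcl6_pos: bool
    mum1_pos: bool
    call: Literal["GCB", "non-GCB"]


def hans_classify(cd10_pos: bool, bcl6_pos: bool, mum1_pos: bool) -> CooCall:
    """Hans decision tree: CD10+ -> GCB; CD10-/BCL6- -> non-GCB;
    CD10-/BCL6+ -> GCB if MUM1- else non-GCB."""
    if cd10_pos:
        call = "GCB"
    elif not bcl6_pos:
        call = "non-GCB"
    else:
        call = "GCB" if not mum1_pos else "non-GCB"
    return CooCall(bool(cd10_pos), bool(bcl6_pos), bool(mum1_pos), call)
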