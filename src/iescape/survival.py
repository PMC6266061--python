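"""Survival analysis: Kaplan-Meier, log-rank, univariate Cox, marker splits.

Time is measured in months throughout; "5-year survival" is the curve
queried at t = 60.  Progression-free and overall survival share the same
machinery — the event column of the clinical table decides which is being
analyzed (1 = progression/death, 0 = censored).

Estimation is delegated to lifelines (product-limit estimator with
Greenwood variance and log-log confidence bounds; Cox partial likelihood
with Efron tie handling, the better choice for month-resolution data with
heavy ties).  A separate closed-form Cox score test at beta = 0 is
implemented here directly; on tie-free data it coincides with the
two-group log-rank chi-square, which serves as an internal cross-check
between the two routes.

Immunohistochemistry markers are dichotomized at the conventional
cutoffs: 10% positive cells for microenvironment (and whole-section)
scoring, 20% for tumor-cell scoring, strictly greater than the cutoff
counting as "high"; a cohort-median cutoff is available as an alternative.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import multivariate_logrank_test
from scipy import stats

__all__ = [
    "SurvivalRecord", "MarkerRecord", "KMCurve", "CoxResult",
    "km_estimate", "logrank_test", "cox_univariate", "cox_score_test",
    "dichotomize_marker",
]


@dataclass(frozen=True)
class SurvivalRecord:
    """One time-to-event observation."""

    sample_id: str
    time: float  # months
    event: int  # 1 = progression/death, 0 = censored
    group: str = "all"

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValueError(f"negative time for {self.sample_id!r}")
        if self.event not in (0, 1):
            raise ValueError(f"event must be 0/1, got {self.event!r}")


@dataclass(frozen=True)
class MarkerRecord:
    """Percent of positively stained cells for one marker in one compartment."""

    sample_id: str
    marker: str
    compartment: Literal["total", "ME", "tumor"]
    percent_positive: float

    def __post_init__(self) -> None:
        if not 0 <= self.percent_positive <= 100:
            raise ValueError(
                f"percent_positive out of [0, 100] for {self.sample_id!r}"
            )
        if self.compartment not in ("total", "ME", "tumor"):
            raise ValueError(f"unknown compartment {self.compartment!r}")


def _to_frame(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        df = records.copy()
    else:
        records = list(records)
        if not records:
            raise ValueError("no survival records")
        df = pd.DataFrame(
            {
                "sample_id": [r.sample_id for r in records],
                "time": [r.time for r in records],
                "event": [r.event for r in records],
                "group": [r.group for r in records],
            }
        )
    if (df["time"] < 0).any():
        raise ValueError("negative survival time")
    if not df["event"].isin([0, 1]).all():
        raise ValueError("event must be 0/1")
    return df


# ---------------------------------------------------------------------------
# Kaplan-Meier
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class KMCurve:
    """Product-limit curve with Greenwood variance and log-log 95% CI."""

    times: np.ndarray  # ascending event times
    survival: np.ndarray  # S at each event time
    variance: np.ndarray  # Greenwood variance of S
    ci_lower: np.ndarray
    ci_upper: np.ndarray

    def survival_at(self, t: float) -> float:
        """S at the largest event time <= t (1.0 before the first event)."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])

    def ci_at(self, t: float) -> tuple[float, float]:
        idx = np.searchsorted(self.times, t, side="right") - 1
        if idx < 0:
            return (1.0, 1.0)
        return (float(self.ci_lower[idx]), float(self.ci_upper[idx]))


def km_estimate(records) -> KMCurve:
    """Kaplan-Meier estimate from survival records (or a clinical frame)."""
    df = _to_frame(records)
    kmf = KaplanMeierFitter(alpha=0.05)
    kmf.fit(df["time"], event_observed=df["event"])
    table = kmf.event_table
    event_rows = table[table["observed"] > 0]
    if event_rows.empty:
        return KMCurve(
            times=np.array([]), survival=np.array([]), variance=np.array([]),
            ci_lower=np.array([]), ci_upper=np.array([]),
        )
    times = event_rows.index.to_numpy(dtype=float)
    surv = kmf.survival_function_.loc[event_rows.index, "KM_estimate"].to_numpy()
    # Greenwood: Var(S) = S^2 * cumsum d / (n (n - d)) over event times;
    # once the risk set is exhausted (S = 0) the variance is taken as 0
    d = event_rows["observed"].to_numpy(dtype=float)
    n = event_rows["at_risk"].to_numpy(dtype=float)
    terms = np.where(n > d, d / (n * np.maximum(n - d, 1.0)), 0.0)
    var = np.where(surv > 0, surv**2 * np.cumsum(terms), 0.0)
    ci = kmf.confidence_interval_.loc[event_rows.index]
    return KMCurve(
        times=times,
        survival=surv,
        variance=var,
        ci_lower=ci.iloc[:, 0].to_numpy(),
        ci_upper=ci.iloc[:, 1].to_numpy(),
    )


# ---------------------------------------------------------------------------
# Log-rank
# ---------------------------------------------------------------------------


def logrank_test(records, group_col: str = "group") -> tuple[float, int, float]:
    """Log-rank test over 2+ groups: (chi_square, df, p)."""
    df = _to_frame(records)
    groups = df[group_col].astype(str)
    sizes = groups.value_counts()
    if len(sizes) < 2:
        raise ValueError(f"log-rank needs >= 2 groups, got one group {sizes.index[0]!r}")
    if (sizes == 0).any():  # pragma: no cover - value_counts omits empties
        raise ValueError("a group has zero records")
    res = multivariate_logrank_test(df["time"], groups, df["event"])
    return float(res.test_statistic), len(sizes) - 1, float(res.p_value)


# ---------------------------------------------------------------------------
# Cox regression
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CoxResult:
    hr: float
    ci95: tuple[float, float]
    p: float
    beta: float
    se: float
    separation: bool = False


def cox_univariate(records, covariate: pd.Series | Sequence[float]) -> CoxResult:
    """Univariate Cox proportional-hazards fit (Efron ties, Wald CI/p).

    ``covariate`` is a binary or real value per record, aligned with the
    record order (or indexed by sample_id when a Series is passed).
    """
    df = _to_frame(records)
    if isinstance(covariate, pd.Series):
        x = covariate.reindex(df["sample_id"]).to_numpy(dtype=float)
        if np.isnan(x).any():
            raise ValueError("covariate missing for some samples")
    else:
        x = np.asarray(list(covariate), dtype=float)
        if len(x) != len(df):
            raise ValueError("covariate length mismatch")
    if np.ptp(x) == 0:
        raise ValueError("constant covariate")
    if int(df["event"].sum()) < 2:
        raise ValueError("need >= 2 events")
    fit_df = pd.DataFrame({"time": df["time"], "event": df["event"], "x": x})
    cph = CoxPHFitter()
    separation = False
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(fit_df, duration_col="time", event_col="event")
    except ConvergenceError:
        # monotone partial likelihood (complete separation): refit with a
        # small ridge penalty so beta stays finite, and flag the result
        separation = True
        warnings.warn(
            "monotone Cox partial likelihood (complete separation); "
            "coefficient capped by a ridge penalty", stacklevel=2,
        )
        cph = CoxPHFitter(penalizer=0.1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(fit_df, duration_col="time", event_col="event")
    beta = float(cph.params_["x"])
    se = float(cph.standard_errors_["x"])
    z = stats.norm.ppf(0.975)
    return CoxResult(
        hr=float(np.exp(beta)),
        ci95=(float(np.exp(beta - z * se)), float(np.exp(beta + z * se))),
        p=float(cph.summary.loc["x", "p"]),
        beta=beta,
        se=se,
        separation=separation,
    )


def cox_score_test(records, covariate: Sequence[float]) -> tuple[float, float]:
    """Cox partial-likelihood score test at beta = 0: (chi_square, p).

    Closed form: at each event time, U accumulates the event subject's
    covariate minus the risk-set mean, and the information accumulates the
    risk-set variance; chi-square = U^2 / I with 1 df.  On tie-free data
    with a binary covariate this is exactly the two-group log-rank
    statistic, which is used as an internal consistency check against the
    lifelines-based log-rank route.
    """
    df = _to_frame(records)
    x = np.asarray(list(covariate), dtype=float)
    if len(x) != len(df):
        raise ValueError("covariate length mismatch")
    t = df["time"].to_numpy(dtype=float)
    e = df["event"].to_numpy(dtype=int)
    order = np.argsort(t, kind="stable")
    t, e, x = t[order], e[order], x[order]
    U = 0.0
    info = 0.0
    n = len(t)
    for i in range(n):
        if e[i] != 1:
            continue
        risk = t >= t[i]
        xr = x[risk]
        mean = xr.mean()
        U += x[i] - mean
        info += np.mean((xr - mean) ** 2)
    if info <= 0:
        raise ValueError("zero information: covariate constant on risk sets")
    chi2 = U * U / info
    return float(chi2), float(stats.chi2.sf(chi2, df=1))


# ---------------------------------------------------------------------------
# Marker dichotomization
# ---------------------------------------------------------------------------


def dichotomize_marker(
    markers: Sequence[MarkerRecord] | pd.DataFrame,
    cutoff_me: float = 10.0,
    cutoff_tumor: float = 20.0,
    use_median: bool = False,
) -> pd.DataFrame:
    """High/low label per (sample, marker, compartment).

    Microenvironment and whole-section ("total") scores are split at
    ``cutoff_me`` (default 10%), tumor-cell scores at ``cutoff_tumor``
    (default 20%); strictly greater than the cutoff counts as high.  With
    ``use_median=True`` the cutoff is instead the cohort median within
    each (marker, compartment).
    """
    if isinstance(markers, pd.DataFrame):
        df = markers.copy()
    else:
        markers = list(markers)
        if not markers:
            raise ValueError("no marker records")
        df = pd.DataFrame(
            {
                "sample_id": [m.sample_id for m in markers],
                "marker": [m.marker for m in markers],
                "compartment": [m.compartment for m in markers],
                "percent_positive": [m.percent_positive for m in markers],
            }
        )
    if df.duplicated(["sample_id", "marker", "compartment"]).any():
        raise ValueError("duplicate (sample, marker, compartment) records")
    if ((df["percent_positive"] < 0) | (df["percent_positive"] > 100)).any():
        raise ValueError("percent_positive out of [0, 100]")
    if use_median:
        cutoff = df.groupby(["marker", "compartment"])["percent_positive"].transform(
            "median"
        )
    else:
        cutoff = df["compartment"].map(
            {"total": cutoff_me, "ME": cutoff_me, "tumor": cutoff_tumor}
        )
        if cutoff.isna().any():
            bad = df.loc[cutoff.isna(), "compartment"].unique()
            raise ValueError(f"unknown compartment(s) {list(bad)}")
    df["cutoff"] = cutoff
    df["label"] = np.where(df["percent_positive"] > cutoff, "high", "low")
    return df
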