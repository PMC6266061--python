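"""Independent brute-force oracles used by the test suite.

These deliberately re-derive results from first principles (explicit
running sums, full enumeration, dense grid search) and share no code
with the package implementation.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np


def ses_running_sum(expression: dict[str, float], gene_set: set[str]) -> float:
    """Unweighted (exponent-0) enrichment score by literal running sum.

    Ranks genes by descending expression with ties broken by ascending
    symbol, walks the list accumulating +1/m for hits and -1/(G-m) for
    misses, and returns the sum of the running-sum values at every rank.
    """
    ordered = sorted(expression, key=lambda g: (-expression[g], g))
    G = len(ordered)
    m = sum(1 for g in ordered if g in gene_set)
    running = 0.0
    total = 0.0
    for g in ordered:
        running += 1.0 / m if g in gene_set else -1.0 / (G - m)
        total += running
    return total


def mann_whitney_exact_p(a: list[float], b: list[float]) -> float:
    """Two-sided exact Mann-Whitney p by enumerating all label splits.

    Assumes no ties.  p = fraction of splits whose U statistic is at
    least as extreme (on either side) as the observed one.
    """
    pooled = sorted(a + b)
    n_a = len(a)

    def u_stat(group_a: tuple[float, ...]) -> float:
        return sum(
            1.0 for x in group_a for y in pooled if y not in group_a and x > y
        )

    u_obs = sum(1.0 for x in a for y in b if x > y)
    mid = n_a * len(b) / 2.0
    count = 0
    total = 0
    for combo in combinations(pooled, n_a):
        total += 1
        if abs(u_stat(combo) - mid) >= abs(u_obs - mid) - 1e-12:
            count += 1
    return count / total


def logrank_two_group(times_a, events_a, times_b, events_b) -> float:
    """Two-group log-rank chi-square by explicit O-E/V tabulation."""
    all_times = sorted(
        set([t for t, e in zip(times_a, events_a) if e == 1]
            + [t for t, e in zip(times_b, events_b) if e == 1])
    )
    O_minus_E = 0.0
    V = 0.0
    for t in all_times:
        n_a = sum(1 for x in times_a if x >= t)
        n_b = sum(1 for x in times_b if x >= t)
        d_a = sum(1 for x, e in zip(times_a, events_a) if x == t and e == 1)
        d_b = sum(1 for x, e in zip(times_b, events_b) if x == t and e == 1)
        n = n_a + n_b
        d = d_a + d_b
        if n < 2:
            continue
        e_a = d * n_a / n
        v = d * (n_a / n) * (n_b / n) * (n - d) / (n - 1) if n > 1 else 0.0
        O_minus_E += d_a - e_a
        V += v
    return O_minus_E**2 / V


def grid_simplex_lsq(S: np.ndarray, b: np.ndarray, step: float = 0.01) -> np.ndarray:
    """Dense-grid least squares over the 3-type simplex."""
    assert S.shape[1] == 3
    best, best_err = None, np.inf
    grid = np.arange(0.0, 1.0 + step / 2, step)
    for f1 in grid:
        for f2 in np.arange(0.0, 1.0 - f1 + step / 2, step):
            f = np.array([f1, f2, 1.0 - f1 - f2])
            err = np.sum((S @ f - b) ** 2)
            if err < best_err:
                best_err, best = err, f
    return best


def icc_a1_anova(X: np.ndarray) -> float:
    """ICC(A,1) via an explicitly tabulated two-way ANOVA table."""
    n, k = X.shape
    grand = X.mean()
    ms_rows = k * ((X.mean(axis=1) - grand) ** 2).sum() / (n - 1)
    ms_cols = n * ((X.mean(axis=0) - grand) ** 2).sum() / (k - 1)
    resid = X - X.mean(axis=1, keepdims=True) - X.mean(axis=0, keepdims=True) + grand
    ms_err = (resid**2).sum() / ((n - 1) * (k - 1))
    return (ms_rows - ms_err) / (
        ms_rows + (k - 1) * ms_err + k * (ms_cols - ms_err) / n
    )
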