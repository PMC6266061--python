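"""Signature-based leukocyte deconvolution of bulk expression.

Estimates, for every bulk sample, the mixing proportions of a panel of
pure cell types (14 leukocyte and non-hematopoietic types by default)
from a signature matrix of pure-type expression profiles.  The model is
linear in linear-scale expression: b = S f with f on the simplex.  The
solver works on the genes shared between signature and mixture, after
weighting each gene by the inverse of the signature's per-gene dispersion
(so high-variance marker genes do not dominate the fit purely by scale).
This weighting is linear in the data, which keeps the solution exactly
scale-equivariant: multiplying a bulk profile by any positive constant
rescales the raw coefficients and leaves the normalized fractions
unchanged, and a noiseless simplex mixture is recovered exactly.  Full
per-gene z-scoring (with centering) is available via ``center=True`` but
makes the weighted signature columns linearly dependent and is therefore
not the default.

Two solvers are offered: non-negative least squares (deterministic,
default) and nu-support-vector regression over a small nu grid with
negative coefficients clipped, in the spirit of CIBERSORT.  Fractions are
always renormalized to sum to one.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import nnls
from sklearn.svm import NuSVR

from .io import ExpressionMatrix

__all__ = ["SignatureMatrix", "FractionTable", "fit_fractions", "build_signature"]

NU_GRID = (0.25, 0.5, 0.75)


@dataclass
class SignatureMatrix:
    """Pure cell-type reference profiles, signature genes x cell types,
    linear-scale expression."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        if df.index.duplicated().any():
            raise ValueError("duplicate signature genes")
        if df.columns.duplicated().any():
            raise ValueError("duplicate cell-type names")
        x = df.to_numpy(dtype=float)
        if not np.isfinite(x).all():
            raise ValueError("non-finite signature values")
        if (x < 0).any():
            raise ValueError("signature values must be >= 0 (linear scale)")
        for i in range(x.shape[1]):
            for j in range(i + 1, x.shape[1]):
                if np.array_equal(x[:, i], x[:, j]):
                    raise ValueError(
                        f"cell types {df.columns[i]!r} and {df.columns[j]!r} "
                        "have identical profiles"
                    )
        self.data = df.astype(float)

    @property
    def cell_types(self) -> list[str]:
        return list(self.data.columns)

    @property
    def genes(self) -> list[str]:
        return list(self.data.index)


@dataclass
class FractionTable:
    """Per-sample cell-type proportions on the simplex (rows sum to 1)."""

    data: pd.DataFrame  # samples x cell types

    def __post_init__(self) -> None:
        x = self.data.to_numpy(dtype=float)
        if (x < -1e-12).any():
            raise ValueError("negative fraction")
        rowsums = x.sum(axis=1)
        if not np.allclose(rowsums, 1.0, atol=1e-9):
            bad = self.data.index[np.argmax(np.abs(rowsums - 1))]
            raise ValueError(f"fractions of sample {bad!r} do not sum to 1")
        self.data = self.data.astype(float).clip(lower=0.0)


def _solve_nnls(S: np.ndarray, b: np.ndarray) -> np.ndarray:
    f, _ = nnls(S, b)
    return f


def _solve_nusvr(S: np.ndarray, b: np.ndarray) -> np.ndarray:
    best_f, best_rmse = None, np.inf
    for nu in NU_GRID:
        model = NuSVR(kernel="linear", nu=nu, C=1.0, tol=1e-6)
        model.fit(S, b)
        coef = np.asarray(model.coef_).ravel()
        rmse = float(np.sqrt(np.mean((S @ coef - b) ** 2)))
        if rmse < best_rmse:
            best_rmse, best_f = rmse, coef
    return np.clip(best_f, 0.0, None)


def fit_fractions(
    signature: SignatureMatrix,
    matrix: ExpressionMatrix,
    solver: Literal["nnls", "nu_svr"] = "nnls",
    scale: Literal["linear", "log2_input"] = "linear",
    center: bool = False,
) -> FractionTable:
    """Estimate cell-type fractions for every sample of ``matrix``.

    Parameters
    ----------
    signature
        Pure-type profiles in linear scale.
    matrix
        Bulk expression.  With ``scale="log2_input"`` the matrix is
        unlogged (2**x) before solving; with ``"linear"`` it is used as is.
    solver
        ``"nnls"`` (deterministic non-negative least squares, default) or
        ``"nu_svr"`` (linear nu-SVR over nu in {0.25, 0.5, 0.75}, keeping
        the nu with the lowest RMSE and clipping negative coefficients).
    center
        Also subtract the signature's per-gene mean (full z-scoring).
        Off by default; see module docstring.
    """
    shared = [g for g in signature.genes if g in set(matrix.gene_symbols)]
    if len(shared) < 2:
        raise ValueError(
            f"only {len(shared)} signature genes shared with the matrix; need >= 2"
        )
    S = signature.data.loc[shared].to_numpy()
    B = matrix.data.loc[shared].to_numpy()
    if scale == "log2_input":
        B = np.power(2.0, B)
    elif scale != "linear":
        raise ValueError(f"unknown scale {scale!r}")

    # per-gene weighting from the signature's dispersion across cell types
    sd = S.std(axis=1, ddof=0)
    sd[sd == 0] = 1.0
    if center:
        mu = S.mean(axis=1)
        Sw = (S - mu[:, None]) / sd[:, None]
        Bw = (B - mu[:, None]) / sd[:, None]
    else:
        Sw = S / sd[:, None]
        Bw = B / sd[:, None]

    solve = {"nnls": _solve_nnls, "nu_svr": _solve_nusvr}[solver]
    fractions = np.empty((matrix.n_samples, S.shape[1]))
    for j, sample in enumerate(matrix.sample_ids):
        b = Bw[:, j]
        if np.all(B[:, j] == 0):
            raise ValueError(f"sample {sample!r} is all zero on signature genes")
        f = solve(Sw, b)
        total = f.sum()
        if total <= 0:
            raise ValueError(f"degenerate fit for sample {sample!r} (all-zero fractions)")
        fractions[j] = f / total
    return FractionTable(
        pd.DataFrame(fractions, index=matrix.sample_ids, columns=signature.cell_types)
    )


def build_signature(
    pure_profiles: ExpressionMatrix,
    labels: pd.Series | Sequence[str],
    top_k: int = 50,
    scale: Literal["linear", "log2_input"] = "log2_input",
) -> SignatureMatrix:
    """Derive a signature matrix from labeled pure-cell-type profiles.

    Per cell type the mean profile is taken (in linear scale); the
    signature genes are the union over types of the ``top_k`` genes by
    one-vs-rest mean difference.  Deterministic given the input order.
    """
    labels = pd.Series(list(labels), index=pure_profiles.data.columns) if not isinstance(
        labels, pd.Series
    ) else labels.reindex(pure_profiles.data.columns)
    if labels.isna().any():
        raise ValueError("cell-type label missing for some profiles")
    types = sorted(labels.unique())
    if len(types) < 2:
        raise ValueError("need >= 2 cell types")
    X = pure_profiles.data.to_numpy()
    if scale == "log2_input":
        X = np.power(2.0, X)
    means = {}
    for t in types:
        cols = (labels == t).to_numpy()
        if cols.sum() < 1:
            raise ValueError(f"cell type {t!r} has no profiles")
        means[t] = X[:, cols].mean(axis=1)
    M = np.column_stack([means[t] for t in types])
    G = M.shape[0]
    k = min(top_k, G)
    if top_k > G:
        import logging

        logging.getLogger("iescape").warning(
            "top_k=%d exceeds gene count %d; using all genes", top_k, G
        )
    selected: set[int] = set()
    for i, t in enumerate(types):
        rest = M[:, [j for j in range(len(types)) if j != i]].mean(axis=1)
        diff = np.abs(M[:, i] - rest)  # markers can be up or down
        # stable deterministic top-k: sort by (-|diff|, gene index)
        order = np.lexsort((np.arange(G), -diff))
        selected.update(order[:k].tolist())
    idx = sorted(selected)
    genes = [pure_profiles.data.index[i] for i in idx]
    return SignatureMatrix(pd.DataFrame(M[idx], index=genes, columns=types))
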