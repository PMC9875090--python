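"""Neutrality-plot regression and Spearman correlation diagnostics.

The neutrality plot regresses GC12 (mean G+C at codon positions 1 and 2)
on GC3 across genes. Under pure mutation pressure all three positions
drift together and the slope approaches 1; under strong selection on the
(amino-acid-determined) first two positions the slope approaches 0. The
default fit is ordinary least squares of GC12 on GC3, with the Pearson
correlation and its two-sided p-value alongside; a reduced-major-axis
slope is available as an option since the literature is split on the
choice.

The correlation matrix uses Spearman's rank correlation (average-rank tie
handling, two-sided p-values) among compositional indices and ENC, with
optional Benjamini–Hochberg adjustment (off by default).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin
from statsmodels.stats.multitest import multipletests

from .errors import CubkitError


@dataclass(frozen=True)
class NeutralityFit:
    slope: float
    intercept: float
    pearson_r: float
    p_value: float
    n: int
    method: str = "ols"


@dataclass
class CorrelationMatrix:
    variables: list[str]
    rho: pd.DataFrame
    p: pd.DataFrame
    adjusted_p: pd.DataFrame | None = None


def neutrality_fit(
    data: pd.DataFrame | None = None,
    gc12: np.ndarray | None = None,
    gc3: np.ndarray | None = None,
    method: str = "ols",
) -> NeutralityFit:
    """Fit GC12 on GC3 across a set of genes.

    ``data`` is a compositional table with GC12 and GC3 columns (as
    produced by :func:`cubkit.composition.composition_table`); or pass the
    two vectors directly.
    """
    if data is not None:
        gc12 = data["GC12"].to_numpy(dtype=float)
        gc3 = data["GC3"].to_numpy(dtype=float)
    gc12 = np.asarray(gc12, dtype=float)
    gc3 = np.asarray(gc3, dtype=float)
    keep = ~(np.isnan(gc12) | np.isnan(gc3))
    gc12, gc3 = gc12[keep], gc3[keep]
    if gc12.size < 3:
        raise CubkitError("neutrality fit needs ≥ 3 points")
    if np.ptp(gc3) == 0:
        raise CubkitError("zero variance in GC3: slope undefined")
    if np.ptp(gc12) == 0:
        # flat response: slope 0, correlation defined as 0
        return NeutralityFit(
            slope=0.0,
            intercept=float(gc12[0]),
            pearson_r=0.0,
            p_value=1.0,
            n=int(gc12.size),
            method=method,
        )
    lr = stats.linregress(gc3, gc12)
    if method == "ols":
        slope, intercept = float(lr.slope), float(lr.intercept)
    elif method == "rma":
        slope = float(
            np.sign(lr.rvalue if lr.rvalue != 0 else 1.0)
            * np.std(gc12, ddof=1)
            / np.std(gc3, ddof=1)
        )
        intercept = float(np.mean(gc12) - slope * np.mean(gc3))
    else:
        raise CubkitError(f"unknown regression method {method!r}")
    return NeutralityFit(
        slope=slope,
        intercept=intercept,
        pearson_r=float(lr.rvalue),
        p_value=float(lr.pvalue),
        n=int(gc12.size),
        method=method,
    )


class NeutralityRegression(RegressorMixin, BaseEstimator):
    """Estimator form of the neutrality-plot fit.

    ``fit(X, y)`` takes GC3 as X (1 column) and GC12 as y; fitted
    attributes are ``slope_``, ``intercept_``, ``pearson_r_``,
    ``p_value_`` and ``n_``.
    """

    def __init__(self, method: str = "ols"):
        self.method = method

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        if X.ndim == 2:
            if X.shape[1] != 1:
                raise CubkitError("NeutralityRegression expects one feature")
            X = X[:, 0]
        res = neutrality_fit(gc12=np.asarray(y), gc3=X, method=self.method)
        self.slope_ = res.slope
        self.intercept_ = res.intercept
        self.pearson_r_ = res.pearson_r
        self.p_value_ = res.p_value
        self.n_ = res.n
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        if X.ndim == 2:
            X = X[:, 0]
        return self.intercept_ + self.slope_ * X


def spearman_matrix(
    rows: pd.DataFrame,
    adjust: str = "none",
    variables: list[str] | None = None,
) -> CorrelationMatrix:
    """Spearman rho/p matrices over the columns of a per-sequence table.

    Constant columns get NaN rows/columns (flagged, not fatal). ``adjust``
    may be ``"bh"`` for Benjamini–Hochberg adjustment of the off-diagonal
    p-values.
    """
    df = rows[variables] if variables is not None else rows
    df = df.select_dtypes("number")
    if len(df) < 4:
        raise CubkitError("spearman_matrix needs ≥ 4 rows")
    cols = list(df.columns)
    k = len(cols)
    rho = np.full((k, k), np.nan)
    p = np.full((k, k), np.nan)
    const = [c for c in cols if df[c].nunique(dropna=True) < 2]
    for i in range(k):
        for j in range(i, k):
            if cols[i] in const or cols[j] in const:
                continue
            if i == j:
                rho[i, j] = 1.0
                p[i, j] = 0.0
                continue
            r, pv = stats.spearmanr(df[cols[i]], df[cols[j]],
                                    nan_policy="omit")
            rho[i, j] = rho[j, i] = r
            p[i, j] = p[j, i] = pv
    rho_df = pd.DataFrame(rho, index=cols, columns=cols)
    p_df = pd.DataFrame(p, index=cols, columns=cols)
    adj_df = None
    if adjust == "bh":
        iu = np.triu_indices(k, 1)
        flat = p[iu]
        ok = ~np.isnan(flat)
        adj = np.full_like(flat, np.nan)
        if ok.any():
            adj[ok] = multipletests(flat[ok], method="fdr_bh")[1]
        mat = np.full((k, k), np.nan)
        mat[iu] = adj
        mat.T[iu] = adj
        np.fill_diagonal(mat, 0.0)
        adj_df = pd.DataFrame(mat, index=cols, columns=cols)
    elif adjust != "none":
        raise CubkitError(f"unknown adjustment {adjust!r}")
    return CorrelationMatrix(
        variables=cols, rho=rho_df, p=p_df, adjusted_p=adj_df
    )
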