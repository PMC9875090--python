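"""Correspondence analysis of the sequence × codon RSCU matrix.

Standard CA: the non-negative table is divided by its grand total, the
matrix of standardized residuals

    S = D_r^{-1/2} (P - r c^T) D_c^{-1/2}

is formed from the row and column masses, and its singular value
decomposition gives principal inertias λ_k = σ_k² and principal
coordinates (standard coordinates scaled by the singular values). Axis k's
share of the total inertia (the "relative inertia") is λ_k / Σλ. The sign
of each axis is fixed by forcing its largest-magnitude column loading
positive, so results are reproducible across SVD backends.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .errors import CubkitError


@dataclass
class COAResult:
    row_coords: pd.DataFrame
    col_coords: pd.DataFrame
    inertias: np.ndarray
    proportions: np.ndarray
    n_axes: int
    total_inertia: float

    @property
    def degenerate(self) -> bool:
        """True when the table carries no variation (zero total inertia)."""
        return self.total_inertia <= 1e-12


def correspondence_analysis(
    matrix: pd.DataFrame, n_axes: int | None = None
) -> COAResult:
    """CA of a non-negative table (rows: sequences, columns: codons).

    All-zero rows/columns are dropped with a warning; NaN entries are not
    allowed (fill missing RSCU with 0 upstream, e.g.
    ``RSCUTransformer(fill_missing=True)``).
    """
    X = matrix.to_numpy(dtype=float)
    if np.isnan(X).any():
        raise CubkitError("CA input contains NaN; fill missing values first")
    if (X < 0).any():
        raise CubkitError("CA input must be non-negative")
    row_keep = X.sum(axis=1) > 0
    col_keep = X.sum(axis=0) > 0
    if not row_keep.all() or not col_keep.all():
        warnings.warn(
            f"dropping {int((~row_keep).sum())} all-zero rows and "
            f"{int((~col_keep).sum())} all-zero columns before CA"
        )
        X = X[np.ix_(row_keep, col_keep)]
    index = matrix.index[row_keep]
    columns = matrix.columns[col_keep]
    n_rows, n_cols = X.shape
    if n_rows < 2 or n_cols < 2:
        raise CubkitError("CA needs ≥ 2 rows and ≥ 2 columns")

    P = X / X.sum()
    r = P.sum(axis=1)
    c = P.sum(axis=0)
    S = (P - np.outer(r, c)) / np.sqrt(np.outer(r, c))
    U, sv, Vt = np.linalg.svd(S, full_matrices=False)

    max_axes = min(n_rows - 1, n_cols - 1)
    k = max_axes if n_axes is None else min(n_axes, max_axes)
    U, sv, Vt = U[:, :max_axes], sv[:max_axes], Vt[:max_axes]

    # reproducible sign: largest |column loading| positive on each axis
    for a in range(max_axes):
        j = int(np.argmax(np.abs(Vt[a])))
        if Vt[a, j] < 0:
            Vt[a] *= -1.0
            U[:, a] *= -1.0

    inertias = sv**2
    total = float(inertias.sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        proportions = (
            inertias / total if total > 0 else np.full_like(inertias, np.nan)
        )
    row_coords = (U * sv) / np.sqrt(r)[:, None]
    col_coords = (Vt.T * sv) / np.sqrt(c)[:, None]
    axes = [f"axis{i + 1}" for i in range(max_axes)]
    return COAResult(
        row_coords=pd.DataFrame(row_coords[:, :k], index=index,
                                columns=axes[:k]),
        col_coords=pd.DataFrame(col_coords[:, :k], index=columns,
                                columns=axes[:k]),
        inertias=inertias[:k],
        proportions=proportions[:k],
        n_axes=k,
        total_inertia=total,
    )


def axis_summary(result: COAResult, k: int = 2) -> dict:
    """Leading-k axis proportions and row coordinates, plot-ready.

    Returns raw proportions of total inertia and, because published CA
    plots sometimes renormalise the two displayed axes over themselves,
    the first-k-renormalised shares as well.
    """
    if k > result.n_axes:
        warnings.warn(
            f"requested {k} axes but only {result.n_axes} available; "
            "clipping"
        )
        k = result.n_axes
    props = result.proportions[:k]
    sub = props.sum()
    return {
        "proportions": props,
        "proportions_renormalized": (
            props / sub if sub > 0 else np.full(k, np.nan)
        ),
        "row_coords": result.row_coords.iloc[:, :k],
    }


class CorrespondenceAnalysis(TransformerMixin, BaseEstimator):
    """sklearn-style CA decomposition.

    Parameters
    ----------
    n_components : int
        Number of axes retained in the fitted coordinates.

    Attributes
    ----------
    row_coords_, col_coords_ : DataFrame
        Principal coordinates of rows (sequences) and columns (codons).
    inertias_ : ndarray
        Principal inertias λ_k, non-increasing.
    proportions_ : ndarray
        λ_k / Σλ shares of total inertia.
    """

    def __init__(self, n_components: int = 2):
        self.n_components = n_components

    def fit(self, X: pd.DataFrame, y=None):
        if not isinstance(X, pd.DataFrame):
            X = pd.DataFrame(np.asarray(X, dtype=float))
        res = correspondence_analysis(X, n_axes=self.n_components)
        self.result_ = res
        self.row_coords_ = res.row_coords
        self.col_coords_ = res.col_coords
        self.inertias_ = res.inertias
        self.proportions_ = res.proportions
        self.total_inertia_ = res.total_inertia
        self.n_features_in_ = X.shape[1]
        return self

    def fit_transform(self, X, y=None):
        return self.fit(X).row_coords_.to_numpy()

    def transform(self, X=None):
        return self.row_coords_.to_numpy()
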