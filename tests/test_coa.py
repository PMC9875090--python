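import numpy as np
import pandas as pd
import pytest

import cubkit as ck
from cubkit.coa import (
    CorrespondenceAnalysis,
    axis_summary,
    correspondence_analysis,
)
from cubkit.errors import CubkitError


def inertia_oracle(X):
    """Principal inertias via eigendecomposition of the chi-square
    residual cross-product — independent of the SVD route."""
    P = X / X.sum()
    r, c = P.sum(axis=1), P.sum(axis=0)
    S = (P - np.outer(r, c)) / np.sqrt(np.outer(r, c))
    eig = np.linalg.eigvalsh(S @ S.T)
    return np.sort(eig)[::-1]


def random_table(rng, shape=(8, 10)):
    return pd.DataFrame(rng.uniform(0.1, 3.0, size=shape))


class TestCA:
    def test_identical_rows_degenerate(self):
        X = pd.DataFrame(np.tile([1.0, 2.0, 3.0], (4, 1)))
        res = correspondence_analysis(X)
        assert res.degenerate
        assert np.isnan(res.proportions).all()

    def test_two_profile_structure_is_rank_one(self):
        X = pd.DataFrame(
            [[1, 2, 3, 1, 1, 2.0],
             [2, 4, 6, 2, 2, 4.0],
             [3, 1, 1, 2, 4, 1.0],
             [6, 2, 2, 4, 8, 2.0]]
        )
        res = correspondence_analysis(X)
        assert res.proportions[0] == pytest.approx(1.0, abs=1e-9)

    def test_matches_eigendecomposition_oracle(self, rng):
        for _ in range(5):
            X = random_table(rng)
            res = correspondence_analysis(X)
            expected = inertia_oracle(X.to_numpy())[: res.n_axes]
            assert np.allclose(res.inertias, expected, atol=1e-8)

    def test_proportions_sum_to_one(self, rng):
        res = correspondence_analysis(random_table(rng))
        assert res.proportions.sum() == pytest.approx(1.0, abs=1e-9)
        assert (np.diff(res.inertias) <= 1e-12).all()  # non-increasing

    def test_axis_count_bound(self, rng):
        res = correspondence_analysis(random_table(rng, (5, 12)))
        assert res.n_axes <= 4

    def test_total_inertia_conserved(self, rng):
        X = random_table(rng)
        res = correspondence_analysis(X)
        P = X.to_numpy() / X.to_numpy().sum()
        r, c = P.sum(axis=1), P.sum(axis=0)
        chi2 = ((P - np.outer(r, c)) ** 2 / np.outer(r, c)).sum()
        assert res.total_inertia == pytest.approx(chi2, abs=1e-9)

    def test_row_permutation_equivariance(self, rng):
        X = random_table(rng)
        perm = rng.permutation(len(X))
        r1 = correspondence_analysis(X)
        r2 = correspondence_analysis(X.iloc[perm])
        assert np.allclose(r1.inertias, r2.inertias)
        assert np.allclose(
            r1.row_coords.to_numpy()[perm], r2.row_coords.to_numpy()
        )

    def test_doubling_invariance(self, rng):
        X = random_table(rng)
        r1 = correspondence_analysis(X)
        r2 = correspondence_analysis(2 * X)
        assert np.allclose(r1.proportions, r2.proportions)
        assert np.allclose(
            r1.row_coords.to_numpy(), r2.row_coords.to_numpy()
        )

    def test_zero_rows_dropped_with_warning(self, rng):
        X = random_table(rng)
        X.iloc[3] = 0.0
        with pytest.warns(UserWarning, match="all-zero"):
            res = correspondence_analysis(X)
        assert len(res.row_coords) == 7

    def test_too_small_is_error(self):
        with pytest.raises(CubkitError):
            correspondence_analysis(pd.DataFrame([[1.0, 2.0]]))

    def test_nan_rejected(self):
        X = pd.DataFrame([[1.0, np.nan], [2.0, 3.0]])
        with pytest.raises(CubkitError, match="NaN"):
            correspondence_analysis(X)


class TestAxisSummary:
    def test_rank_two_matrix(self, rng):
        # three distinct row profiles → rank-2 residual
        base = rng.uniform(0.5, 2.0, size=(3, 8))
        X = pd.DataFrame(np.vstack([base, base * [[1.0]] * 3]))
        summary = axis_summary(correspondence_analysis(X), k=2)
        assert summary["proportions"].sum() == pytest.approx(1.0, abs=1e-9)
        assert summary["proportions_renormalized"].sum() == (
            pytest.approx(1.0)
        )

    def test_k_zero(self, rng):
        summary = axis_summary(correspondence_analysis(random_table(rng)),
                               k=0)
        assert len(summary["proportions"]) == 0

    def test_k_clipped_with_warning(self, rng):
        res = correspondence_analysis(random_table(rng, (3, 5)))
        with pytest.warns(UserWarning, match="clipping"):
            summary = axis_summary(res, k=10)
        assert len(summary["proportions"]) == res.n_axes

    def test_three_cluster_separation(self, code):
        """Axis 1 separates panels generated from distinct usage models."""
        rng = np.random.default_rng(55)
        seqs = []
        for label, gc3 in (("lo", 0.12), ("mid", 0.45), ("hi", 0.8)):
            model = ck.usage_model(gc3=gc3)
            seqs += [
                ck.sample_cds(model, 300, rng, seq_id=f"{label}_{i}")
                for i in range(6)
            ]
        m = ck.RSCUTransformer(code, fill_missing=True).fit_transform(seqs)
        res = correspondence_analysis(m)
        ax1 = res.row_coords["axis1"]
        lo = ax1[[i for i in ax1.index if i.startswith("lo")]]
        hi = ax1[[i for i in ax1.index if i.startswith("hi")]]
        # extreme clusters do not overlap on axis 1
        assert lo.max() < hi.min() or hi.max() < lo.min()


def test_estimator_interface(rng):
    X = random_table(rng)
    est = CorrespondenceAnalysis(n_components=2).fit(X)
    assert est.row_coords_.shape == (8, 2)
    assert est.col_coords_.shape == (10, 2)
    assert est.proportions_.shape == (2,)
    coords = est.fit_transform(X)
    assert np.allclose(coords, est.row_coords_.to_numpy())
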