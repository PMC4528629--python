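import math

import numpy as np
import pytest

from sparsepc import (
    CenteredMatrix,
    RspcaConfig,
    ThresholdSpec,
    angle_degrees,
    bic,
    center_columns,
    fit_rank_one_penalized,
    gic,
    lambda_grid,
    make_spike_model,
    rank_one_svd,
    rspca,
    sample_data,
    sigma2_hat,
)
from sparsepc.core import SparseFit


def matrix_with_singular_values(rng, n, p, values):
    """Build a matrix with prescribed singular values via random orthonormal bases."""
    U, _ = np.linalg.qr(rng.standard_normal((n, n)))
    V, _ = np.linalg.qr(rng.standard_normal((p, p)))
    k = len(values)
    A = U[:, :k] @ np.diag(values) @ V[:, :k].T
    ids_f = [f"f{i}" for i in range(p)]
    ids_s = [f"s{i}" for i in range(n)]
    return CenteredMatrix(A - A.mean(axis=0), ids_f, ids_s, centered=True)


class TestSigma2Hat:
    def test_exact_rank_one_gives_zero(self, rng):
        a = rng.standard_normal(6)
        a -= a.mean()
        b = rng.standard_normal(4)
        X = CenteredMatrix(np.outer(a, b), list("abcd"), [f"s{i}" for i in range(6)],
                           centered=True)
        assert sigma2_hat(X) == pytest.approx(0.0, abs=1e-12)

    def test_known_singular_values(self, rng):
        # singular values {4, 3}: residual after removing the leading one is 9
        X = matrix_with_singular_values(rng, 5, 5, [4.0, 3.0])
        s = np.linalg.svd(X.values, compute_uv=False)
        expected = np.sum(s[1:] ** 2) / 25
        assert sigma2_hat(X) == pytest.approx(expected, abs=1e-10)
        assert expected == pytest.approx(9.0 / 25.0, abs=0.05)

    def test_scale_equivariance(self, small_matrix):
        doubled = CenteredMatrix(2 * small_matrix.values, small_matrix.feature_ids,
                                 small_matrix.sample_ids, centered=True)
        assert sigma2_hat(doubled) == pytest.approx(4 * sigma2_hat(small_matrix),
                                                    rel=1e-10)


def perfect_fit(n, p, df):
    v = np.zeros(p)
    v[:df] = 1 / np.sqrt(df)
    u = np.zeros(n)
    u[0] = 1.0
    return SparseFit(d=0.0, u=u, v=v, support=np.arange(df), method="pca")


class TestCriteria:
    def test_bic_penalty_only_for_perfect_fit(self):
        n, p, df = 10, 20, 3
        X = CenteredMatrix(np.zeros((n, p)), [f"f{i}" for i in range(p)],
                           [f"s{i}" for i in range(n)], centered=True)
        fit = perfect_fit(n, p, df)
        assert bic(X, fit, sigma2=1.0) == pytest.approx(3 * math.log(200) / 200)

    def test_bic_empty_fit_normalized_residual(self, rng):
        X = center_columns(rng.standard_normal((10, 20)))
        sigma2 = float(np.sum(X.values**2)) / 200
        fit = SparseFit(d=0.0, u=np.zeros(10), v=np.zeros(20),
                        support=np.array([], dtype=int), method="pca", empty=True)
        assert bic(X, fit, sigma2) == pytest.approx(1.0)

    def test_bic_hand_computed_on_fixed_matrix(self):
        A = np.array(
            [[1, 2, 0, -1, 3, 1],
             [0, -2, 1, 2, -1, 0],
             [2, 1, -1, 0, 1, -2],
             [-3, -1, 0, -1, -3, 1]], dtype=float)
        X = center_columns(A)
        v = np.zeros(6)
        v[[0, 4]] = [0.6, 0.8]
        u = np.array([0.5, -0.5, 0.5, -0.5])
        fit = SparseFit(d=2.0, u=u, v=v, support=np.array([0, 4]), method="pca")
        # independent arithmetic: residual computed entry by entry in python
        resid = 0.0
        for j in range(4):
            for i in range(6):
                resid += (X.values[j, i] - 2.0 * u[j] * v[i]) ** 2
        sigma2 = 0.9
        expected = resid / (24 * sigma2) + 2 * math.log(24) / 24
        assert bic(X, fit, sigma2) == pytest.approx(expected, rel=1e-12)

    def test_gic_penalty_closed_form(self):
        n, p, df = 10, 20, 3
        X = CenteredMatrix(np.zeros((n, p)), [f"f{i}" for i in range(p)],
                           [f"s{i}" for i in range(n)], centered=True)
        fit = perfect_fit(n, p, df)
        expected = 3 * math.log(math.log(200)) * math.log(20) / 200
        assert gic(X, fit, 1.0) == pytest.approx(expected)
        assert expected == pytest.approx(0.07494, abs=5e-5)

    def test_gic_empty_fit_residual_only(self, rng):
        X = center_columns(rng.standard_normal((10, 20)))
        fit = SparseFit(d=0.0, u=np.zeros(10), v=np.zeros(20),
                        support=np.array([], dtype=int), method="pca", empty=True)
        assert gic(X, fit, 2.0) == pytest.approx(
            float(np.sum(X.values**2)) / (200 * 2.0))

    @pytest.mark.parametrize("n,p", [(50, 1000), (10, 20)])
    def test_gic_vs_bic_penalty_ordering(self, n, p):
        np_ = n * p
        gic_factor = math.log(math.log(np_)) * math.log(p)
        bic_factor = math.log(np_)
        assert (gic_factor > bic_factor) == (
            math.log(math.log(np_)) * math.log(p) > math.log(np_))
        if p == 1000:
            assert gic_factor > bic_factor  # GIC is stricter at p >> n

    def test_nonpositive_sigma2_rejected(self, small_matrix):
        fit = rank_one_svd(small_matrix)
        with pytest.raises(ValueError):
            bic(small_matrix, fit, 0.0)
        with pytest.raises(ValueError):
            gic(small_matrix, fit, -1.0)


class TestLambdaGrid:
    def test_endpoints_for_size_two(self, small_matrix):
        u0 = rank_one_svd(small_matrix).u
        lam_max = np.max(np.abs(small_matrix.values.T @ u0))
        grid = lambda_grid(small_matrix, u0, size=2)
        np.testing.assert_allclose(grid, [lam_max, 1e-3 * lam_max])

    def test_positive_and_strictly_decreasing(self, small_matrix):
        u0 = rank_one_svd(small_matrix).u
        grid = lambda_grid(small_matrix, u0, size=50)
        assert np.all(grid > 0)
        assert np.all(np.diff(grid) < 0)

    def test_endpoint_fit_behaviour(self, rng):
        X = center_columns(rng.standard_normal((20, 30)))
        base = rank_one_svd(X)
        grid = lambda_grid(X, base.u, size=10)
        empty = fit_rank_one_penalized(
            X, ThresholdSpec(penalty="lasso", lam=float(grid[0])), u0=base.u)
        assert empty.empty
        dense = fit_rank_one_penalized(
            X, ThresholdSpec(penalty="lasso", lam=float(grid[-1])), u0=base.u)
        assert dense.df >= 0.9 * X.p


class TestFitRankOnePenalized:
    def test_unpenalized_limit_matches_svd(self, small_matrix):
        base = rank_one_svd(small_matrix)
        fit = fit_rank_one_penalized(
            small_matrix, ThresholdSpec(penalty="lasso", lam=0.0), u0=base.u,
            tol=1e-10, max_iter=1000)
        # arccos is ill-conditioned near 0 degrees; compare loadings directly
        np.testing.assert_allclose(fit.v, base.v, atol=1e-8)
        assert angle_degrees(fit.v, base.v) < 1e-4
        assert fit.d == pytest.approx(base.d, rel=1e-8)

    def test_full_shrinkage_gives_empty_fit(self, small_matrix):
        base = rank_one_svd(small_matrix)
        lam = float(np.max(np.abs(small_matrix.values.T @ base.u))) + 1e-9
        fit = fit_rank_one_penalized(
            small_matrix, ThresholdSpec(penalty="lasso", lam=lam), u0=base.u)
        assert fit.empty and fit.d == 0.0 and fit.support.size == 0

    def test_unit_norms_and_support_invariant(self, spike_data):
        X, _ = spike_data
        base = rank_one_svd(X)
        fit = fit_rank_one_penalized(
            X, ThresholdSpec(penalty="lasso", lam=2.0), u0=base.u)
        assert np.linalg.norm(fit.u) == pytest.approx(1.0, abs=1e-8)
        assert np.linalg.norm(fit.v) == pytest.approx(1.0, abs=1e-8)
        np.testing.assert_array_equal(fit.support, np.flatnonzero(fit.v))
        assert fit.d == pytest.approx(float(fit.u @ X.values @ fit.v), abs=1e-8)

    def test_moderate_lambda_recovers_true_support(self):
        # strong-signal regime: the full true support survives moderate shrinkage
        model = make_spike_model(200, 0.8, 0.4)
        hits = 0
        for rep in range(100):
            X = sample_data(model, 50, np.random.default_rng(5000 + rep))
            base = rank_one_svd(X)
            lam = 0.3 * float(np.max(np.abs(X.values.T @ base.u)))
            fit = fit_rank_one_penalized(
                X, ThresholdSpec(penalty="lasso", lam=lam), u0=base.u)
            if set(model.support_true).issubset(set(fit.support.tolist())):
                hits += 1
        assert hits >= 95

    def test_nonunit_u0_normalized_with_warning(self, small_matrix):
        base = rank_one_svd(small_matrix)
        with pytest.warns(UserWarning, match="normaliz"):
            fit = fit_rank_one_penalized(
                small_matrix, ThresholdSpec(penalty="lasso", lam=0.1), u0=2 * base.u)
        assert np.linalg.norm(fit.u) == pytest.approx(1.0, abs=1e-8)


class TestRspca:
    def test_beats_conventional_pca_on_spike_grid(self):
        model = make_spike_model(300, 0.8, 0.4)
        rspca_angles, pca_angles = [], []
        for rep in range(20):
            X = sample_data(model, 50, np.random.default_rng(9000 + rep))
            fit = rspca(X, RspcaConfig(penalty="lasso"))[0]
            rspca_angles.append(angle_degrees(fit.v, model.v_true))
            pca_angles.append(angle_degrees(rank_one_svd(X).v, model.v_true))
        assert np.median(rspca_angles) < np.median(pca_angles)

    def test_gic_at_least_as_sparse_as_bic(self):
        model = make_spike_model(300, 0.6, 0.4)
        wins = 0
        for rep in range(20):
            X = sample_data(model, 50, np.random.default_rng(4000 + rep))
            gic_fit = rspca(X, RspcaConfig(penalty="lasso", criterion="gic"))[0]
            bic_fit = rspca(X, RspcaConfig(penalty="lasso", criterion="bic"))[0]
            if gic_fit.df <= bic_fit.df:
                wins += 1
        assert wins >= 16  # GIC penalizes model size harder when p >> n

    def test_two_planted_components_recovered(self, rng):
        n, p = 60, 40
        u1 = np.zeros(n); u1[: n // 2] = 1.0; u1 -= u1.mean(); u1 /= np.linalg.norm(u1)
        u2 = np.zeros(n); u2[::2] = 1.0; u2 -= u2.mean(); u2 /= np.linalg.norm(u2)
        u2 -= (u2 @ u1) * u1; u2 /= np.linalg.norm(u2)
        v1 = np.zeros(p); v1[:5] = 1 / np.sqrt(5)
        v2 = np.zeros(p); v2[10:15] = 1 / np.sqrt(5)
        A = 30 * np.outer(u1, v1) + 15 * np.outer(u2, v2)
        A += 0.1 * rng.standard_normal((n, p))
        X = center_columns(A)
        fits = rspca(X, RspcaConfig(penalty="lasso", n_pcs=2))
        assert set(fits[0].support.tolist()) == set(range(5))
        assert set(fits[1].support.tolist()) == set(range(10, 15))

    def test_criterion_path_monotonicity(self, spike_data):
        X, _ = spike_data
        fits, paths = rspca(X, RspcaConfig(penalty="lasso"), return_paths=True)
        path = paths[0].sort_values("lambda", ascending=False)
        np_sigma = X.n * X.p
        # df non-increasing as lambda increases (path is sorted decreasing)
        assert np.all(np.diff(path["df"].to_numpy()) >= 0)
        # residual term non-increasing as lambda decreases
        resid = path["criterion"].to_numpy() - path["df"].to_numpy() * np.log(
            np.log(np_sigma)) * np.log(X.p) / np_sigma
        assert np.all(np.diff(resid) <= 1e-8)

    def test_deterministic_given_input(self, spike_data):
        X, _ = spike_data
        f1 = rspca(X, RspcaConfig(penalty="scad"))[0]
        f2 = rspca(X, RspcaConfig(penalty="scad"))[0]
        np.testing.assert_array_equal(f1.v, f2.v)
        assert f1.lam == f2.lam

    def test_config_validation(self):
        with pytest.raises(ValueError):
            RspcaConfig(criterion="aic")
        with pytest.raises(ValueError):
            RspcaConfig(lambda_grid_size=1)
        with pytest.raises(ValueError):
            RspcaConfig(tol=0.0)
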