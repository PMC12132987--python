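"""Coordinate-descent solvers: oracle equivalence, KKT, reductions."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from bnt.exceptions import ConvergenceError, DataError
from bnt.mle import fit_mle_binomial, fit_mle_continuous
from bnt.model import loglik_binomial
from bnt.penalized import (
    PenaltySpec,
    adaptive_weights,
    cd_update_logistic,
    cd_update_normal,
    fit_cd_logistic,
    fit_cd_normal,
    fit_penalized,
    irls_quadratic,
    lambda_grid,
    lambda_max_logistic,
    lambda_max_normal,
    objective_logistic,
    objective_normal,
    path_logistic,
    path_normal,
    sigma_from_beta2,
    soft_threshold,
)
from bnt.mle import score_binomial
from helpers import grid_search_1d, random_dataset, solve_l1_lbfgsb


class TestSoftThreshold:
    @pytest.mark.parametrize(
        "a, b, expected",
        [(3, 1, 2), (-3, 1, -2), (1, 2, 0), (-1, 2, 0), (0, 0, 0), (2.5, 2.5, 0)],
    )
    def test_cases(self, a, b, expected):
        assert soft_threshold(a, b) == expected

    def test_negative_threshold_rejected(self):
        with pytest.raises(DataError):
            soft_threshold(1.0, -0.1)

    @settings(max_examples=50, deadline=None)
    @given(st.floats(-100, 100), st.floats(0, 100))
    def test_shrinks_toward_zero_by_at_most_b(self, a, b):
        s = soft_threshold(a, b)
        assert abs(s) <= abs(a)
        assert abs(a - s) <= b + 1e-12


class TestCoordinateUpdates:
    def test_normal_update_unpenalized_is_least_squares_step(self, small_dataset):
        ds = small_dataset
        beta = np.zeros(ds.q2 + 1)
        new = cd_update_normal(1, beta, ds, 0.0, 1.0)
        pos = ds.positive
        zk = ds.Z2[pos, 1]
        expected = float(zk @ ds.x[pos]) / float(zk @ zk)
        assert new == pytest.approx(expected, rel=1e-10)

    def test_normal_update_matches_grid_search(self, rng):
        ds = random_dataset(rng, n=12, q=2)
        beta = rng.normal(0, 0.5, 3)
        lam, omega_k = 1.0, 1.3
        k = 2

        def f(b):
            trial = beta.copy()
            trial[k] = b
            return objective_normal(trial, ds, lam, np.array([1.0, omega_k]))

        best = grid_search_1d(f)
        assert cd_update_normal(k, beta, ds, lam, omega_k) == pytest.approx(
            best, abs=1e-3
        )

    def test_logistic_update_matches_grid_search(self, rng):
        ds = random_dataset(rng, n=10, q=2)
        beta = rng.normal(0, 0.5, 3)
        state = irls_quadratic(beta, ds)
        lam, omega_k = 1.0, 0.8
        k = 1

        def quad_obj(b):
            trial = beta.copy()
            trial[k] = b
            r = state.gamma - ds.Z1 @ trial
            return float(np.sum(state.w * r * r)) + lam * omega_k * abs(b)

        best = grid_search_1d(quad_obj)
        assert cd_update_logistic(k, beta, state, ds, lam, omega_k) == pytest.approx(
            best, abs=1e-3
        )

    def test_orthogonal_partial_residual_gives_zero(self, rng):
        # response built orthogonal to column 1 on the nonzero rows
        n = 20
        Z = np.column_stack([np.ones(n), rng.standard_normal(n)])
        x = np.ones(n)  # constant: orthogonal to centered covariate
        Z[:, 1] -= Z[:, 1].mean()
        from bnt.data import SemicontinuousDataset

        ds = SemicontinuousDataset(x, np.ones(n, dtype=int), Z, Z)
        beta = np.array([1.0, 0.0])
        assert cd_update_normal(1, beta, ds, 0.5, 1.0) == 0.0


class TestIRLSQuadratic:
    def test_expansion_at_zero(self, small_dataset):
        state = irls_quadratic(np.zeros(small_dataset.q1 + 1), small_dataset)
        np.testing.assert_allclose(state.w, 0.25)
        np.testing.assert_allclose(state.gamma, 4.0 * (small_dataset.y - 0.5))

    def test_perfect_fit_work_response_is_linear_predictor(self):
        # y_i equal to p(z_i) exactly => gamma = eta
        from bnt.data import SemicontinuousDataset

        Z = np.ones((2, 1))
        ds = SemicontinuousDataset(
            np.array([0.0, 1.0]), np.array([0, 1]), Z, Z
        )
        state = irls_quadratic(np.array([0.0]), ds)
        # y - p = (-0.5, 0.5): gamma = eta + (y-p)/w = (-2, 2)
        np.testing.assert_allclose(state.gamma, [-2.0, 2.0])

    def test_gradient_matches_score_at_expansion_point(self, rng):
        ds = random_dataset(rng, n=30, q=3)
        beta = rng.normal(0, 0.5, 4)
        state = irls_quadratic(beta, ds)
        # d/db [-sum w (gamma - z'b)^2] at b = beta equals 2 * score
        grad_quad = 2.0 * ds.Z1.T @ (state.w * (state.gamma - ds.Z1 @ beta))
        np.testing.assert_allclose(
            grad_quad, 2.0 * score_binomial(beta, ds), atol=1e-8
        )


class TestFitCDNormal:
    def test_full_shrinkage_at_lambda_max(self, small_dataset):
        lmax = lambda_max_normal(small_dataset)
        fit = fit_cd_normal(small_dataset, lmax * 1.0001)
        assert fit.active_set.size == 0
        assert np.all(fit.beta[1:] == 0.0)
        xbar = small_dataset.x[small_dataset.positive].mean()
        assert fit.beta[0] == pytest.approx(xbar, rel=1e-6)

    def test_unpenalized_equals_least_squares(self, small_dataset):
        fit = fit_cd_normal(small_dataset, 0.0)
        ref, _sigma, _ = fit_mle_continuous(small_dataset)
        np.testing.assert_allclose(fit.beta, ref, atol=1e-8)

    def test_kkt_conditions_at_solution(self, rng):
        ds = random_dataset(rng, n=40, q=4)
        omega = rng.uniform(0.5, 2.0, 4)
        lam = 0.3 * lambda_max_normal(ds, omega)
        fit = fit_cd_normal(ds, lam, omega)
        pos = ds.positive
        grad = 2.0 * ds.Z2[pos].T @ (ds.x[pos] - ds.Z2[pos] @ fit.beta)
        tol = 1e-4
        for j in range(1, ds.q2 + 1):
            bound = lam * omega[j - 1]
            if fit.beta[j] != 0:
                assert abs(abs(grad[j]) - bound) < tol
            else:
                assert abs(grad[j]) <= bound + tol
        assert abs(grad[0]) < tol  # unpenalized intercept at optimum


class TestFitCDLogistic:
    def test_full_shrinkage_at_lambda_max(self, small_dataset):
        lmax = lambda_max_logistic(small_dataset)
        fit = fit_cd_logistic(small_dataset, lmax * 1.0001)
        assert fit.active_set.size == 0
        ybar = small_dataset.y.mean()
        assert fit.beta[0] == pytest.approx(np.log(ybar / (1 - ybar)), abs=1e-5)

    def test_unpenalized_matches_newton_mle(self, small_dataset):
        fit = fit_cd_logistic(small_dataset, 0.0)
        ref, _ = fit_mle_binomial(small_dataset)
        np.testing.assert_allclose(fit.beta, ref, atol=1e-6)

    def test_objective_not_worse_than_mle_start(self, rng):
        ds = random_dataset(rng, n=50, q=3)
        lam = 0.2 * lambda_max_logistic(ds)
        fit = fit_cd_logistic(ds, lam)
        mle, _ = fit_mle_binomial(ds)
        assert objective_logistic(fit.beta, ds, lam) <= objective_logistic(
            mle, ds, lam
        ) + 1e-8


class TestOracleEquivalence:
    """Penalized objectives at the CD solutions match a generic convex
    solver (bound-constrained L-BFGS-B on the positive/negative split)."""

    @pytest.mark.parametrize("seed", range(8))
    def test_normal_part(self, seed):
        rng = np.random.default_rng(seed)
        ds = random_dataset(rng, n=rng.integers(25, 60), q=rng.integers(2, 5))
        omega = rng.uniform(0.5, 3.0, ds.q2)
        lam = float(rng.uniform(0.05, 0.6)) * lambda_max_normal(ds, omega)
        fit = fit_cd_normal(ds, lam, omega)
        pos = ds.positive
        Zp, xp = ds.Z2[pos], ds.x[pos]
        pen = np.concatenate([[0.0], omega])

        def f(b):
            r = xp - Zp @ b
            return float(r @ r)

        def g(b):
            return -2.0 * Zp.T @ (xp - Zp @ b)

        _beta, obj_ref = solve_l1_lbfgsb(f, g, lam, pen, Zp.shape[1])
        obj_cd = objective_normal(fit.beta, ds, lam, omega)
        assert obj_cd <= obj_ref + 1e-5
        assert obj_cd >= obj_ref - 1e-5

    @pytest.mark.parametrize("seed", range(8))
    def test_logistic_part(self, seed):
        rng = np.random.default_rng(100 + seed)
        ds = random_dataset(rng, n=rng.integers(30, 60), q=rng.integers(2, 5))
        omega = rng.uniform(0.5, 3.0, ds.q1)
        lam = float(rng.uniform(0.05, 0.6)) * lambda_max_logistic(ds, omega)
        fit = fit_cd_logistic(ds, lam, omega)
        pen = np.concatenate([[0.0], omega])

        def f(b):
            return -2.0 * loglik_binomial(b, ds)

        def g(b):
            return -2.0 * score_binomial(b, ds)

        _beta, obj_ref = solve_l1_lbfgsb(f, g, lam, pen, ds.q1 + 1)
        obj_cd = objective_logistic(fit.beta, ds, lam, omega)
        assert obj_cd <= obj_ref + 1e-5
        assert obj_cd >= obj_ref - 1e-5


class TestPaths:
    def test_warm_start_matches_cold_start(self, rng):
        ds = random_dataset(rng, n=50, q=4)
        grid = lambda_grid(lambda_max_normal(ds), 20)
        betas = path_normal(ds, grid)
        for i in [0, 7, 19]:
            cold = fit_cd_normal(ds, grid[i])
            np.testing.assert_allclose(betas[i], cold.beta, atol=1e-6)
        grid1 = lambda_grid(lambda_max_logistic(ds), 20)
        betas1 = path_logistic(ds, grid1)
        for i in [0, 7, 19]:
            cold = fit_cd_logistic(ds, grid1[i])
            np.testing.assert_allclose(betas1[i], cold.beta, atol=1e-5)

    def test_active_set_grows_along_normal_path(self, rng):
        ds = random_dataset(rng, n=60, q=4)
        grid = lambda_grid(lambda_max_normal(ds), 40)
        betas = path_normal(ds, grid)
        sizes = (betas[:, 1:] != 0).sum(axis=1)
        # non-decreasing in the descending-lambda direction
        assert np.all(np.diff(sizes) >= 0) or sizes[-1] >= sizes[0]

    def test_inactive_coefficients_are_bitwise_zero(self, rng):
        ds = random_dataset(rng, n=40, q=4)
        lam = 0.5 * lambda_max_normal(ds)
        fit = fit_cd_normal(ds, lam)
        inactive = np.setdiff1d(np.arange(1, ds.q2 + 1), fit.active_set)
        assert all(fit.beta[j] == 0.0 for j in inactive)


class TestAdaptiveWeights:
    def test_reciprocal_of_mle_magnitude(self, small_dataset):
        omega1, omega2 = adaptive_weights(small_dataset)
        b1, _ = fit_mle_binomial(small_dataset)
        b2, _s, _ = fit_mle_continuous(small_dataset)
        np.testing.assert_allclose(omega1, 1.0 / np.abs(b1[1:]), rtol=1e-10)
        np.testing.assert_allclose(omega2, 1.0 / np.abs(b2[1:]), rtol=1e-10)

    def test_cap_applied_to_tiny_coefficients(self):
        # direct check of the capping rule
        from bnt.penalized import WEIGHT_CAP

        assert WEIGHT_CAP == 1e6
        val = np.minimum(1.0 / np.maximum(np.abs(1e-9), 1.0 / WEIGHT_CAP), WEIGHT_CAP)
        assert val == 1e6


class TestFitPenalized:
    def test_lasso_equals_alasso_with_unit_weights_bitwise(self, rng):
        ds = random_dataset(rng, n=50, q=3)
        lam1 = 0.3 * lambda_max_logistic(ds)
        lam2 = 0.3 * lambda_max_normal(ds)
        lasso = fit_penalized(ds, PenaltySpec("lasso", lam1, lam2))
        alasso = fit_penalized(
            ds,
            PenaltySpec("alasso", lam1, lam2, np.ones(ds.q1), np.ones(ds.q2)),
        )
        assert np.array_equal(lasso.beta1, alasso.beta1)
        assert np.array_equal(lasso.beta2, alasso.beta2)
        assert lasso.sigma == alasso.sigma

    def test_unpenalized_equals_joint_mle(self, small_dataset):
        fit = fit_penalized(small_dataset, PenaltySpec("lasso", 0.0, 0.0))
        b1, _ = fit_mle_binomial(small_dataset)
        b2, sigma, _ = fit_mle_continuous(small_dataset)
        np.testing.assert_allclose(fit.beta1, b1, atol=1e-6)
        np.testing.assert_allclose(fit.beta2, b2, atol=1e-8)
        assert fit.sigma == pytest.approx(sigma, rel=1e-6)

    def test_both_parts_intercept_only_at_lambda_max(self, small_dataset):
        fit = fit_penalized(
            small_dataset,
            PenaltySpec(
                "lasso",
                1.01 * lambda_max_logistic(small_dataset),
                1.01 * lambda_max_normal(small_dataset),
            ),
        )
        assert fit.active_set1.size == 0
        assert fit.active_set2.size == 0

    def test_parts_are_independent(self, rng):
        ds = random_dataset(rng, n=50, q=3)
        lam2 = 0.3 * lambda_max_normal(ds)
        a = fit_penalized(ds, PenaltySpec("lasso", 0.1, lam2))
        b = fit_penalized(ds, PenaltySpec("lasso", 5.0, lam2))
        np.testing.assert_array_equal(a.beta2, b.beta2)
        lam1 = 0.3 * lambda_max_logistic(ds)
        c = fit_penalized(ds, PenaltySpec("lasso", lam1, 0.1))
        d = fit_penalized(ds, PenaltySpec("lasso", lam1, 5.0))
        np.testing.assert_array_equal(c.beta1, d.beta1)

    def test_sigma_is_ml_residual_scale(self, small_dataset):
        lam2 = 0.4 * lambda_max_normal(small_dataset)
        fit = fit_penalized(small_dataset, PenaltySpec("lasso", 0.0, lam2))
        assert fit.sigma == pytest.approx(
            sigma_from_beta2(small_dataset, fit.beta2), rel=1e-12
        )

    def test_degenerate_single_class_rejected(self):
        from bnt.data import SemicontinuousDataset
        from bnt.exceptions import DegenerateDataError

        Z = np.column_stack([np.ones(10), np.arange(10.0)])
        x = np.abs(np.random.default_rng(0).normal(2, 1, 10))
        ds = SemicontinuousDataset(x, np.ones(10, dtype=int), Z, Z)
        with pytest.raises(DegenerateDataError):
            fit_penalized(ds, PenaltySpec("lasso", 1.0, 1.0))
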