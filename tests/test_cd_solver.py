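"""Coordinate-descent solver: closed forms, oracle agreement, KKT
certificates, warm starts, active sets, parallel determinism and the
two hard error surfaces."""

import numpy as np
import pytest

from masslasso import (
    BufferOverflowError,
    CDOptions,
    ConvergenceError,
    MassLasso,
    calculate_lambda_start,
    cd_solve_path,
    cd_solve_voxel,
    compute_crossproducts,
    compute_gram,
    ista_reference,
    kkt_residual,
    objective_value,
    resolve_worker_count,
    soft_threshold,
    zscore_columns,
)
from masslasso.core import MSG_BUFFER_OVERFLOW, MSG_MAX_ITER


def _objective_cols(X, Y, res, li):
    dense = res.coefficients(li)
    lam = res.lambdas[li]
    return np.array([
        objective_value(X, Y[:, j], dense[:, j], res.intercepts[0, j], lam)
        for j in range(Y.shape[1])
    ])


class TestSingleVoxel:
    def test_orthonormal_closed_form(self):
        C = np.eye(2)
        state = cd_solve_voxel(C, np.array([0.8, 0.1]), 0.25)
        np.testing.assert_allclose(state.beta, [0.55, 0.0], atol=1e-12)
        assert state.converged

    def test_zero_solution_above_lambda_start(self, small_design, rng):
        y = rng.standard_normal(30)
        C = compute_gram(small_design)
        c = compute_crossproducts(small_design, y)[:, 0]
        state = cd_solve_voxel(C, c, np.abs(c).max() * 1.01)
        np.testing.assert_array_equal(state.beta, 0.0)
        assert state.converged

    def test_matches_ista_oracle_on_correlated_design(self, rng):
        raw = rng.standard_normal((25, 3))
        raw[:, 2] = raw[:, 0] + 0.3 * rng.standard_normal(25)
        X, _ = zscore_columns(raw)
        y = rng.standard_normal(25)
        lam = 0.1
        C = compute_gram(X)
        c = compute_crossproducts(X, y)[:, 0]
        state = cd_solve_voxel(C, c, lam, opts=CDOptions(tol_value=1e-10))
        ref = ista_reference(X, y, lam, tol=1e-12)
        o_cd = objective_value(X, y, state.beta, y.mean(), lam)
        o_ref = objective_value(X, y, ref, y.mean(), lam)
        assert abs(o_cd - o_ref) < 1e-8

    def test_objective_monotone_across_coordinate_updates(self, rng):
        raw = rng.standard_normal((20, 5))
        X, _ = zscore_columns(raw)
        y = rng.standard_normal(20)
        C = compute_gram(X)
        c = compute_crossproducts(X, y)[:, 0]
        trace = []
        cd_solve_voxel(C, c, 0.05, trace=trace)
        diffs = np.diff(trace)
        assert (diffs <= 1e-12).all()

    def test_max_iter_error_message(self, rng):
        raw = rng.standard_normal((30, 8))
        X, _ = zscore_columns(raw)
        y = rng.standard_normal(30)
        C = compute_gram(X)
        c = compute_crossproducts(X, y)[:, 0]
        with pytest.raises(ConvergenceError, match="Max. iter. reached, no convergence!"):
            cd_solve_voxel(C, c, 0.01, opts=CDOptions(n_iter_max=2))


class TestPath:
    def test_scalar_lasso_closed_form(self, rng):
        x, _ = zscore_columns(rng.standard_normal((20, 1)))
        y = rng.standard_normal(20)
        lam = 0.1
        res = cd_solve_path(x, y, [lam], CDOptions(cpu_load_factor=0.0))
        c = compute_crossproducts(x, y).item()
        assert res.coefficients(0)[0, 0] == pytest.approx(
            soft_threshold(c, lam), abs=1e-10)

    def test_all_zero_above_lambda_start_and_intercepts(self, small_design, small_responses):
        ls = calculate_lambda_start(small_design, small_responses)
        res = cd_solve_path(small_design, small_responses, [ls * 1.01],
                            CDOptions(cpu_load_factor=0.0))
        assert (res.nonzero_counts() == 0).all()
        np.testing.assert_allclose(res.intercepts[0],
                                   small_responses.mean(axis=0), atol=1e-12)

    def test_residual_mean_zero_after_fit(self, small_design, small_responses):
        res = cd_solve_path(small_design, small_responses, [0.1],
                            CDOptions(cpu_load_factor=0.0))
        dense = res.coefficients(0)
        fitted = small_design @ dense + res.intercepts
        resid = small_responses - fitted
        np.testing.assert_allclose(resid.mean(axis=0), 0.0, atol=1e-6)

    def test_warm_equals_cold_benchmark_b_shape(self, rng):
        X, _ = zscore_columns(rng.standard_normal((60, 40)))
        Y = rng.standard_normal((60, 100))
        lambdas = 2.0 ** -np.arange(2, 7)
        opts = CDOptions(cpu_load_factor=0.0)
        warm = cd_solve_path(X, Y, lambdas, opts)
        for li, lam in enumerate(lambdas):
            cold = cd_solve_path(X, Y, [lam], opts)
            o_w = _objective_cols(X, Y, warm, li)
            o_c = _objective_cols(X, Y, cold, 0)
            np.testing.assert_allclose(o_w, o_c, atol=1e-2 * 10, rtol=0)
        # much tighter agreement when both paths run at tol 1e-8
        tight = CDOptions(cpu_load_factor=0.0, tol_value=1e-8)
        warm_t = cd_solve_path(X, Y[:, :10], lambdas, tight)
        for li, lam in enumerate(lambdas):
            cold_t = cd_solve_path(X, Y[:, :10], [lam], tight)
            np.testing.assert_allclose(
                _objective_cols(X, Y[:, :10], warm_t, li),
                _objective_cols(X, Y[:, :10], cold_t, 0), atol=1e-8, rtol=0)

    def test_path_l1_norm_monotone(self, rng):
        X, _ = zscore_columns(rng.standard_normal((40, 30)))
        Y = rng.standard_normal((40, 8))
        lambdas = 2.0 ** -np.arange(1, 7)
        res = cd_solve_path(X, Y, lambdas, CDOptions(cpu_load_factor=0.0))
        norms = np.vstack([np.abs(res.coefficients(li)).sum(axis=0)
                           for li in range(len(lambdas))])
        assert (np.diff(norms, axis=0) >= -2e-3).all()

    def test_kkt_certificate_random_battery(self, rng):
        tol = 1e-3
        for _ in range(15):
            n = int(rng.integers(20, 50))
            p = int(rng.integers(3, 40))
            X, _ = zscore_columns(rng.standard_normal((n, p)))
            y = rng.standard_normal(n)
            lam = float(rng.uniform(0.05, 0.3))
            res = cd_solve_path(X, y, [lam], CDOptions(cpu_load_factor=0.0))
            beta = res.coefficients(0)[:, 0]
            assert kkt_residual(X, y, beta, lam) <= 5 * tol

    def test_lambda_zero_rejected_when_overparameterized(self, rng):
        X, _ = zscore_columns(rng.standard_normal((10, 20)))
        with pytest.raises(ValueError, match="p > n"):
            cd_solve_path(X, rng.standard_normal(10), [0.0])

    def test_lambda_zero_allowed_ols_limit(self, rng):
        X, _ = zscore_columns(rng.standard_normal((30, 4)))
        beta = np.array([1.0, -2.0, 0.5, 0.0])
        y = X @ beta + 1.0
        res = cd_solve_path(X, y, [0.0], CDOptions(cpu_load_factor=0.0, tol_value=1e-8))
        np.testing.assert_allclose(res.coefficients(0)[:, 0], beta, atol=1e-5)


class TestBufferAndWorkers:
    @pytest.mark.parametrize("factor,cores,expected", [
        (1.0, 16, 16), (0.0, 16, 1), (0.99, 16, 15), (0.5, 8, 4), (0.1, 4, 1),
    ])
    def test_resolve_worker_count(self, factor, cores, expected):
        assert resolve_worker_count(factor, cores) == expected

    def test_buffer_overflow_error_message(self, rng):
        # buffer_factor 0.01 with n=40 gives capacity 1; a dense-solution
        # regime at small lambda needs far more nonzeros.
        X, _ = zscore_columns(rng.standard_normal((40, 10)))
        beta = rng.standard_normal(10)
        y = X @ beta
        with pytest.raises(BufferOverflowError, match="N_nz over maximum, larger buffer is required!"):
            cd_solve_path(X, y, [0.01],
                          CDOptions(buffer_factor=0.01, cpu_load_factor=0.0))

    def test_parallel_determinism(self, rng):
        X, _ = zscore_columns(rng.standard_normal((30, 10)))
        Y = rng.standard_normal((30, 6))
        lambdas = [0.25, 0.1]
        r1 = cd_solve_path(X, Y, lambdas, CDOptions(), n_workers=1)
        r2 = cd_solve_path(X, Y, lambdas, CDOptions(), n_workers=2)
        for li in range(2):
            np.testing.assert_array_equal(r1.coefficients(li), r2.coefficients(li))
        np.testing.assert_array_equal(r1.iterations, r2.iterations)


def test_model_front_end_matches_function(small_design, small_responses):
    model = MassLasso(small_responses, small_design)
    res = model.fit([0.2, 0.1], method="cd", cpu_load_factor=0.0)
    direct = cd_solve_path(small_design, small_responses, [0.2, 0.1],
                           CDOptions(cpu_load_factor=0.0))
    np.testing.assert_array_equal(res.coefficients(-1), direct.coefficients(-1))
    assert "lasso path" in res.summary()


def test_sklearn_cross_check(small_design, small_responses):
    """Independent library solving the same objective agrees with CD."""
    sklearn = pytest.importorskip("sklearn.linear_model")
    lam = 0.15
    res = cd_solve_path(small_design, small_responses, [lam],
                        CDOptions(cpu_load_factor=0.0, tol_value=1e-8))
    for j in range(small_responses.shape[1]):
        sk = sklearn.Lasso(alpha=lam, fit_intercept=True, tol=1e-12, max_iter=100000)
        sk.fit(small_design, small_responses[:, j])
        np.testing.assert_allclose(res.coefficients(0)[:, j], sk.coef_, atol=1e-5)
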