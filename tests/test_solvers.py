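"""Solver building blocks and the alternating weight/shrinkage iteration."""

import numpy as np
import pytest

from eriwsta import (
    DivergenceError,
    SolverConfig,
    WeightSchemeParams,
    cost_function,
    gradient_step,
    matrix_operator,
    soft_threshold,
    solve_twist,
    solve_weighted_ista,
)


def _dense_instance(seed, m=12, n=8, noise=0.05):
    rng = np.random.default_rng(seed)
    A = rng.standard_normal((m, n))
    x_true = rng.standard_normal(n) * (rng.random(n) < 0.5)
    b = A @ x_true + noise * rng.standard_normal(m)
    op = matrix_operator(A)
    op.lipschitz = float(np.linalg.eigvalsh(A.T @ A)[-1])
    return op, b


class TestSoftThreshold:
    @pytest.mark.parametrize(
        "v,theta,expected", [(5.0, 2.0, 3.0), (0.0, 4.0, 0.0), (-1.0, 3.0, 0.0), (-5.0, 2.0, -3.0)]
    )
    def test_closed_form(self, v, theta, expected):
        assert soft_threshold(v, theta) == expected

    @pytest.mark.parametrize("v,theta", [(-1.0, 3.0), (2.5, 0.7), (-4.2, 1.3), (0.3, 0.0)])
    def test_is_proximal_operator_of_abs(self, v, theta):
        """Brute-force oracle: grid minimizer of 1/2 (u-v)^2 + theta |u|."""
        grid = np.arange(-5.0, 5.0, 1e-4)
        best = grid[np.argmin(0.5 * (grid - v) ** 2 + theta * np.abs(grid))]
        assert soft_threshold(v, theta) == pytest.approx(best, abs=1e-4)

    def test_vectorized_with_per_coordinate_thresholds(self):
        out = soft_threshold(np.array([3.0, -3.0, 0.5]), np.array([1.0, 2.0, 1.0]))
        np.testing.assert_allclose(out, [2.0, -1.0, 0.0])

    def test_shrinks_magnitude_and_keeps_sign(self, rng):
        v = rng.standard_normal(50)
        out = soft_threshold(v, 0.3)
        assert np.all(np.abs(out) <= np.abs(v))
        assert np.all((out == 0) | (np.sign(out) == np.sign(v)))

    def test_negative_threshold_rejected(self):
        with pytest.raises(ValueError):
            soft_threshold(1.0, -0.1)


class TestGradientStep:
    def test_fixed_point_at_exact_solution(self, rng):
        A = rng.standard_normal((6, 6))
        x = rng.standard_normal(6)
        op = matrix_operator(A)
        np.testing.assert_allclose(gradient_step(x, op, A @ x, L=10.0), x, atol=1e-12)

    def test_from_zero_is_scaled_backprojection(self, rng):
        A = rng.standard_normal((5, 4))
        b = rng.standard_normal(5)
        op = matrix_operator(A)
        np.testing.assert_allclose(
            gradient_step(np.zeros(4), op, b, L=2.0), A.T @ b / 2.0, rtol=1e-12
        )

    def test_matches_dense_arithmetic_both_scales(self, rng):
        A = rng.standard_normal((7, 5))
        x = rng.standard_normal(5)
        b = rng.standard_normal(7)
        op = matrix_operator(A)
        expected = x - A.T @ (A @ x - b) / 3.0
        np.testing.assert_allclose(gradient_step(x, op, b, 3.0, "half"), expected, rtol=1e-12)
        expected2 = x - 2.0 * A.T @ (A @ x - b) / 3.0
        np.testing.assert_allclose(gradient_step(x, op, b, 3.0, "paper"), expected2, rtol=1e-12)


class TestCostFunction:
    def test_entropy_only_case(self):
        op = matrix_operator(np.eye(4))
        phi, parts = cost_function(np.zeros(4), np.full(4, 0.25), op, np.zeros(4), 1.0, 1.0)
        assert phi == pytest.approx(-np.log(4))
        assert parts["data"] == 0.0 and parts["weighted_l1"] == 0.0

    def test_beta_zero_reduces_to_data_term(self, rng):
        A = rng.standard_normal((6, 4))
        x, b = rng.standard_normal(4), rng.standard_normal(6)
        op = matrix_operator(A)
        phi, _ = cost_function(x, np.ones(4), op, b, beta=0.0)
        assert phi == pytest.approx(0.5 * np.sum((A @ x - b) ** 2))

    def test_matches_naive_summation(self, rng):
        A = rng.standard_normal((6, 4))
        x, b = rng.standard_normal(4), rng.standard_normal(6)
        w = rng.dirichlet(np.ones(4))
        op = matrix_operator(A)
        beta, gamma = 0.7, 0.3
        phi, _ = cost_function(x, w, op, b, beta, gamma)
        naive = 0.5 * sum((A @ x - b) ** 2) + beta * (
            sum(w[i] * abs(x[i]) for i in range(4))
            + gamma * sum(w[i] * np.log(w[i]) for i in range(4))
        )
        assert phi == pytest.approx(naive, rel=1e-12)

    def test_offsimplex_weights_rejected_when_entropy_active(self):
        op = matrix_operator(np.eye(3))
        with pytest.raises(ValueError):
            cost_function(np.zeros(3), np.ones(3), op, np.zeros(3), 1.0, gamma=1.0)


class TestWeightedIsta:
    def test_identity_single_step_is_soft_thresholded_data(self, rng):
        b = rng.standard_normal(9)
        op = matrix_operator(np.eye(9))
        op.lipschitz = 1.0
        config = SolverConfig(beta=0.4, scheme=WeightSchemeParams("constant"), max_iter=1)
        trace = solve_weighted_ista(op, b, config)
        np.testing.assert_allclose(trace.x, soft_threshold(b, 0.4), rtol=1e-14)

    def test_constant_scheme_reproduces_reference_ista_bitwise(self):
        """Same floating-point sequence as a standalone ISTA loop."""
        op, b = _dense_instance(3)
        A = np.asarray(op.as_matrix())
        L = op.lipschitz
        beta, iters = 0.2, 25
        config = SolverConfig(beta=beta, scheme=WeightSchemeParams("constant"), max_iter=iters)
        trace = solve_weighted_ista(op, b, config)
        x = np.zeros(A.shape[1])
        for _ in range(iters):
            r = x - A.T @ (A @ x - b) / L
            theta = beta * (1.0 / L) * np.ones(A.shape[1])
            x = np.sign(r) * np.maximum(np.abs(r) - theta, 0.0)
        assert np.array_equal(trace.x, x)

    def test_descent_on_dense_and_blur_instances(self, blur_instance):
        for seed in range(5):
            op, b = _dense_instance(seed, m=20, n=40)
            config = SolverConfig(
                beta=0.5, scheme=WeightSchemeParams("entropy", gamma=0.1), max_iter=30
            )
            trace = solve_weighted_ista(op, b, config)
            assert np.all(np.diff(trace.objective) <= 1e-10)
        op, b, _ = blur_instance
        config = SolverConfig(
            beta=10.0, scheme=WeightSchemeParams("entropy", gamma=1e-2), max_iter=30
        )
        trace = solve_weighted_ista(op, b, config)
        assert np.all(np.diff(trace.objective) <= 1e-10)

    def test_x_update_is_exact_coordinatewise_minimizer(self, rng):
        """prox vs brute-force grid search on L/2 (u - r)^2 + beta w |u|."""
        L, beta = 2.3, 0.8
        r = rng.uniform(-2, 2, 6)
        w = rng.dirichlet(np.ones(6))
        x_up = soft_threshold(r, beta * w / L)
        grid = np.arange(-4.0, 4.0, 1e-4)
        for i in range(6):
            g = 0.5 * L * (grid - r[i]) ** 2 + beta * w[i] * np.abs(grid)
            assert x_up[i] == pytest.approx(grid[np.argmin(g)], abs=1e-4)

    def test_fixed_point_stationarity(self):
        """Once converged, a further iteration moves the iterate by <= 1e-8."""
        op, b = _dense_instance(9, m=10, n=6, noise=0.0)
        scheme = WeightSchemeParams("entropy", gamma=0.5)
        config = SolverConfig(beta=0.3, scheme=scheme, max_iter=5000)
        trace = solve_weighted_ista(op, b, config)
        one_more = solve_weighted_ista(
            op, b, SolverConfig(beta=0.3, scheme=scheme, max_iter=1, x0_mode="custom", x0=trace.x)
        )
        assert np.linalg.norm(one_more.x - trace.x) <= 1e-8

    def test_uniform_entropy_limit_matches_rescaled_ista(self, blur_instance):
        op, b, _ = blur_instance
        n = op.domain_size
        ent = SolverConfig(
            beta=10.0, scheme=WeightSchemeParams("entropy", gamma=1e9), max_iter=30
        )
        ista = SolverConfig(beta=10.0 / n, scheme=WeightSchemeParams("constant"), max_iter=30)
        xa = solve_weighted_ista(op, b, ent).x
        xb = solve_weighted_ista(op, b, ista).x
        assert np.max(np.abs(xa - xb)) <= 1e-8

    def test_trace_length_and_early_stop(self, blur_instance):
        op, b, _ = blur_instance
        config = SolverConfig(beta=1.0, scheme=WeightSchemeParams("constant"), max_iter=12)
        assert solve_weighted_ista(op, b, config).iterations == 12
        config2 = SolverConfig(
            beta=1.0, scheme=WeightSchemeParams("constant"), max_iter=500, tol=1e-6
        )
        assert solve_weighted_ista(op, b, config2).iterations < 500

    def test_divergence_reported_with_iteration(self):
        op, b = _dense_instance(4)
        op.lipschitz = 1e-12  # invalid bound: gradient steps blow up
        config = SolverConfig(beta=0.1, scheme=WeightSchemeParams("constant"), max_iter=500)
        with np.errstate(over="ignore", invalid="ignore"), pytest.raises(DivergenceError):
            solve_weighted_ista(op, b, config)


class TestTwist:
    def test_first_iteration_is_ist_step(self, rng):
        op, b = _dense_instance(5)
        config = SolverConfig(beta=0.3, scheme=WeightSchemeParams("constant"), max_iter=1)
        tw = solve_twist(op, b, config)
        ist = solve_weighted_ista(op, b, config)
        np.testing.assert_allclose(tw.x, ist.x, rtol=1e-12)

    def test_deterministic_across_runs(self):
        op, b = _dense_instance(6)
        config = SolverConfig(beta=0.2, scheme=WeightSchemeParams("constant"), max_iter=20)
        t1 = solve_twist(op, b, config)
        t2 = solve_twist(op, b, config)
        assert np.array_equal(t1.x, t2.x)
        assert t1.objective == t2.objective

    def test_beats_ista_residual_on_noiseless_instance(self):
        """Fixed seeded well-conditioned instance, equal iteration budget."""
        rng = np.random.default_rng(42)
        A = rng.standard_normal((30, 30)) + 6 * np.eye(30)
        x_true = rng.standard_normal(30)
        op = matrix_operator(A)
        op.lipschitz = float(np.linalg.eigvalsh(A.T @ A)[-1])
        b = A @ x_true
        config = SolverConfig(
            beta=1e-3, scheme=WeightSchemeParams("constant"), max_iter=15, twist_xi_min=0.04
        )
        res_tw = np.linalg.norm(op.forward(solve_twist(op, b, config).x) - b)
        res_ista = np.linalg.norm(op.forward(solve_weighted_ista(op, b, config).x) - b)
        assert res_tw < res_ista
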