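"""Step-I solvers: fidelity, proxes, penalties, lambda_max, alternation."""

import numpy as np
import pytest
from scipy.optimize import minimize, minimize_scalar

from col0rme.covariance import empirical_covariance
from col0rme.support import (
    RegularizerSpec,
    cel0_penalty,
    extract_support,
    fidelity_value,
    irl1_weights,
    lambda_max,
    noise_variance_update,
    prox_nonneg_l1,
    restarted_support,
    solve_support,
    solve_variance_cel0,
    solve_variance_l1,
    solve_variance_tv,
    tv_value,
)

from conftest import make_operator


def sparse_instance(op, idx_vals, s=0.0, seed=None):
    """Exact covariance of a sparse variance image (+ optional noise floor)."""
    x = np.zeros(op.grid.n_fine)
    for i, v in idx_vals:
        x[i] = v
    R = op.covariance_forward(x) + s * np.eye(op.grid.n_coarse)
    return x, R


class TestFidelity:
    def test_zero_at_exact_model(self, small_op):
        x, R = sparse_instance(small_op, [(18, 5.0), (45, 3.0)], s=0.7)
        assert fidelity_value(x, 0.7, R, small_op) < 1e-18

    def test_value_at_origin(self, small_op):
        rng = np.random.default_rng(0)
        m = small_op.grid.n_coarse
        R = rng.standard_normal((m, m))
        R = R @ R.T
        assert abs(fidelity_value(np.zeros(small_op.grid.n_fine), 0.0, R, small_op)
                   - 0.5 * np.sum(R**2)) < 1e-9 * np.sum(R**2)

    def test_dense_oracle(self, small_op, dense_A):
        rng = np.random.default_rng(1)
        n = small_op.grid.n_fine
        m = small_op.grid.n_coarse
        K = np.column_stack([np.kron(dense_A[:, i], dense_A[:, i]) for i in range(n)])
        x = rng.random(n)
        s = 0.3
        R = rng.standard_normal((m, m))
        R = R + R.T
        resid = R.ravel() - K @ x - s * np.eye(m).ravel()
        expected = 0.5 * resid @ resid
        assert abs(fidelity_value(x, s, R, small_op) - expected) < 1e-8 * expected


class TestNoiseVarianceUpdate:
    def test_exact_model(self, small_op):
        x, R = sparse_instance(small_op, [(10, 4.0)], s=3.0)
        assert abs(noise_variance_update(x, R, small_op) - 3.0) < 1e-10

    def test_negative_residual_projected(self, small_op):
        x, R0 = sparse_instance(small_op, [(10, 4.0)])
        R = R0 - np.eye(small_op.grid.n_coarse)
        assert noise_variance_update(x, R, small_op) == 0.0

    def test_matches_scalar_minimization(self, small_op):
        rng = np.random.default_rng(2)
        m = small_op.grid.n_coarse
        x = rng.random(small_op.grid.n_fine)
        R = rng.standard_normal((m, m))
        R = R @ R.T
        s_hat = noise_variance_update(x, R, small_op)
        res = minimize_scalar(
            lambda s: fidelity_value(x, s, R, small_op),
            bounds=(0.0, 10.0 * np.trace(R) / m),
            method="bounded",
            options={"xatol": 1e-12},
        )
        assert abs(s_hat - res.x) < 1e-8 * max(1.0, s_hat)


class TestProxNonnegL1:
    def test_zero(self):
        np.testing.assert_allclose(prox_nonneg_l1(np.zeros(3), 1.0), 0.0)

    def test_piecewise(self):
        np.testing.assert_allclose(
            prox_nonneg_l1(np.array([-5.0, 0.5, 2.0]), 1.0), [0.0, 0.0, 1.0]
        )

    def test_scalar_grid_oracle(self):
        rng = np.random.default_rng(3)
        grid = np.linspace(0.0, 10.0, 200_001)
        for _ in range(100):
            v = rng.uniform(-5, 5)
            t = rng.uniform(0, 3)
            brute = grid[np.argmin(t * grid + 0.5 * (grid - v) ** 2)]
            assert abs(prox_nonneg_l1(np.array([v]), t)[0] - brute) < 1e-4

    def test_negative_threshold_error(self):
        with pytest.raises(ValueError):
            prox_nonneg_l1(np.zeros(2), -1.0)


class TestCEL0Penalty:
    def test_zero_origin(self, small_op):
        _, eta = small_op.column_norms()
        assert abs(cel0_penalty(np.zeros(small_op.grid.n_fine), 2.0, eta)) < 1e-10
        w = irl1_weights(np.zeros(small_op.grid.n_fine), 2.0, eta)
        np.testing.assert_allclose(w, eta * np.sqrt(4.0))

    def test_saturation_counts_nonzeros(self, small_op):
        _, eta = small_op.column_norms()
        lam = 0.5
        x = np.zeros(small_op.grid.n_fine)
        x[[3, 40]] = 100.0 * np.sqrt(2 * lam) / eta[[3, 40]]
        assert abs(cel0_penalty(x, lam, eta) - 2 * lam) < 1e-12
        assert np.all(irl1_weights(x, lam, eta)[[3, 40]] == 0.0)

    def test_scalar_formula_oracle(self):
        lam, eta = 1.3, np.array([0.7])
        thresh = np.sqrt(2 * lam) / eta[0]
        for v in np.linspace(0, 2 * thresh, 41):
            expected = (
                lam - 0.5 * eta[0] ** 2 * (v - thresh) ** 2 if v <= thresh else lam
            )
            assert abs(cel0_penalty([v], lam, eta) - expected) < 1e-12


class TestLambdaMax:
    @pytest.mark.parametrize("kind", ["l1", "cel0"])
    def test_contract(self, small_op, kind):
        _, R = sparse_instance(small_op, [(18, 5.0), (45, 3.0)], s=0.5)
        lam_max = lambda_max(R, small_op, kind)
        solver = solve_variance_l1 if kind == "l1" else solve_variance_cel0
        x_hi, _ = solver(R, small_op, 1.01 * lam_max, s_fixed=0.0)
        assert np.all(x_hi == 0.0)
        x_lo, _ = solver(R, small_op, 0.5 * lam_max, s_fixed=0.0)
        assert x_lo.max() > 0.0

    def test_homogeneity_l1(self, small_op):
        _, R = sparse_instance(small_op, [(20, 2.0)])
        lam1 = lambda_max(R, small_op, "l1")
        lam3 = lambda_max(3.0 * R, small_op, "l1")
        assert abs(lam3 - 3.0 * lam1) < 1e-10 * lam1

    def test_tv_unsupported(self, small_op):
        with pytest.raises(ValueError):
            lambda_max(np.eye(small_op.grid.n_coarse), small_op, "tv")


class TestVarianceSolvers:
    def test_l1_recovers_one_sparse_support(self, small_op):
        x_true, R = sparse_instance(small_op, [(27, 5.0)])
        lam = 1e-3 * lambda_max(R, small_op, "l1")
        x, converged = solve_variance_l1(R, small_op, lam, tol=1e-10, max_iter=2000)
        assert np.argmax(x) == 27

    def test_l1_matches_bound_constrained_oracle(self, small_op, dense_A):
        # oracle: high-accuracy L-BFGS-B on the smooth-on-the-orthant objective
        rng = np.random.default_rng(4)
        n = small_op.grid.n_fine
        K = np.column_stack([np.kron(dense_A[:, i], dense_A[:, i]) for i in range(n)])
        _, R = sparse_instance(small_op, [(12, 4.0), (50, 2.0)], s=0.2)
        lam = 0.05 * lambda_max(R, small_op, "l1")
        r = R.ravel()

        def obj(x):
            resid = r - K @ x
            return 0.5 * resid @ resid + lam * x.sum()

        def grad(x):
            return -K.T @ (r - K @ x) + lam

        res = minimize(
            obj, np.zeros(n), jac=grad, method="L-BFGS-B",
            bounds=[(0, None)] * n, options={"maxiter": 5000, "ftol": 1e-15},
        )
        x, _ = solve_variance_l1(R, small_op, lam, tol=1e-12, max_iter=5000)
        assert obj(x) <= res.fun + 1e-6 * max(1.0, abs(res.fun))

    def test_cel0_beats_exhaustive_l0_on_tiny_grid(self):
        # 3x3 coarse, q=2 -> 6x6 fine grid: exhaustive search over all
        # supports of size <= 2 is the l0 oracle
        op = make_operator(M=3, q=2, side=5)
        n = op.grid.n_fine
        x_true = np.zeros(n)
        x_true[[8, 27]] = [5.0, 4.0]
        R = op.covariance_forward(x_true)
        lam = 0.02 * lambda_max(R, op, "cel0")
        x, _ = solve_variance_cel0(R, op, lam, tol=1e-10, max_inner=2000)
        support = set(np.flatnonzero(x > 1e-8 * x.max()))
        A = op.matrix()
        K = np.column_stack([np.kron(A[:, i], A[:, i]) for i in range(n)])
        r = R.ravel()

        def l0_obj(idx):
            Ki = K[:, list(idx)]
            coef, *_ = np.linalg.lstsq(Ki, r, rcond=None)
            coef = np.maximum(coef, 0.0)
            resid = r - Ki @ coef
            return 0.5 * resid @ resid + lam * np.count_nonzero(coef)

        best = min(
            (l0_obj((i, j)) for i in range(n) for j in range(i + 1, n)),
            default=np.inf,
        )
        # CEL0 objective of our solution is within tolerance of the l0 optimum
        resid = r - K @ x
        ours = 0.5 * resid @ resid + cel0_penalty(x, lam, op.column_norms()[1])
        assert ours <= best + 1e-6 * max(1.0, best)
        assert support == {8, 27}

    def test_cel0_objective_leq_l1_solution(self, small_op):
        _, eta = small_op.column_norms()
        _, R = sparse_instance(small_op, [(18, 5.0), (45, 3.0)])
        lam = 0.1 * lambda_max(R, small_op, "cel0")
        x_cel0, _ = solve_variance_cel0(R, small_op, lam, tol=1e-10)
        x_l1, _ = solve_variance_l1(R, small_op, lam, tol=1e-10)

        def cel0_obj(x):
            return fidelity_value(x, 0.0, R, small_op) + cel0_penalty(x, lam, eta)

        assert cel0_obj(x_cel0) <= cel0_obj(x_l1) + 1e-9


class TestTV:
    def test_tv_value_two_block_image(self):
        # 4x4 image: left half 0, right half c -> one vertical edge of
        # length 4 and jump c (one-sided differences, Neumann)
        c = 3.0
        img = np.zeros((4, 4))
        img[:, 2:] = c
        assert abs(tv_value(img.ravel(), 4) - 4 * c) < 1e-12

    def test_large_lambda_flattens(self, small_op):
        _, R = sparse_instance(small_op, [(18, 5.0)], s=0.1)
        x, _ = solve_variance_tv(R, small_op, 1e4, s_fixed=0.1, max_iter=800)
        assert np.ptp(x) < 1e-3 * max(1.0, x.max())

    def test_against_subgradient_oracle(self, small_op):
        # slow projected-subgradient oracle on the same objective
        _, R = sparse_instance(small_op, [(18, 5.0), (45, 3.0)], s=0.2)
        lam = 0.05
        x_pd, _ = solve_variance_tv(R, small_op, lam, s_fixed=0.2, max_iter=2000, tol=1e-12)

        from col0rme.support import _StepIContext, tv_operator

        ctx = _StepIContext(small_op, R)
        L = small_op.grid.fine_size
        D = tv_operator(L)

        def obj(x):
            return ctx.fidelity(x, 0.2) + lam * tv_value(x, L)

        x = np.zeros(small_op.grid.n_fine)
        step0 = 1.0 / ctx.lipschitz()
        best = obj(x)
        x_best = x.copy()
        for k in range(4000):
            g = ctx.grad_x(x, 0.2)
            Dx = (D @ x).reshape(2, -1)
            mag = np.sqrt((Dx**2).sum(axis=0))
            sub = Dx / np.maximum(mag, 1e-12)
            g = g + lam * (D.T @ sub.ravel())
            x = np.maximum(0.0, x - step0 / np.sqrt(k + 1.0) * g)
            v = obj(x)
            if v < best:
                best, x_best = v, x.copy()
        assert obj(x_pd) <= best + 1e-4 * max(1.0, abs(best))


class TestExtractSupport:
    def test_zero_gives_empty_with_warning(self):
        with pytest.warns(UserWarning):
            s = extract_support(np.zeros(10))
        assert s.size == 0

    def test_exact_zero_threshold(self):
        x = np.zeros(10)
        x[[2, 7]] = [1.0, 0.5]
        np.testing.assert_array_equal(extract_support(x, 0.0), [2, 7])

    def test_relative_threshold(self):
        x = np.array([1.0, 0.005, 0.5, 0.0])
        np.testing.assert_array_equal(extract_support(x, 1e-2), [0, 2])


class TestSolveSupport:
    def test_pure_noise_stack(self):
        """Zero emitters, known Gaussian noise: x ~ 0 and s within 10%."""
        rng = np.random.default_rng(7)
        s_true = 4.0
        frames = rng.normal(0.0, np.sqrt(s_true), size=(1000, 4, 4))
        op = make_operator(M=4, q=2, side=5)
        sol = solve_support(frames, op, RegularizerSpec("cel0", gamma_fraction=0.5))
        assert abs(sol.noise_variance - s_true) / s_true < 0.1
        assert sol.variance_image.max() <= 1e-2 * s_true

    def test_noiseless_exact_covariance(self, small_op):
        x_true, R = sparse_instance(small_op, [(18, 5.0), (45, 3.0)])
        sol = solve_support(small_op.covariance_forward(x_true), small_op,
                            RegularizerSpec("l1", gamma_fraction=1e-4))
        assert sol.objective_trace[-1] < 1e-3 * sol.objective_trace[0]
        assert sol.noise_variance < 1e-3
        # the two dominant variances sit at the true emitter pixels
        assert set(np.argsort(sol.variance_image)[-2:]) == {18, 45}

    @pytest.mark.parametrize("kind", ["cel0", "l1", "tv"])
    def test_objective_trace_nonincreasing(self, small_op, kind):
        _, R = sparse_instance(small_op, [(18, 5.0), (45, 3.0)], s=0.5)
        reg = (RegularizerSpec(kind, lambda_value=1e-2) if kind == "tv"
               else RegularizerSpec(kind, gamma_fraction=0.05))
        sol = solve_support(R, small_op, reg)
        diffs = np.diff(sol.objective_trace)
        assert np.all(diffs <= 1e-9 * np.maximum(1.0, np.abs(sol.objective_trace[:-1])))


class TestRestartedSupport:
    def test_single_restart_matches_plain(self, small_op):
        _, R = sparse_instance(small_op, [(18, 5.0)], s=0.2)
        reg = RegularizerSpec("cel0", gamma_fraction=0.2)
        plain = solve_support(R, small_op, reg)
        one = restarted_support(R, small_op, reg, max_restarts=1)
        np.testing.assert_array_equal(plain.support, one.support)
        np.testing.assert_allclose(plain.variance_image, one.variance_image)

    def test_union_support_contains_single_run(self):
        from col0rme.simulate import preset_config, simulate_dataset

        stack, truth = simulate_dataset(preset_config("LB", 8, 4), T=300, seed=5)
        op = truth.config.operator()
        reg = RegularizerSpec("cel0", gamma_fraction=0.05)
        single = solve_support(stack.frames, op, reg)
        multi = restarted_support(stack.frames, op, reg, max_restarts=4)
        assert set(single.support) <= set(multi.support)
        assert multi.restarts_used >= 1

    def test_restarting_improves_jaccard(self):
        from col0rme.metrics import jaccard_index
        from col0rme.simulate import preset_config, simulate_dataset

        stack, truth = simulate_dataset(preset_config("LB", 8, 4), T=500, seed=3)
        op = truth.config.operator()
        reg = RegularizerSpec("cel0", gamma_fraction=0.05)
        single = solve_support(stack.frames, op, reg)
        multi = restarted_support(stack.frames, op, reg, max_restarts=6)
        ji_s, _ = jaccard_index(single.support, truth.support, grid_size=32)
        ji_m, _ = jaccard_index(multi.support, truth.support, grid_size=32)
        assert ji_m >= ji_s

    def test_requires_cel0(self, small_op):
        with pytest.raises(ValueError):
            restarted_support(np.eye(16), small_op, RegularizerSpec("l1", gamma_fraction=0.5))
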