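import itertools

import numpy as np
import pytest

from pdestride.dictionary import DesignSystem, standardize
from pdestride.solvers import (
    SolverConfig,
    batched_l0_path_supports,
    debias_restricted_lstsq,
    draw_randomization_weights,
    fit_iht,
    fit_iht_d,
    fit_lasso,
    fit_omp,
    fit_stridge,
    lambda_max,
    lasso_kkt_violation,
    make_path,
    solve_path,
)

from conftest import make_gaussian_system, make_orthonormal_system


def soft(x, t):
    return np.sign(x) * np.maximum(np.abs(x) - t, 0.0)


class TestLambdaMax:
    def test_single_column_gradient_convention(self):
        theta = np.zeros((4, 1))
        theta[0, 0] = 1.0  # unit-norm column
        ut = 2.0 * theta[:, 0]
        sys_ = DesignSystem(theta=theta, ut=ut, labels=("c0",),
                            standardized=True)
        # one gradient step from zero gives coefficient 2 (up to the
        # spectral-margin factor)
        assert lambda_max(sys_, "iht") == pytest.approx(2.0, rel=5e-3)

    def test_orthogonal_response_degenerate(self):
        theta = np.array([[1.0], [0.0]])
        ut = np.array([0.0, 1.0])
        sys_ = DesignSystem(theta=theta, ut=ut, labels=("c0",),
                            standardized=True)
        assert lambda_max(sys_, "lasso") == 0.0

    def test_zero_response_rejected(self):
        sys_, _ = make_orthonormal_system()
        bad = DesignSystem(theta=sys_.theta, ut=np.zeros(sys_.n_samples),
                           labels=sys_.labels, standardized=True)
        with pytest.raises(ValueError):
            lambda_max(bad, "lasso")

    def test_lasso_boundary(self):
        sys_, _ = make_gaussian_system(seed=5, noise=0.1)
        lm = lambda_max(sys_, "lasso")
        assert not np.any(fit_lasso(sys_, 1.01 * lm))
        assert np.any(fit_lasso(sys_, 0.99 * lm))

    def test_requires_standardized(self, burgers_system):
        with pytest.raises(ValueError):
            lambda_max(burgers_system, "lasso")


class TestMakePath:
    def test_two_point_grid(self):
        np.testing.assert_allclose(make_path(1.0, 0.1, 2), [1.0, 0.1])

    def test_default_geometric_grid(self):
        grid = make_path(5.0)
        assert grid.size == 20
        ratios = grid[1:] / grid[:-1]
        np.testing.assert_allclose(ratios, ratios[0], rtol=1e-12)
        assert grid[-1] == pytest.approx(0.5)

    def test_log_grid_is_arithmetic(self):
        lg = np.log10(make_path(2.0, 0.01, 7))
        np.testing.assert_allclose(np.diff(lg), np.diff(lg)[0], atol=1e-12)

    def test_invalid_args(self):
        with pytest.raises(ValueError):
            make_path(0.0)
        with pytest.raises(ValueError):
            make_path(1.0, M=1)


class TestLasso:
    def test_orthonormal_soft_threshold_closed_form(self):
        sys_, _ = make_orthonormal_system(seed=2, noise=0.2)
        lam = 0.3
        xi = fit_lasso(sys_, lam)
        expected = soft(sys_.theta.T @ sys_.ut, lam)
        np.testing.assert_allclose(xi, expected, atol=1e-8)

    def test_unit_weights_equal_unweighted(self):
        sys_, _ = make_gaussian_system(seed=1, noise=0.1)
        lam = 0.5 * lambda_max(sys_, "lasso")
        np.testing.assert_allclose(
            fit_lasso(sys_, lam),
            fit_lasso(sys_, lam, weights=np.ones(sys_.n_terms)),
            atol=1e-10,
        )

    def test_kkt_at_exit(self):
        sys_, _ = make_gaussian_system(seed=4, noise=0.3, corr=0.3)
        lam = 0.2 * lambda_max(sys_, "lasso")
        xi = fit_lasso(sys_, lam)
        assert lasso_kkt_violation(sys_, lam, xi) < 1e-6

    def test_above_lambda_max_zero(self):
        sys_, _ = make_gaussian_system(seed=6, noise=0.1)
        xi = fit_lasso(sys_, 1.5 * lambda_max(sys_, "lasso"))
        assert not np.any(xi)


class TestRandomizationWeights:
    def test_alpha_one_all_ones(self):
        np.testing.assert_array_equal(draw_randomization_weights(7, 1.0, 0),
                                      np.ones(7))

    def test_uniform_moments(self):
        w = draw_randomization_weights(100_000, 0.2, seed=1)
        assert w.min() >= 0.2 and w.max() <= 1.0
        assert abs(w.mean() - 0.6) < 0.005
        assert abs(w.var() - 0.8**2 / 12) < 0.002

    def test_seed_reproducible(self):
        np.testing.assert_array_equal(
            draw_randomization_weights(10, 0.5, 3),
            draw_randomization_weights(10, 0.5, 3),
        )


class TestIht:
    def test_above_lambda_max_zero_fixed_point(self):
        sys_, _ = make_gaussian_system(seed=0, noise=0.1)
        lm = lambda_max(sys_, "iht")
        assert not np.any(fit_iht(sys_, 1.1 * lm))

    def test_lambda_zero_converges_to_least_squares(self):
        sys_, xi_true = make_orthonormal_system(seed=3)
        xi = fit_iht(sys_, 0.0, SolverConfig(method="iht", max_iter=500))
        ls, *_ = np.linalg.lstsq(sys_.theta, sys_.ut, rcond=None)
        np.testing.assert_allclose(xi, ls, atol=1e-6)

    def test_matches_exhaustive_l0_on_easy_design(self):
        sys_, xi_true = make_orthonormal_system(n=40, p=8, k=2, seed=7)
        lam = 0.5 * np.min(np.abs(xi_true[xi_true != 0]))
        xi = fit_iht(sys_, lam, SolverConfig(method="iht", max_iter=500))
        best = exhaustive_l0_support(sys_, lam)
        assert tuple(np.flatnonzero(xi)) == best

    def test_objective_nonincreasing_from_zero(self):
        sys_, _ = make_gaussian_system(seed=9, noise=0.2)
        lam = 0.3 * lambda_max(sys_, "iht")
        xi = fit_iht(sys_, lam)
        res0 = sys_.ut @ sys_.ut
        res = np.sum((sys_.ut - sys_.theta @ xi) ** 2)
        assert res <= res0


def exhaustive_l0_support(system, thr, max_k=None):
    """Brute-force minimizer of 1/2||r||^2 + (thr^2/2)|S| over all supports."""
    n, p = system.theta.shape
    best, best_obj = (), 0.5 * float(system.ut @ system.ut)
    idx = range(p)
    for k in range(1, (max_k or p) + 1):
        for S in itertools.combinations(idx, k):
            coef, *_ = np.linalg.lstsq(system.theta[:, S], system.ut,
                                       rcond=None)
            r = system.ut - system.theta[:, S] @ coef
            obj = 0.5 * float(r @ r) + 0.5 * thr**2 * k
            if obj < best_obj - 1e-12:
                best, best_obj = S, obj
    return best


class TestIhtD:
    def test_empty_support_returns_zero(self):
        sys_, _ = make_gaussian_system(seed=0, noise=0.1)
        lm = lambda_max(sys_, "iht_d")
        assert not np.any(fit_iht_d(sys_, 1.05 * lm))

    def test_debias_equals_restricted_least_squares(self):
        sys_, xi_true = make_gaussian_system(seed=2, noise=0.05)
        support = np.flatnonzero(xi_true)
        xi = debias_restricted_lstsq(sys_, support)
        # normal-equations oracle
        sub = sys_.theta[:, support]
        oracle = np.linalg.solve(sub.T @ sub, sub.T @ sys_.ut)
        np.testing.assert_allclose(xi[support], oracle, rtol=1e-9)

    def test_clean_burgers_path_contains_truth(self, burgers_system):
        std = standardize(burgers_system)
        path = solve_path(std, SolverConfig(method="iht_d"))
        truth = {std.labels.index("u*u_{x}"), std.labels.index("u_{xx}")}
        assert any(set(sup) == truth for sup in path.supports)

    def test_pure_function_of_inputs(self):
        sys_, _ = make_gaussian_system(seed=11, noise=0.2)
        lam = 0.3 * lambda_max(sys_, "iht_d")
        np.testing.assert_array_equal(fit_iht_d(sys_, lam),
                                      fit_iht_d(sys_, lam))


class TestStridge:
    def test_lambda_zero_full_ridge(self):
        sys_, _ = make_gaussian_system(seed=1, noise=0.2)
        cfg = SolverConfig(method="stridge")
        xi = fit_stridge(sys_, 0.0, cfg)
        p = sys_.n_terms
        oracle = np.linalg.solve(
            sys_.theta.T @ sys_.theta + cfg.ridge_lambda * np.eye(p),
            sys_.theta.T @ sys_.ut,
        )
        np.testing.assert_allclose(xi, oracle, rtol=1e-10)
        assert np.count_nonzero(xi) == p

    def test_large_lambda_empty(self):
        sys_, _ = make_gaussian_system(seed=1, noise=0.2)
        lm = lambda_max(sys_, "stridge")
        assert not np.any(fit_stridge(sys_, 1.5 * lm))

    def test_matches_independent_trace(self):
        # independently coded threshold-then-refit iteration
        sys_, _ = make_gaussian_system(seed=8, noise=0.3, corr=0.4)
        lam = 0.4 * lambda_max(sys_, "stridge")
        lamR = 1e-5
        active = np.ones(sys_.n_terms, bool)
        for _ in range(50):
            idx = np.flatnonzero(active)
            sub = sys_.theta[:, idx]
            coef = np.linalg.solve(sub.T @ sub + lamR * np.eye(idx.size),
                                   sub.T @ sys_.ut)
            xi_ref = np.zeros(sys_.n_terms)
            xi_ref[idx] = coef
            new = np.abs(xi_ref) >= lam
            if np.array_equal(new, active):
                break
            active = new
        xi_ref[~active] = 0.0
        np.testing.assert_allclose(fit_stridge(sys_, lam), xi_ref, atol=1e-12)


class TestOmp:
    def test_one_sparse_selects_max_correlation(self):
        sys_, _ = make_orthonormal_system(seed=4, k=1)
        xi = fit_omp(sys_, 1)
        g = np.abs(sys_.theta.T @ sys_.ut)
        assert np.flatnonzero(xi)[0] == np.argmax(g)

    def test_recovers_two_sparse_exactly(self):
        sys_, xi_true = make_orthonormal_system(seed=5, k=2)
        xi = fit_omp(sys_, 2)
        assert set(np.flatnonzero(xi)) == set(np.flatnonzero(xi_true))
        np.testing.assert_allclose(xi, xi_true, atol=1e-8)

    def test_k_zero_returns_zero(self):
        sys_, _ = make_orthonormal_system(seed=6)
        assert not np.any(fit_omp(sys_, 0))


class TestSolvePath:
    def test_support_empty_at_lambda_max(self):
        for method in ("lasso", "iht", "iht_d", "stridge", "omp"):
            sys_, _ = make_gaussian_system(seed=3, noise=0.1)
            path = solve_path(sys_, SolverConfig(method=method))
            assert path.supports[0] == ()

    def test_lasso_support_monotone_on_orthonormal(self):
        sys_, _ = make_orthonormal_system(seed=7, k=3, noise=0.2)
        path = solve_path(sys_, SolverConfig(method="lasso"))
        sizes = [len(s) for s in path.supports]
        assert all(a <= b for a, b in zip(sizes, sizes[1:]))

    def test_batched_matches_single(self):
        rng = np.random.default_rng(0)
        systems = [make_gaussian_system(seed=s, noise=0.15, corr=0.2)[0]
                   for s in range(12)]
        grid = make_path(lambda_max(systems[0], "iht_d"), 0.1, 8)
        cfg = SolverConfig(method="iht_d")
        sel = batched_l0_path_supports(
            np.stack([s.theta for s in systems]),
            np.stack([s.ut for s in systems]), grid, cfg,
        )
        for b, sys_ in enumerate(systems):
            for m, lam in enumerate(grid):
                xi = fit_iht_d(sys_, lam, cfg)
                assert np.array_equal(
                    sel[b, m], xi != 0
                ), f"mismatch at slice {b}, lambda {lam:.3g}"
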