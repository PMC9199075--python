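import numpy as np
import pytest

from pdestride.dictionary import DesignSystem
from pdestride.solvers import RegularizationPath, SolverConfig
from pdestride.stability import (
    ImportanceProfile,
    StabilityConfig,
    importance_profile,
    pde_stride,
    refit,
    stable_support,
    subsample_systems,
)

from conftest import make_gaussian_system


def path_from_supports(lambdas, supports, p, labels=None):
    coefs = np.zeros((len(lambdas), p))
    for m, sup in enumerate(supports):
        coefs[m, list(sup)] = 1.0
    return RegularizationPath(
        lambdas=np.asarray(lambdas, float),
        supports=[tuple(s) for s in supports],
        coefficients=coefs,
        labels=labels or tuple(f"c{j}" for j in range(p)),
        epsilon=lambdas[-1] / lambdas[0],
    )


class TestSubsampling:
    def test_half_size_rows(self):
        sys_, _ = make_gaussian_system(n=4, p=2, seed=0, noise=0.5)
        raw = DesignSystem(theta=sys_.theta, ut=sys_.ut, labels=sys_.labels)
        subs = subsample_systems(raw, StabilityConfig(B=1, seed=0))
        assert len(subs) == 1
        assert subs[0].n_samples == 2

    def test_subsamples_standardized(self):
        sys_, _ = make_gaussian_system(n=60, p=4, seed=1, noise=0.5)
        raw = DesignSystem(theta=sys_.theta * 3.0 + 1.0, ut=sys_.ut,
                           labels=sys_.labels)
        for sub in subsample_systems(raw, StabilityConfig(B=5, seed=2)):
            assert sub.standardized
            assert np.abs(sub.theta.mean(axis=0)).max() < 1e-10
            np.testing.assert_allclose(np.mean(sub.theta**2, axis=0), 1.0,
                                       atol=1e-10)

    def test_seed_reproducible(self):
        sys_, _ = make_gaussian_system(n=30, p=3, seed=3, noise=0.5)
        raw = DesignSystem(theta=sys_.theta, ut=sys_.ut, labels=sys_.labels)
        a = subsample_systems(raw, StabilityConfig(B=4, seed=7))
        b = subsample_systems(raw, StabilityConfig(B=4, seed=7))
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x.theta, y.theta)

    def test_too_few_samples(self):
        sys_, _ = make_gaussian_system(n=60, p=3, seed=0, noise=0.5)
        raw = DesignSystem(theta=sys_.theta[:3], ut=sys_.ut[:3],
                           labels=sys_.labels)
        with pytest.raises(ValueError):
            subsample_systems(raw, StabilityConfig())


class TestImportanceProfile:
    def test_hand_counted_fraction(self):
        lambdas = [1.0, 0.1]
        paths = [
            path_from_supports(lambdas, [(), (0,)], 3),
            path_from_supports(lambdas, [(), (0,)], 3),
            path_from_supports(lambdas, [(), ()], 3),
            path_from_supports(lambdas, [(), (0, 2)], 3),
        ]
        prof = importance_profile(paths, StabilityConfig(B=4))
        assert prof.pi[1, 0] == 0.75        # selected in 3 of 4
        assert prof.pi[1, 1] == 0.0         # never selected
        assert prof.pi[1, 2] == 0.25
        assert np.all(prof.pi[0] == 0.0)

    def test_always_selected_row_of_ones(self):
        lambdas = [1.0, 0.5, 0.1]
        paths = [path_from_supports(lambdas, [(1,), (1,), (1,)], 2)
                 for _ in range(5)]
        prof = importance_profile(paths, StabilityConfig(B=5))
        np.testing.assert_array_equal(prof.pi[:, 1], 1.0)

    def test_mismatched_grids_rejected(self):
        a = path_from_supports([1.0, 0.1], [(), ()], 2)
        b = path_from_supports([2.0, 0.2], [(), ()], 2)
        with pytest.raises(ValueError):
            importance_profile([a, b], StabilityConfig())

    def test_values_in_unit_interval(self):
        with pytest.raises(ValueError):
            ImportanceProfile(pi=np.array([[1.2]]), lambdas=np.array([1.0]),
                              labels=("c0",))


class TestStableSupport:
    def profile(self, pi_min):
        pi = np.vstack([np.zeros_like(pi_min), pi_min])
        return ImportanceProfile(
            pi=pi, lambdas=np.array([1.0, 0.1]),
            labels=tuple(f"c{j}" for j in range(len(pi_min))),
        )

    def test_all_below_threshold_empty(self):
        prof = self.profile(np.array([0.5, 0.79, 0.1]))
        assert stable_support(prof, StabilityConfig()) == ()

    def test_exactly_at_threshold_included(self):
        prof = self.profile(np.array([0.8, 0.3]))
        assert stable_support(prof, StabilityConfig()) == ("c0",)

    def test_raising_threshold_never_grows_support(self):
        prof = self.profile(np.array([0.95, 0.85, 0.7, 0.2]))
        prev = None
        for pith in (0.6, 0.7, 0.8, 0.9, 1.0):
            sup = set(stable_support(prof, StabilityConfig(pi_threshold=pith)))
            if prev is not None:
                assert sup <= prev
            prev = sup


class TestRefit:
    def test_square_full_rank_exact(self):
        rng = np.random.default_rng(0)
        theta = rng.normal(size=(3, 3))
        xi = np.array([1.0, -2.0, 0.5])
        sys_ = DesignSystem(theta=theta, ut=theta @ xi,
                            labels=("a", "b", "c"))
        coefs = refit(sys_, ["a", "b", "c"])
        np.testing.assert_allclose([coefs["a"], coefs["b"], coefs["c"]],
                                   xi, rtol=1e-10)

    def test_collinear_support_reported(self):
        rng = np.random.default_rng(1)
        col = rng.normal(size=10)
        theta = np.column_stack([col, 2 * col])
        sys_ = DesignSystem(theta=theta, ut=col, labels=("a", "b"))
        with pytest.raises(ValueError, match="a"):
            refit(sys_, ["a", "b"])

    def test_requires_raw_system(self):
        sys_, _ = make_gaussian_system()
        with pytest.raises(ValueError):
            refit(sys_, ["c0"])

    def test_clean_burgers_coefficients(self, burgers_system):
        coefs = refit(burgers_system, ["u*u_{x}", "u_{xx}"])
        assert coefs["u*u_{x}"] == pytest.approx(-1.0, rel=0.01)
        assert coefs["u_{xx}"] == pytest.approx(0.1, rel=0.01)


class TestPdeStride:
    def test_deterministic_under_seed(self, burgers_system):
        kwargs = dict(
            solver_config=SolverConfig(method="iht_d"),
            stability_config=StabilityConfig(seed=5, B=40),
        )
        a = pde_stride(burgers_system, **kwargs)
        b = pde_stride(burgers_system, **kwargs)
        assert a.stable_support == b.stable_support
        np.testing.assert_array_equal(a.profile.pi, b.profile.pi)

    def test_profile_entries_valid(self, burgers_system):
        res = pde_stride(burgers_system, SolverConfig(method="iht_d"),
                         StabilityConfig(seed=1, B=40))
        assert res.profile.pi.min() >= 0.0 and res.profile.pi.max() <= 1.0
        assert res.profile.pi.shape == (20, 19)

    def test_coefficients_defined_on_support(self, burgers_system):
        res = pde_stride(burgers_system, SolverConfig(method="iht_d"),
                         StabilityConfig(seed=2, B=40))
        assert set(res.coefficients) == set(res.stable_support)
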