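"""Achievability and method-comparison studies on the benchmark systems.

A *trial* at a design point (N, p, sigma) draws a fresh noise realization
and a fresh uniform sample of N space-time points, assembles the design,
runs the chosen inference mode, and declares success iff the recovered
support equals the true support exactly (no extras, no misses).  Success
frequencies over independent repetitions, swept over N, trace the
phase-transition (achievability) curve; the smallest N whose frequency
reaches 90% estimates the sample complexity.

The clean simulations are expensive and deterministic, so they are
computed once per process and cached; per-repetition randomness re-draws
the noise and the sampled points only.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .dictionary import (
    DesignSystem,
    ReactionDictionarySpec,
    Term,
    build_design,
    burgers_terms,
    gray_scott_terms,
    par_reaction_terms,
    standardize,
    vorticity_terms,
)
from .fields import NoiseSpec, SpatioTemporalField, add_noise
from .preprocess import svd_denoise, valid_sample_mask
from .simulators import (
    BurgersConfig,
    CavityConfig,
    GrayScottConfig,
    ParOdeConfig,
    simulate_burgers,
    simulate_cavity_vorticity,
    simulate_gray_scott,
    simulate_par_ode,
)
from .solvers import SolverConfig, solve_path
from .stability import (
    SelectionResult,
    StabilityConfig,
    pde_stride,
    stability_selection_profile,
)

__all__ = [
    "DesignPoint",
    "AchievabilityResult",
    "BenchmarkProblem",
    "get_problem",
    "benchmark_selection",
    "success_trial",
    "achievability_grid",
    "sample_complexity",
    "method_comparison",
]


@dataclass(frozen=True)
class DesignPoint:
    """One (problem, N, sigma, method, mode) configuration."""

    problem: str
    N: int
    sigma: float = 0.0
    method: str = "iht_d"
    mode: str = "stability"  # or "raw-path"

    def __post_init__(self) -> None:
        if self.N <= 0:
            raise ValueError("N must be positive")
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")
        if self.mode not in ("stability", "raw-path"):
            raise ValueError("mode must be 'stability' or 'raw-path'")


@dataclass
class AchievabilityResult:
    """Success frequencies with Bernoulli variances f(1-f)/reps."""

    points: List[DesignPoint]
    frequencies: np.ndarray
    variances: np.ndarray
    repetitions: int

    def as_rows(self) -> List[Dict]:
        rows = []
        for pt, f, v in zip(self.points, self.frequencies, self.variances):
            rows.append(
                dict(
                    problem=pt.problem, N=pt.N, sigma=pt.sigma,
                    method=pt.method, mode=pt.mode,
                    reps=self.repetitions, frequency=float(f),
                    variance=float(v),
                )
            )
        return rows


# ----------------------------------------------------------------------
# Benchmark problems
# ----------------------------------------------------------------------

@dataclass
class BenchmarkProblem:
    """A ground-truth system plus its dictionary and sampling rules."""

    name: str
    terms: List[Term]
    target: str
    truth: Tuple[str, ...]          # true support labels (constant excluded)
    simulate: callable
    region: Optional[Tuple[Tuple[float, float], ...]] = None
    max_order: int = 4
    denoise_rank: Optional[int] = None  # fixed rank; None -> elbow
    # extra wall-adjacent layers excluded from sampling beyond the stencil
    # margin; wall-bounded flows use a wider ring because the low-order
    # wall-vorticity closure contaminates boundary-adjacent values
    boundary_margin: int = 0

    def clean_field(self) -> SpatioTemporalField:
        key = self.name
        if key not in _SIM_CACHE:
            _SIM_CACHE[key] = self.simulate()
        return _SIM_CACHE[key]


_SIM_CACHE: Dict[str, SpatioTemporalField] = {}
_POOL_CACHE: Dict[Tuple, DesignSystem] = {}


def _registry() -> Dict[str, BenchmarkProblem]:
    return {
        "burgers": BenchmarkProblem(
            name="burgers",
            terms=burgers_terms(),
            target="u",
            truth=("u*u_{x}", "u_{xx}"),
            simulate=lambda: simulate_burgers(BurgersConfig()),
            max_order=4,
        ),
        "vorticity": BenchmarkProblem(
            name="vorticity",
            terms=vorticity_terms(),
            target="w",
            truth=("w_{xx}", "w_{yy}", "u*w_{x}", "v*w_{y}"),
            simulate=lambda: simulate_cavity_vorticity(CavityConfig()),
            region=((0.0, 1.0), (0.6, 1.0)),
            max_order=2,
            boundary_margin=3,
        ),
        # reduced-resolution study conditions: 64^3 grid, coarser explicit
        # Euler step, last 8 frames stored
        "grayscott": BenchmarkProblem(
            name="grayscott",
            terms=gray_scott_terms(),
            target="u",
            truth=("u_{xx}", "u_{yy}", "u_{zz}", "u", "u*v^2"),
            simulate=lambda: simulate_gray_scott(
                GrayScottConfig(n=64, dt=0.01, t_final=5.0, n_save=8)
            ),
            region=((1.0, 1.5),) * 3,
            max_order=2,
        ),
        "par_P": BenchmarkProblem(
            name="par_P",
            terms=par_reaction_terms(),
            target="P",
            truth=("P", "A*P^2"),
            simulate=lambda: simulate_par_ode(ParOdeConfig()),
            max_order=2,
        ),
        "par_A": BenchmarkProblem(
            name="par_A",
            terms=par_reaction_terms(),
            target="A",
            truth=("A", "A^2*P"),
            simulate=lambda: simulate_par_ode(ParOdeConfig()),
            max_order=2,
        ),
    }


_PROBLEMS = _registry()


def get_problem(name: str) -> BenchmarkProblem:
    try:
        return _PROBLEMS[name]
    except KeyError:
        raise KeyError(
            f"unknown problem {name!r}; choose from {sorted(_PROBLEMS)}"
        ) from None


# ----------------------------------------------------------------------
# Design pools: the full-eligibility design, cached for clean data
# ----------------------------------------------------------------------

def design_pool(
    problem: BenchmarkProblem,
    sigma: float,
    noise_seed: int = 0,
    denoise: str = "auto",
) -> DesignSystem:
    """Design system evaluated at every eligible space-time point.

    Per-trial systems are uniform row subsets of this pool, which makes
    repeated trials at different N cheap.  Noisy data are denoised by
    truncated SVD before differentiation when ``denoise`` is "auto"
    (the default: denoise iff sigma > 0) or "always".
    """
    if sigma == 0.0:
        noise_seed = 0  # clean pools are noise-independent
    key = (problem.name, float(sigma), int(noise_seed), denoise)
    if sigma == 0.0 and key in _POOL_CACHE:
        return _POOL_CACHE[key]
    field = problem.clean_field()
    if sigma > 0:
        field = add_noise(field, NoiseSpec(sigma=sigma, seed=noise_seed))
    if denoise == "always" or (denoise == "auto" and sigma > 0):
        field, _reports = svd_denoise(field, rank=problem.denoise_rank)
    mask = valid_sample_mask(field, problem.max_order, problem.region)
    if problem.boundary_margin and field.boundary != "periodic":
        m = problem.boundary_margin
        for ax in range(field.ndim_space):
            sl = [slice(None)] * (field.ndim_space + 1)
            sl[ax + 1] = slice(0, m)
            mask[tuple(sl)] = False
            sl[ax + 1] = slice(field.shape[ax + 1] - m, None)
            mask[tuple(sl)] = False
    samples = np.stack(np.nonzero(mask), axis=1)
    system = build_design(field, problem.terms, samples, problem.target)
    if sigma == 0.0:
        _POOL_CACHE[key] = system
    return system


def _subset_rows(system: DesignSystem, rows: np.ndarray) -> DesignSystem:
    return DesignSystem(
        theta=system.theta[rows],
        ut=system.ut[rows],
        labels=system.labels,
        sample_indices=None
        if system.sample_indices is None
        else system.sample_indices[rows],
        constant_index=system.constant_index,
    )


def trial_system(
    problem: BenchmarkProblem,
    N: int,
    sigma: float,
    sample_seed: int,
    noise_seed: int = 0,
    denoise: str = "auto",
) -> DesignSystem:
    """N-point design with fresh uniform sampling (and noise, if sigma>0)."""
    pool = design_pool(problem, sigma, noise_seed, denoise)
    if N > pool.n_samples:
        raise ValueError(
            f"N={N} exceeds the {pool.n_samples} eligible points"
        )
    rng = np.random.default_rng(sample_seed)
    rows = rng.choice(pool.n_samples, size=N, replace=False)
    return _subset_rows(pool, rows)


def benchmark_selection(
    problem_name: str,
    N: int,
    sigma: float = 0.0,
    seed: int = 0,
    solver_config: Optional[SolverConfig] = None,
    stability_config: Optional[StabilityConfig] = None,
    denoise: str = "auto",
) -> SelectionResult:
    """One full PDE-STRIDE run on a benchmark at the given design point."""
    problem = get_problem(problem_name)
    rng = np.random.default_rng(seed)
    sample_seed = int(rng.integers(2**31))
    noise_seed = int(rng.integers(2**31))
    system = trial_system(problem, N, sigma, sample_seed, noise_seed, denoise)
    stab = stability_config or StabilityConfig(seed=int(rng.integers(2**31)))
    return pde_stride(system, solver_config, stab)


# ----------------------------------------------------------------------
# Success trials and achievability
# ----------------------------------------------------------------------

def _truth_nonconstant(truth: Sequence[str]) -> frozenset:
    return frozenset(t for t in truth if t != "1")


def success_trial(
    point: DesignPoint,
    truth: Optional[Sequence[str]] = None,
    seed: int = 0,
    solver_config: Optional[SolverConfig] = None,
    stability_config: Optional[StabilityConfig] = None,
    denoise: str = "auto",
) -> bool:
    """One repetition: success iff some lambda recovers the truth exactly.

    In "stability" mode the candidate set at each lambda is the
    pi-thresholded importance set; in "raw-path" mode it is the solver's
    support on the full-system path.  An explicit constant column is
    unpenalized and excluded from the comparison.
    """
    problem = get_problem(point.problem)
    truth_set = _truth_nonconstant(truth if truth is not None else problem.truth)
    labels_all = {t.label for t in problem.terms}
    if not truth_set <= labels_all:
        return False
    rng = np.random.default_rng(seed)
    sample_seed = int(rng.integers(2**31))
    noise_seed = int(rng.integers(2**31))
    run_seed = int(rng.integers(2**31))
    system = trial_system(
        problem, point.N, point.sigma, sample_seed, noise_seed, denoise
    )
    scfg = solver_config or SolverConfig(method=point.method)
    if scfg.method != point.method:
        scfg = replace(scfg, method=point.method)
    if point.mode == "stability":
        stab = stability_config or StabilityConfig()
        stab = replace(stab, seed=run_seed)
        profile = stability_selection_profile(system, scfg, stab)
        thresholded = profile.pi >= stab.pi_threshold
        labels = np.asarray(profile.labels)
        for m in range(thresholded.shape[0]):
            if frozenset(labels[thresholded[m]]) == truth_set:
                return True
        return False
    # raw-path mode
    scfg = replace(scfg, seed=run_seed)
    std = standardize(system)
    path = solve_path(std, scfg)
    label_arr = np.asarray(std.labels)
    for sup in path.supports:
        if frozenset(label_arr[list(sup)]) == truth_set:
            return True
    return False


def achievability_grid(
    points: Sequence[DesignPoint],
    truth: Optional[Sequence[str]] = None,
    reps: int = 20,
    seed: int = 0,
    solver_config: Optional[SolverConfig] = None,
    stability_config: Optional[StabilityConfig] = None,
    denoise: str = "auto",
) -> AchievabilityResult:
    """Success frequency per design point over independent repetitions.

    Each repetition re-draws the sampled points and (for sigma > 0) the
    noise realization, with repetition seeds derived from ``seed``.
    """
    if reps < 1:
        raise ValueError("reps must be at least 1")
    rng = np.random.default_rng(seed)
    freqs = np.empty(len(points))
    for i, pt in enumerate(points):
        wins = 0
        for _rep in range(reps):
            trial_seed = int(rng.integers(2**31))
            wins += success_trial(
                pt, truth, trial_seed, solver_config, stability_config, denoise
            )
        freqs[i] = wins / reps
    variances = freqs * (1.0 - freqs) / reps
    return AchievabilityResult(
        points=list(points), frequencies=freqs, variances=variances,
        repetitions=reps,
    )


def sample_complexity(
    result: AchievabilityResult, level: float = 0.9
) -> Optional[int]:
    """Smallest N in the grid whose success frequency reaches ``level``.

    Returns None when no grid point crosses the level ("not reached").
    """
    crossing = [
        (pt.N, f)
        for pt, f in zip(result.points, result.frequencies)
        if f >= level
    ]
    if not crossing:
        return None
    return min(n for n, _ in crossing)


def method_comparison(
    points: Sequence[DesignPoint],
    methods: Sequence[str] = ("randomized_lasso", "stridge", "iht_d", "omp"),
    reps: int = 30,
    seed: int = 0,
    truth: Optional[Sequence[str]] = None,
) -> AchievabilityResult:
    """Raw-path success frequencies across (N, sigma) x method."""
    expanded = [
        replace(pt, method=m, mode="raw-path") for m in methods for pt in points
    ]
    return achievability_grid(expanded, truth=truth, reps=reps, seed=seed)
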