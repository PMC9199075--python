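"""Stability selection: subsampling, importance profiles, stable support.

The pipeline (``pde_stride``) draws B random half-subsamples of the rows
of the design system, re-standardizes each, solves a regularization path
per subsample on a shared lambda grid, aggregates per-component selection
frequencies into importance profiles, thresholds the profile at the
smallest lambda to obtain the stable support, and refits that support by
ordinary least squares on the full unstandardized system so that the
coefficients carry physical units.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .dictionary import DesignSystem, standardize
from .solvers import (
    RegularizationPath,
    SolverConfig,
    batched_l0_path_supports,
    draw_randomization_weights,
    lambda_max,
    make_path,
    solve_path,
)

__all__ = [
    "StabilityConfig",
    "ImportanceProfile",
    "SelectionResult",
    "subsample_systems",
    "importance_profile",
    "stable_support",
    "refit",
    "pde_stride",
]


@dataclass
class StabilityConfig:
    """Stability-selection parameters (defaults are the standard settings)."""

    B: int = 250
    subsample_fraction: float = 0.5
    M: int = 20
    epsilon: float = 0.1
    pi_threshold: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.B < 1:
            raise ValueError("B must be at least 1")
        if not 0 < self.pi_threshold <= 1:
            raise ValueError("pi_threshold must lie in (0, 1]")
        if not 0 < self.subsample_fraction < 1:
            raise ValueError("subsample_fraction must lie in (0, 1)")


@dataclass
class ImportanceProfile:
    """Selection frequency of every component along the lambda grid.

    ``pi[m, k]`` is the fraction of subsamples whose support at
    ``lambdas[m]`` contains component k.
    """

    pi: np.ndarray                # (M, p), entries in [0, 1]
    lambdas: np.ndarray           # (M,), descending
    labels: Tuple[str, ...]

    def __post_init__(self) -> None:
        if np.any(self.pi < 0) or np.any(self.pi > 1):
            raise ValueError("importance values must lie in [0, 1]")
        if self.pi.shape != (len(self.lambdas), len(self.labels)):
            raise ValueError("profile shape inconsistent with grid/labels")


@dataclass
class SelectionResult:
    """Stable support with refit coefficients and diagnostics."""

    stable_support: Tuple[str, ...]
    coefficients: Dict[str, float]     # physical-scale values on the support
    profile: ImportanceProfile
    solver_config: SolverConfig
    stability_config: StabilityConfig

    def __post_init__(self) -> None:
        if set(self.coefficients) != set(self.stable_support):
            raise ValueError("coefficients must be defined exactly on the support")


# ----------------------------------------------------------------------


def _draw_index_sets(n: int, cfg: StabilityConfig) -> np.ndarray:
    rng = np.random.default_rng(cfg.seed)
    size = int(np.floor(n * cfg.subsample_fraction))
    return np.stack(
        [rng.choice(n, size=size, replace=False) for _ in range(cfg.B)]
    )


def subsample_systems(
    system: DesignSystem, cfg: StabilityConfig
) -> List[DesignSystem]:
    """B independent row-subsets of size floor(N/2), each re-standardized."""
    n = system.n_samples
    if n < 4:
        raise ValueError("need at least 4 samples to subsample")
    if n < 2 * system.n_terms:
        warnings.warn("sample size below 2p; subsampled fits may be unstable")
    idx_sets = _draw_index_sets(n, cfg)
    out = []
    for rows in idx_sets:
        sub = DesignSystem(
            theta=system.theta[rows],
            ut=system.ut[rows],
            labels=system.labels,
            sample_indices=None
            if system.sample_indices is None
            else system.sample_indices[rows],
            constant_index=system.constant_index,
        )
        out.append(standardize(sub))
    return out


def importance_profile(
    subpaths: Sequence[RegularizationPath], cfg: StabilityConfig
) -> ImportanceProfile:
    """Fraction of subsamples selecting each component at each lambda."""
    if not subpaths:
        raise ValueError("no paths given")
    grid = subpaths[0].lambdas
    labels = subpaths[0].labels
    for path in subpaths[1:]:
        if path.lambdas.shape != grid.shape or not np.allclose(
            path.lambdas, grid
        ):
            raise ValueError("all paths must share one lambda grid")
        if path.labels != labels:
            raise ValueError("all paths must share one label set")
    counts = np.zeros((grid.size, len(labels)))
    for path in subpaths:
        for m, sup in enumerate(path.supports):
            counts[m, list(sup)] += 1.0
    return ImportanceProfile(
        pi=counts / len(subpaths), lambdas=grid, labels=labels
    )


def _profile_from_bool(
    selected: np.ndarray, lambdas: np.ndarray, labels: Tuple[str, ...]
) -> ImportanceProfile:
    return ImportanceProfile(
        pi=selected.mean(axis=0), lambdas=lambdas, labels=labels
    )


def stable_support(
    profile: ImportanceProfile, cfg: StabilityConfig
) -> Tuple[str, ...]:
    """Components whose importance at lambda_min reaches the threshold (>=)."""
    pi_min = profile.pi[-1]
    keep = pi_min >= cfg.pi_threshold
    return tuple(l for l, k in zip(profile.labels, keep) if k)


def refit(system_raw: DesignSystem, support: Sequence[str]) -> Dict[str, float]:
    """Ordinary least squares of Ut on the supported raw columns.

    Uses the full (unstandardized) system, so coefficients are on the
    physical scale of the dictionary terms.
    """
    support = list(support)
    if not support:
        raise ValueError("empty support")
    if system_raw.standardized:
        raise ValueError("refit expects the raw (unstandardized) system")
    idx = [system_raw.labels.index(l) for l in support]
    sub = system_raw.theta[:, idx]
    coef, _res, rank, _sv = np.linalg.lstsq(sub, system_raw.ut, rcond=None)
    if rank < len(support):
        raise ValueError(
            f"restricted design is rank-deficient; collinear among {support}"
        )
    return dict(zip(support, (float(c) for c in coef)))


# ----------------------------------------------------------------------


def stability_selection_profile(
    system_raw: DesignSystem,
    solver_config: SolverConfig,
    cfg: StabilityConfig,
) -> ImportanceProfile:
    """Importance profile of the full PDE-STRIDE subsampling stage.

    The lambda grid is fixed once from the standardized full system so all
    subsample paths share it.  IHT / IHT-d run through the batched kernel;
    other methods solve per-subsample paths.
    """
    std_full = standardize(system_raw)
    lam_max = lambda_max(std_full, solver_config.method, solver_config)
    if lam_max <= 0:
        raise ValueError("degenerate system: lambda_max is zero")
    grid = make_path(lam_max, cfg.epsilon, cfg.M)
    subs = subsample_systems(system_raw, cfg)
    labels = subs[0].labels

    if solver_config.method == "iht_d":
        thetas = np.stack([s.theta for s in subs])
        uts = np.stack([s.ut for s in subs])
        selected = batched_l0_path_supports(thetas, uts, grid, solver_config)
        return _profile_from_bool(selected, grid, labels)

    rng = np.random.default_rng(cfg.seed + 1)
    paths = []
    for sub in subs:
        weights = None
        if solver_config.method == "randomized_lasso":
            weights = draw_randomization_weights(
                sub.n_terms, solver_config.alpha,
                int(rng.integers(2**31)),
            )
        paths.append(
            solve_path(sub, solver_config, lambdas=grid, weights=weights)
        )
    return importance_profile(paths, cfg)


def pde_stride(
    system: DesignSystem,
    solver_config: Optional[SolverConfig] = None,
    stability_config: Optional[StabilityConfig] = None,
) -> SelectionResult:
    """Full stability-based identification on an assembled design system.

    Subsample -> standardize -> per-subsample lambda paths -> importance
    profile -> threshold at lambda_min -> least-squares refit on the raw
    system.  A constant dictionary column, if present, is unpenalized
    (absorbed by centering) and therefore always part of the model.
    """
    solver_config = solver_config or SolverConfig()
    stability_config = stability_config or StabilityConfig()
    profile = stability_selection_profile(system, solver_config, stability_config)
    support = list(stable_support(profile, stability_config))
    if system.constant_index is not None:
        support.insert(0, system.labels[system.constant_index])
    coefficients = refit(system, support) if support else {}
    return SelectionResult(
        stable_support=tuple(support),
        coefficients=coefficients,
        profile=profile,
        solver_config=solver_config,
        stability_config=stability_config,
    )
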