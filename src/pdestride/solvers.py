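"""Sparsity-promoting regression solvers over a regularization path.

All solvers act on *standardized* design systems (columns centered with
unit mean square, response centered) and are pure functions of
``(system, lambda, config, seed)``.

The l0 family (IHT, IHT-d, STRidge, OMP) treats lambda as the direct
magnitude threshold of the hard-thresholding operator: entries with
``|x| <= lambda`` are zeroed.  For IHT and IHT-d the design and response
are first jointly rescaled so the spectral norm of Theta is below one,
which is the regime where hard-thresholded Landweber iterations are
guaranteed not to increase the l0 objective; joint rescaling leaves the
regression coefficients unchanged.

IHT-d interleaves each thresholding step with a debiasing stage that
refits the coefficients on the current support by restricted least
squares (skipped when the residual already satisfies the loose
confidence bound), so its lambda acts on debiased coefficient
magnitudes rather than on single gradient steps.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
from sklearn.linear_model import OrthogonalMatchingPursuit

from .dictionary import DesignSystem

__all__ = [
    "SolverConfig",
    "RegularizationPath",
    "lambda_max",
    "make_path",
    "fit_lasso",
    "draw_randomization_weights",
    "fit_iht",
    "fit_iht_d",
    "fit_stridge",
    "fit_omp",
    "fit",
    "solve_path",
    "batched_l0_path_supports",
]

_METHODS = ("lasso", "randomized_lasso", "iht", "iht_d", "stridge", "omp")
_SPECTRAL_DELTA = 1e-3


@dataclass
class SolverConfig:
    """Knobs shared by the solver family.

    alpha
        Weakness of randomized LASSO: per-column penalty weights are drawn
        i.i.d. from Uniform[alpha, 1].
    ridge_lambda
        Ridge penalty of the STRidge inner solves.
    descent_monitor_c
        Constant c of the sufficient-decrease check
        ||r_{n+1}||^2 < (1 - c) ||r_n||^2 used to monitor IHT descent.
    l0_threshold_mode
        "direct": lambda is the magnitude threshold (default);
        "penalty": lambda is the l0 penalty weight, threshold sqrt(2*lambda).
    """

    method: str = "iht_d"
    alpha: float = 0.2
    ridge_lambda: float = 1e-5
    max_iter: int = 200
    tol: float = 1e-9
    debias_max_steps: int = 100
    descent_monitor_c: float = 1e-4
    seed: int = 0
    l0_threshold_mode: str = "direct"

    def __post_init__(self) -> None:
        if self.method not in _METHODS:
            raise ValueError(f"unknown method {self.method!r}")
        if not 0 < self.alpha <= 1:
            raise ValueError("alpha must lie in (0, 1]")
        if self.ridge_lambda < 0:
            raise ValueError("ridge_lambda must be non-negative")
        if not 0 < self.descent_monitor_c < 1:
            raise ValueError("descent_monitor_c must lie in (0, 1)")
        if self.l0_threshold_mode not in ("direct", "penalty"):
            raise ValueError("l0_threshold_mode must be 'direct' or 'penalty'")


@dataclass
class RegularizationPath:
    """Per-lambda supports and coefficients on a geometric lambda grid."""

    lambdas: np.ndarray                  # (M,), descending
    supports: List[Tuple[int, ...]]      # per-lambda sorted column indices
    coefficients: np.ndarray             # (M, p)
    labels: Tuple[str, ...]
    epsilon: float

    @property
    def lambda_max(self) -> float:
        return float(self.lambdas[0])

    @property
    def lambda_min(self) -> float:
        return float(self.lambdas[-1])

    def __post_init__(self) -> None:
        for m, sup in enumerate(self.supports):
            nz = tuple(np.flatnonzero(self.coefficients[m]))
            if tuple(sup) != nz:
                raise ValueError("recorded support inconsistent with coefficients")


def _require_standardized(system: DesignSystem) -> None:
    if not system.standardized:
        raise ValueError("solver requires a standardized design system")


def _threshold_value(lam: float, config: SolverConfig) -> float:
    if config.l0_threshold_mode == "penalty":
        return float(np.sqrt(2.0 * lam))
    return float(lam)


def _spectral_scale(theta: np.ndarray) -> float:
    smax = np.linalg.norm(theta, 2)
    if smax == 0:
        raise ValueError("design matrix is identically zero")
    return 1.0 / (smax * (1.0 + _SPECTRAL_DELTA))


def lambda_max(
    system: DesignSystem,
    method: str = "iht_d",
    config: Optional[SolverConfig] = None,
) -> float:
    """Smallest lambda for which the solver returns the empty support.

    For the l1 family this is the classic ``max_k |theta_k . ut|``.  For
    plain IHT it is the largest coefficient magnitude after one gradient
    step from zero on the spectrally rescaled system; for the debiased
    variants (IHT-d, STRidge) lambda thresholds refit coefficients, so it
    is the largest magnitude of the full least-squares (resp. ridge)
    solution.
    """
    _require_standardized(system)
    config = config or SolverConfig(method=method)
    if not np.any(system.ut):
        raise ValueError("zero response vector")
    g = system.theta.T @ system.ut
    gmax = float(np.max(np.abs(g)))
    if gmax == 0.0:
        return 0.0  # degenerate: response orthogonal to every column
    if method in ("lasso", "randomized_lasso"):
        return gmax
    if method == "stridge":
        p = system.n_terms
        G = system.theta.T @ system.theta + config.ridge_lambda * np.eye(p)
        coef = np.linalg.solve(G, g)
        return float(np.max(np.abs(coef)))
    if method == "iht_d" and system.n_samples >= system.n_terms:
        # lambda thresholds the *debiased* coefficients, so the empty
        # model appears once lambda exceeds every least-squares magnitude
        coef, *_ = np.linalg.lstsq(system.theta, system.ut, rcond=None)
        return float(np.max(np.abs(coef)))
    # iht (and underdetermined iht_d) / omp: one gradient step from zero
    # after rescaling
    s = _spectral_scale(system.theta)
    return s**2 * gmax


def make_path(
    lam_max: float, epsilon: float = 0.1, M: int = 20
) -> np.ndarray:
    """Geometric grid of M lambdas from lambda_max down to epsilon*lambda_max."""
    if lam_max <= 0:
        raise ValueError("lambda_max must be positive")
    if M < 2:
        raise ValueError("path needs at least two lambdas")
    if not 0 < epsilon < 1:
        raise ValueError("epsilon must lie in (0, 1)")
    return lam_max * epsilon ** (np.arange(M) / (M - 1))


# ----------------------------------------------------------------------
# LASSO / randomized LASSO by cyclical coordinate descent
# ----------------------------------------------------------------------

def _soft(x: float, t: float) -> float:
    return np.sign(x) * max(abs(x) - t, 0.0)


def fit_lasso(
    system: DesignSystem,
    lam: float,
    weights: Optional[np.ndarray] = None,
    config: Optional[SolverConfig] = None,
    xi0: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Minimize 1/2 ||ut - Theta xi||^2 + lam * sum_k |xi_k| / W_k.

    Cyclical coordinate descent; ``weights`` (the randomized-LASSO W_k in
    [alpha, 1]) default to 1.  Deterministic given inputs.
    """
    _require_standardized(system)
    config = config or SolverConfig(method="lasso")
    theta, ut = system.theta, system.ut
    n, p = theta.shape
    if weights is None:
        lam_k = np.full(p, lam)
    else:
        weights = np.asarray(weights, float)
        if weights.shape != (p,) or np.any(weights <= 0) or np.any(weights > 1):
            raise ValueError("weights must be p values in (0, 1]")
        lam_k = lam / weights
    xi = np.zeros(p) if xi0 is None else xi0.astype(float).copy()
    col_sq = np.einsum("np,np->p", theta, theta)
    r = ut - theta @ xi
    for sweep in range(max(config.max_iter, 2000)):
        delta_max = 0.0
        for k in range(p):
            if col_sq[k] == 0:
                continue
            old = xi[k]
            rho = theta[:, k] @ r + col_sq[k] * old
            new = _soft(rho, lam_k[k]) / col_sq[k]
            if new != old:
                r += theta[:, k] * (old - new)
                xi[k] = new
                delta_max = max(delta_max, abs(new - old))
        if delta_max <= config.tol * max(1.0, float(np.max(np.abs(xi)))):
            break
    else:
        warnings.warn("LASSO coordinate descent did not converge")
    return xi


def lasso_kkt_violation(
    system: DesignSystem, lam: float, xi: np.ndarray,
    weights: Optional[np.ndarray] = None,
) -> float:
    """Max KKT violation of a LASSO solution (0 at optimum)."""
    p = system.n_terms
    lam_k = np.full(p, lam) if weights is None else lam / np.asarray(weights)
    g = system.theta.T @ (system.ut - system.theta @ xi)
    viol = np.where(
        xi != 0,
        np.abs(g - lam_k * np.sign(xi)),
        np.maximum(np.abs(g) - lam_k, 0.0),
    )
    return float(np.max(viol))


def draw_randomization_weights(p: int, alpha: float, seed: int) -> np.ndarray:
    """p i.i.d. Uniform[alpha, 1] penalty weights."""
    if not 0 < alpha <= 1:
        raise ValueError("alpha must lie in (0, 1]")
    if alpha == 1.0:
        return np.ones(p)
    return np.random.default_rng(seed).uniform(alpha, 1.0, size=p)


# ----------------------------------------------------------------------
# IHT and IHT-d
# ----------------------------------------------------------------------

def _hard_threshold(x: np.ndarray, thr: float) -> np.ndarray:
    out = x.copy()
    # tiny relative slack so lambda = lambda_max yields the empty model
    # regardless of last-ulp differences between evaluation orders
    out[np.abs(out) <= thr * (1.0 + 1e-12)] = 0.0
    return out


def _debias_bound(thr: float, support_size) -> float:
    """Loose residual bound ending the debias stage.

    Debiasing stops once ||r||^2 <= (thr^2 / 2) * |S|: with the hard
    threshold thr the implied l0 penalty weight is thr^2/2, and the bound
    says the data-fit term no longer dominates the model-complexity term,
    which attributes low confidence to large supports.
    """
    return 0.5 * thr**2 * support_size


def fit_iht(
    system: DesignSystem,
    lam: float,
    config: Optional[SolverConfig] = None,
    xi0: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Iterative hard thresholding: xi <- H_lam(xi + Theta'(ut - Theta xi)).

    Theta and ut are jointly rescaled so ||Theta||_2 < 1 (coefficients are
    invariant under the joint rescaling).  Iterates until the support and
    values stabilize; a monotone-descent monitor guards against divergence.
    """
    _require_standardized(system)
    config = config or SolverConfig(method="iht")
    thr = _threshold_value(lam, config)
    s = _spectral_scale(system.theta)
    theta, ut = s * system.theta, s * system.ut
    xi = np.zeros(system.n_terms) if xi0 is None else xi0.astype(float).copy()
    r = ut - theta @ xi
    res2 = float(r @ r)
    for _ in range(config.max_iter):
        xi_new = _hard_threshold(xi + theta.T @ r, thr)
        r_new = ut - theta @ xi_new
        res2_new = float(r_new @ r_new)
        moved = float(np.max(np.abs(xi_new - xi))) if xi.size else 0.0
        if moved <= config.tol * max(1.0, float(np.max(np.abs(xi_new), initial=0.0))):
            xi = xi_new
            break
        if res2_new >= (1.0 - config.descent_monitor_c) * res2 and res2_new > res2:
            warnings.warn("IHT descent monitor violated; returning last iterate")
            return xi
        xi, r, res2 = xi_new, r_new, res2_new
    return xi


def fit_iht_d(
    system: DesignSystem,
    lam: float,
    config: Optional[SolverConfig] = None,
    xi0: Optional[np.ndarray] = None,
) -> np.ndarray:
    """IHT with debiasing.

    Each iteration takes one thresholded gradient step to extract a
    candidate support, then debiases the coefficients by solving the
    least-squares problem restricted to that support (the debias stage is
    skipped when the residual already satisfies the loose confidence
    bound).  The outer loop runs to support convergence; a revisited
    support (2-cycle) ends the iteration at the support with the lower
    l0 objective.

    Because lambda thresholds debiased (least-squares scale) magnitudes,
    the iteration starts from the hard-thresholded full least-squares
    estimate whenever the system is overdetermined, and from zero
    otherwise.
    """
    _require_standardized(system)
    config = config or SolverConfig(method="iht_d")
    thr = _threshold_value(lam, config)
    s = _spectral_scale(system.theta)
    theta, ut = s * system.theta, s * system.ut
    p = system.n_terms

    def debiased(support) -> np.ndarray:
        idx = list(support)
        coef, *_ = np.linalg.lstsq(theta[:, idx], ut, rcond=None)
        out = np.zeros(p)
        out[idx] = coef
        return out

    def objective(x: np.ndarray) -> float:
        r = ut - theta @ x
        return 0.5 * float(r @ r) + _debias_bound(thr, np.count_nonzero(x))

    if xi0 is not None:
        xi = xi0.astype(float).copy()
    elif system.n_samples >= p:
        coef, *_ = np.linalg.lstsq(theta, ut, rcond=None)
        xi = _hard_threshold(coef, thr)
    else:
        xi = np.zeros(p)
    history: List[Tuple[int, ...]] = []
    for _ in range(config.max_iter):
        r = ut - theta @ xi
        xi_new = _hard_threshold(xi + theta.T @ r, thr)
        support = tuple(np.flatnonzero(xi_new))
        if not support:
            return np.zeros(p)
        res2 = float((ut - theta @ xi_new) @ (ut - theta @ xi_new))
        if res2 > _debias_bound(thr, len(support)):
            xi_next = debiased(support)
        else:
            xi_next = xi_new
        if history and support == history[-1]:
            xi = xi_next
            break
        if len(history) >= 2 and support == history[-2]:
            # 2-cycle: keep the better of the two supports
            alt = debiased(history[-1])
            xi = xi_next if objective(xi_next) <= objective(alt) else alt
            break
        history.append(support)
        xi = xi_next
    return xi


def debias_restricted_lstsq(
    system: DesignSystem, support: Sequence[int]
) -> np.ndarray:
    """Exact restricted least squares (the limit of the debias iteration)."""
    _require_standardized(system)
    idx = list(support)
    coef, *_ = np.linalg.lstsq(system.theta[:, idx], system.ut, rcond=None)
    out = np.zeros(system.n_terms)
    out[idx] = coef
    return out


# ----------------------------------------------------------------------
# STRidge
# ----------------------------------------------------------------------

def fit_stridge(
    system: DesignSystem,
    lam: float,
    config: Optional[SolverConfig] = None,
    xi0: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Sequential thresholding of ridge regression.

    Repeats {ridge solve on the active set, zero out |xi_k| < lam} until
    the support is fixed.  lam = 0 returns the plain ridge solution.
    """
    _require_standardized(system)
    config = config or SolverConfig(method="stridge")
    theta, ut = system.theta, system.ut
    p = system.n_terms
    active = np.ones(p, dtype=bool)
    xi = np.zeros(p)
    for _ in range(max(p, 10)):
        if not active.any():
            return np.zeros(p)
        idx = np.flatnonzero(active)
        sub = theta[:, idx]
        G = sub.T @ sub + config.ridge_lambda * np.eye(idx.size)
        coef = np.linalg.solve(G, sub.T @ ut)
        xi = np.zeros(p)
        xi[idx] = coef
        new_active = np.abs(xi) >= lam if lam > 0 else xi != 0
        if np.array_equal(new_active, active):
            break
        active = new_active
    xi[~active] = 0.0
    return xi


# ----------------------------------------------------------------------
# OMP (delegated to scikit-learn)
# ----------------------------------------------------------------------

def fit_omp(system: DesignSystem, k: int) -> np.ndarray:
    """Greedy residual-correlation selection with per-step restricted refit."""
    _require_standardized(system)
    p = system.n_terms
    if k <= 0:
        return np.zeros(p)
    k = min(k, p, system.n_samples)
    omp = OrthogonalMatchingPursuit(n_nonzero_coefs=k, fit_intercept=False)
    omp.fit(system.theta, system.ut)
    return np.asarray(omp.coef_, float)


# ----------------------------------------------------------------------
# Path construction
# ----------------------------------------------------------------------

def fit(
    system: DesignSystem,
    lam: float,
    config: SolverConfig,
    weights: Optional[np.ndarray] = None,
    xi0: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Dispatch a single-lambda solve to the configured method."""
    m = config.method
    if m == "lasso":
        return fit_lasso(system, lam, None, config, xi0)
    if m == "randomized_lasso":
        if weights is None:
            weights = draw_randomization_weights(
                system.n_terms, config.alpha, config.seed
            )
        return fit_lasso(system, lam, weights, config, xi0)
    if m == "iht":
        return fit_iht(system, lam, config, xi0)
    if m == "iht_d":
        return fit_iht_d(system, lam, config, xi0)
    if m == "stridge":
        return fit_stridge(system, lam, config, xi0)
    raise ValueError(f"method {m!r} has no single-lambda solver (use solve_path)")


def solve_path(
    system: DesignSystem,
    config: SolverConfig,
    lambdas: Optional[np.ndarray] = None,
    epsilon: float = 0.1,
    M: int = 20,
    weights: Optional[np.ndarray] = None,
) -> RegularizationPath:
    """Solve along a descending lambda grid with warm starts.

    For OMP, path position m maps to sparsity level k = m (the empty model
    at lambda_max), following the grid-position convention.
    """
    _require_standardized(system)
    if lambdas is None:
        lam_max = lambda_max(system, config.method, config)
        lambdas = make_path(lam_max, epsilon, M)
    lambdas = np.asarray(lambdas, float)
    if np.any(np.diff(lambdas) > 0):
        raise ValueError("lambda grid must be descending")
    p = system.n_terms
    coefs = np.zeros((lambdas.size, p))
    supports: List[Tuple[int, ...]] = []
    if config.method == "randomized_lasso" and weights is None:
        weights = draw_randomization_weights(p, config.alpha, config.seed)
    # warm starts only for the convex solvers; the l0 iterations are
    # cold-started at every lambda so large-lambda local minima cannot
    # lock in down the path
    warm = config.method in ("lasso", "randomized_lasso")
    xi = None
    for m, lam in enumerate(lambdas):
        if config.method == "omp":
            xi = fit_omp(system, m)
        else:
            xi = fit(system, lam, config, weights=weights, xi0=xi if warm else None)
        coefs[m] = xi
        supports.append(tuple(np.flatnonzero(xi)))
    return RegularizationPath(
        lambdas=lambdas,
        supports=supports,
        coefficients=coefs,
        labels=system.labels,
        epsilon=float(lambdas[-1] / lambdas[0]),
    )


# ----------------------------------------------------------------------
# Batched IHT / IHT-d over many subsampled systems (stability selection)
# ----------------------------------------------------------------------

def batched_l0_path_supports(
    thetas: np.ndarray,
    uts: np.ndarray,
    lambdas: np.ndarray,
    config: SolverConfig,
) -> np.ndarray:
    """Supports of IHT-d along a shared lambda grid for B systems.

    ``thetas`` is (B, n, p) of standardized sub-designs, ``uts`` is (B, n).
    Returns a boolean array (B, M, p).  Identical algorithm to
    :func:`fit_iht` / :func:`fit_iht_d`, vectorized over the batch; the
    debias step size uses the conservative bound 1/||Theta_b||_2^2 <=
    1/||Theta_S||_2^2, which after spectral rescaling is (1 + delta)^2.
    """
    if config.method != "iht_d":
        raise ValueError("batched path supports is specific to iht_d")
    B, n, p = thetas.shape
    svals = np.linalg.svd(thetas, compute_uv=False)
    smax = svals[:, 0]
    if np.any(smax == 0):
        raise ValueError("zero sub-design encountered")
    s = 1.0 / (smax * (1.0 + _SPECTRAL_DELTA))
    th = thetas * s[:, None, None]
    ut = uts * s[:, None]
    debias = True

    # everything below works through the per-slice Gram matrices
    G = np.matmul(th.transpose(0, 2, 1), th)          # (B, p, p)
    c = np.matmul(th.transpose(0, 2, 1), ut[:, :, None])[:, :, 0]  # (B, p)
    uu = np.einsum("bn,bn->b", ut, ut)                # (B,)

    def residual2(x: np.ndarray) -> np.ndarray:
        Gx = np.matmul(G, x[:, :, None])[:, :, 0]
        return uu - 2.0 * np.einsum("bp,bp->b", c, x) + np.einsum(
            "bp,bp->b", x, Gx
        )

    def masked_lstsq(mask: np.ndarray) -> np.ndarray:
        """Restricted least squares for every slice via masked normal
        equations (off-support rows/columns replaced by the identity)."""
        mf = mask.astype(float)
        A = G * mf[:, :, None] * mf[:, None, :]
        diag = np.einsum("bpp->bp", A)
        diag += (1.0 - mf) + 1e-12 * mf
        rhs = c * mf
        try:
            sol = np.linalg.solve(A, rhs[:, :, None])[:, :, 0]
        except np.linalg.LinAlgError:
            sol = np.stack(
                [np.linalg.lstsq(A[b], rhs[b], rcond=None)[0] for b in range(B)]
            )
        return sol * mf

    ls_full = None
    if debias and n >= p:
        # start every lambda from the thresholded full LS estimate,
        # matching the single-system solver; QR-based lstsq per slice
        # (normal equations would square the condition number and smear
        # coefficients across nearly collinear column families)
        ls_full = np.stack(
            [np.linalg.lstsq(th[b], ut[b], rcond=None)[0] for b in range(B)]
        )

    M = len(lambdas)
    out = np.zeros((B, M, p), dtype=bool)
    for m, lam in enumerate(lambdas):
        thr = _threshold_value(float(lam), config)
        if ls_full is not None:
            xi = np.where(np.abs(ls_full) > thr * (1.0 + 1e-12), ls_full, 0.0)
        else:
            xi = np.zeros((B, p))
        prev1 = np.zeros((B, p), dtype=bool)
        prev2 = np.zeros((B, p), dtype=bool)
        done = np.zeros(B, dtype=bool)
        for it in range(config.max_iter):
            grad = c - np.matmul(G, xi[:, :, None])[:, :, 0]
            cand = xi + grad
            mask = np.abs(cand) > thr * (1.0 + 1e-12)
            cand *= mask
            if debias:
                sizes = mask.sum(axis=1)
                need = (residual2(cand) > _debias_bound(thr, sizes)) & (sizes > 0)
                if need.any():
                    solved = masked_lstsq(mask)
                    cand = np.where(need[:, None], solved, cand)
            # frozen slices keep their state
            cand[done] = xi[done]
            mask[done] = prev1[done]
            conv = (mask == prev1).all(axis=1)
            cyc = (mask == prev2).all(axis=1) & ~conv & (it >= 2)
            if cyc.any():
                # keep the better endpoint of a 2-cycle
                obj_new = 0.5 * residual2(cand) + _debias_bound(
                    thr, mask.sum(axis=1)
                )
                obj_old = 0.5 * residual2(xi) + _debias_bound(
                    thr, prev1.sum(axis=1)
                )
                keep_old = cyc & (obj_old < obj_new)
                cand[keep_old] = xi[keep_old]
                mask[keep_old] = prev1[keep_old]
            done |= conv | cyc
            prev2, prev1, xi = prev1, mask, cand
            if done.all():
                break
        out[:, m, :] = prev1
    return out
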