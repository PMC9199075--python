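"""Denoising and finite-difference differentiation of gridded data.

Time derivatives use first-order forward differences (the last frame is
invalid); spatial derivatives use second-order central stencils, with
higher orders built by composing the first- and second-derivative stencils.
For non-periodic boundaries, points whose stencil does not fit are marked
invalid rather than switching to one-sided formulas, so that order
reduction never contaminates the regression dictionary.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
from scipy.ndimage import correlate1d

from .fields import SpatioTemporalField

__all__ = [
    "DerivativeField",
    "DenoiseReport",
    "svd_denoise",
    "time_derivative",
    "spatial_derivative",
    "spatial_derivative_multi",
    "valid_sample_mask",
    "sample_points",
]


@dataclass
class DerivativeField:
    """A derivative array aligned with its parent field.

    ``order`` is the per-dimension derivative multi-index, time first, e.g.
    ``(1, 0)`` for u_t of a 1-D field or ``(0, 1, 1)`` for a mixed xy
    derivative in 2-D.  Entries where the stencil does not fit are NaN and
    flagged False in ``valid``.
    """

    values: np.ndarray
    order: Tuple[int, ...]
    scheme: str
    valid: np.ndarray


@dataclass
class DenoiseReport:
    singular_values: np.ndarray
    rank_kept: int
    method: str  # "elbow-auto" or "fixed-rank"


def _elbow_rank(s: np.ndarray, shape: Tuple[int, int]) -> int:
    """Locate the elbow of the singular-value curve.

    The noise floor of an additive-Gaussian-corrupted matrix is estimated
    from the median singular value, and the elbow is placed where the curve
    sinks into that floor: every singular value above the optimal
    hard-threshold multiple of the median is kept.  This is robust to large
    leading drops in the spectrum, where a naive max-curvature rule would
    truncate after the first mode.
    """
    s = s[s > 0]
    if s.size <= 2:
        return max(1, s.size)
    m, n = shape
    beta = min(m, n) / max(m, n)
    # optimal hard-threshold coefficient relative to the median (rank-aware
    # approximation for aspect ratio beta)
    omega = 0.56 * beta**3 - 0.95 * beta**2 + 1.82 * beta + 1.43
    thresh = omega * float(np.median(s))
    rank = int(np.sum(s > thresh))
    return max(1, min(rank, s.size))


def svd_denoise(
    field: SpatioTemporalField, rank: Optional[int] = None
) -> Tuple[SpatioTemporalField, Dict[str, DenoiseReport]]:
    """Truncated-SVD denoising of each variable's (time x space) matrix.

    If ``rank`` is None, the cut-off is placed at the elbow of the singular
    value curve (max-curvature rule); otherwise the given rank is kept.
    Returns the reconstructed field and a per-variable report.
    """
    out = {}
    reports = {}
    for name, arr in field.data.items():
        mat = arr.reshape(arr.shape[0], -1)
        if not np.any(mat):
            raise ValueError(f"variable {name!r} is identically zero")
        U, s, Vt = np.linalg.svd(mat, full_matrices=False)
        if rank is None:
            r = _elbow_rank(s, mat.shape)
            method = "elbow-auto"
        else:
            r = int(rank)
            method = "fixed-rank"
        if not 1 <= r <= s.size:
            raise ValueError(f"rank {r} outside [1, {s.size}]")
        rec = (U[:, :r] * s[:r]) @ Vt[:r]
        out[name] = rec.reshape(arr.shape)
        reports[name] = DenoiseReport(singular_values=s, rank_kept=r, method=method)
    return field.copy_with(out), reports


def time_derivative(field: SpatioTemporalField, variable: str) -> DerivativeField:
    """First-order forward difference in time; last frame invalid."""
    arr = field.data[variable]
    if arr.shape[0] < 2:
        raise ValueError("need at least two time frames")
    vals = np.full_like(arr, np.nan, dtype=float)
    vals[:-1] = (arr[1:] - arr[:-1]) / field.dt
    valid = np.ones(arr.shape, dtype=bool)
    valid[-1] = False
    order = (1,) + (0,) * field.ndim_space
    return DerivativeField(vals, order, "forward-time-order1", valid)


# stencils on the unit grid; scale by dx**-order
_STENCILS = {
    1: np.array([-0.5, 0.0, 0.5]),
    2: np.array([1.0, -2.0, 1.0]),
    3: np.array([-0.5, 1.0, 0.0, -1.0, 0.5]),    # D1 o D2
    4: np.array([1.0, -4.0, 6.0, -4.0, 1.0]),    # D2 o D2
}


def _margin(order: int) -> int:
    return (order + 1) // 2


def spatial_derivative(
    field: SpatioTemporalField, variable: str, axis: int, order: int
) -> DerivativeField:
    """Central-difference spatial derivative along one axis.

    ``axis`` counts spatial dimensions (0 = x).  Orders 1 and 2 are the
    standard second-order stencils; orders 3 and 4 compose them.  Periodic
    fields wrap; otherwise a margin of ceil(order/2) points per side is
    invalidated.
    """
    if order not in _STENCILS:
        raise ValueError(f"derivative order {order} not supported (1..4)")
    if not 0 <= axis < field.ndim_space:
        raise ValueError(f"axis {axis} out of range")
    arr = field.data[variable].astype(float)
    dx = field.dx[axis]
    ax = axis + 1  # account for leading time axis
    periodic = field.boundary == "periodic"
    mode = "wrap" if periodic else "nearest"
    vals = correlate1d(arr, _STENCILS[order], axis=ax, mode=mode)
    vals /= dx**order
    valid = np.ones(arr.shape, dtype=bool)
    if not periodic:
        m = _margin(order)
        sl = [slice(None)] * arr.ndim
        sl[ax] = slice(0, m)
        vals[tuple(sl)] = np.nan
        valid[tuple(sl)] = False
        sl[ax] = slice(arr.shape[ax] - m, None)
        vals[tuple(sl)] = np.nan
        valid[tuple(sl)] = False
    order_idx = [0] * (field.ndim_space + 1)
    order_idx[ax] = order
    return DerivativeField(vals, tuple(order_idx), "central-space-order2", valid)


def spatial_derivative_multi(
    field: SpatioTemporalField, variable: str, orders: Sequence[int]
) -> DerivativeField:
    """Mixed partial derivative given per-axis orders, by composition."""
    orders = tuple(int(o) for o in orders)
    if len(orders) != field.ndim_space:
        raise ValueError("orders must have one entry per spatial axis")
    work = field
    name = variable
    total_valid = np.ones(field.data[variable].shape, dtype=bool)
    vals = field.data[variable].astype(float)
    for axis, o in enumerate(orders):
        if o == 0:
            continue
        tmp = work.copy_with({name: np.nan_to_num(vals)})
        d = spatial_derivative(tmp, name, axis, o)
        # propagate invalidity from earlier axes through the new stencil
        vals = d.values
        total_valid &= d.valid
    order_idx = (0,) + orders
    vals = np.where(total_valid, vals, np.nan)
    return DerivativeField(vals, order_idx, "central-space-order2", total_valid)


def valid_sample_mask(
    field: SpatioTemporalField,
    max_order: int,
    region: Optional[Sequence[Tuple[float, float]]] = None,
    time_window: Optional[Tuple[int, int]] = None,
) -> np.ndarray:
    """Boolean mask of space-time indices safe to sample.

    Excludes the last frame (forward time difference), the spatial stencil
    margin for non-periodic boundaries given the maximum derivative order
    in the dictionary, and everything outside ``region`` (per-dimension
    physical intervals) if given.  ``time_window`` restricts to frame
    indices ``[lo, hi)``.
    """
    mask = np.ones(field.shape, dtype=bool)
    mask[-1] = False
    if time_window is not None:
        lo, hi = time_window
        mask[:lo] = False
        mask[hi:] = False
    if field.boundary != "periodic":
        m = _margin(max_order)
        for ax in range(field.ndim_space):
            sl = [slice(None)] * (field.ndim_space + 1)
            sl[ax + 1] = slice(0, m)
            mask[tuple(sl)] = False
            sl[ax + 1] = slice(field.shape[ax + 1] - m, None)
            mask[tuple(sl)] = False
    if region is not None:
        coords = field.spatial_coords()
        for ax, (lo, hi) in enumerate(region):
            c = coords[ax]
            inside = (c >= lo) & (c <= hi)
            shape = [1] * (field.ndim_space + 1)
            shape[ax + 1] = c.size
            mask &= inside.reshape(shape)
    return mask


def sample_points(
    field: SpatioTemporalField,
    n: int,
    seed: int = 0,
    *,
    max_order: int = 4,
    region: Optional[Sequence[Tuple[float, float]]] = None,
    time_window: Optional[Tuple[int, int]] = None,
    mask: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Draw ``n`` unique space-time indices uniformly from the eligible set.

    Returns an ``(n, 1 + ndim_space)`` integer array of (t, x, ...) indices.
    Only stencil-valid points are eligible; raises if fewer than ``n``
    points are available.
    """
    if mask is None:
        mask = valid_sample_mask(field, max_order, region, time_window)
    flat = np.flatnonzero(mask.ravel())
    if n > flat.size:
        raise ValueError(f"requested {n} samples but only {flat.size} eligible")
    rng = np.random.default_rng(seed)
    chosen = rng.choice(flat, size=n, replace=False)
    return np.stack(np.unravel_index(chosen, mask.shape), axis=1)
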