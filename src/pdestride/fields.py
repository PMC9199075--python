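"""Gridded spatio-temporal fields and the additive-noise model.

A :class:`SpatioTemporalField` carries one or more state variables sampled on
a regular Cartesian grid in space and a uniform grid in time.  It is the
common currency between the benchmark simulators, the preprocessing
(denoising/differentiation) stage and the dictionary builder.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Tuple

import h5py
import numpy as np

__all__ = ["SpatioTemporalField", "NoiseSpec", "add_noise"]

_BOUNDARIES = ("periodic", "dirichlet-noslip", "lid-driven")


@dataclass
class SpatioTemporalField:
    """One or more state variables on a (time, *space) grid.

    Parameters
    ----------
    data
        Mapping from variable name to an array of shape ``(nt, *spatial)``.
        All variables must share one shape.
    dx
        Spatial grid spacing per spatial dimension, in domain units.
    dt
        Time step between stored frames.
    domain_extent
        Per-dimension ``(lo, hi)`` interval of the spatial domain.
    boundary
        One of ``periodic``, ``dirichlet-noslip``, ``lid-driven``.
        Non-periodic boundaries make near-edge stencil points invalid for
        differentiation downstream.
    t0
        Physical time of the first stored frame.
    """

    data: Dict[str, np.ndarray]
    dx: Tuple[float, ...]
    dt: float
    domain_extent: Tuple[Tuple[float, float], ...]
    boundary: str = "periodic"
    t0: float = 0.0

    def __post_init__(self) -> None:
        if not self.data:
            raise ValueError("field needs at least one variable")
        self.dx = tuple(float(d) for d in np.atleast_1d(self.dx))
        self.domain_extent = tuple(
            (float(a), float(b)) for a, b in self.domain_extent
        )
        shapes = {v.shape for v in self.data.values()}
        if len(shapes) != 1:
            raise ValueError(f"variables have inconsistent shapes: {shapes}")
        shape = shapes.pop()
        if len(shape) != 1 + len(self.dx):
            raise ValueError(
                f"array rank {len(shape)} inconsistent with {len(self.dx)} "
                "spatial dimensions plus time"
            )
        if any(d <= 0 for d in self.dx) or self.dt <= 0:
            raise ValueError("dx and dt must be positive")
        if self.boundary not in _BOUNDARIES:
            raise ValueError(f"unknown boundary {self.boundary!r}")
        for name, arr in self.data.items():
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"non-finite values in variable {name!r}")

    # -- convenience ------------------------------------------------------
    @property
    def variable_names(self) -> Tuple[str, ...]:
        return tuple(self.data)

    @property
    def shape(self) -> Tuple[int, ...]:
        return next(iter(self.data.values())).shape

    @property
    def nt(self) -> int:
        return self.shape[0]

    @property
    def spatial_shape(self) -> Tuple[int, ...]:
        return self.shape[1:]

    @property
    def ndim_space(self) -> int:
        return len(self.dx)

    def spatial_coords(self) -> Tuple[np.ndarray, ...]:
        """Per-axis node coordinates implied by extent and spacing."""
        coords = []
        for (lo, _hi), d, n in zip(self.domain_extent, self.dx, self.spatial_shape):
            coords.append(lo + d * np.arange(n))
        return tuple(coords)

    def copy_with(self, data: Dict[str, np.ndarray]) -> "SpatioTemporalField":
        return SpatioTemporalField(
            data=data,
            dx=self.dx,
            dt=self.dt,
            domain_extent=self.domain_extent,
            boundary=self.boundary,
            t0=self.t0,
        )

    # -- serialization ----------------------------------------------------
    def to_hdf5(self, path) -> None:
        """One dataset per variable plus grid metadata attributes."""
        with h5py.File(path, "w") as f:
            for name, arr in self.data.items():
                f.create_dataset(name, data=arr)
            f.attrs["variables"] = list(self.data)
            f.attrs["dx"] = self.dx
            f.attrs["dt"] = self.dt
            f.attrs["extent"] = np.asarray(self.domain_extent)
            f.attrs["boundary"] = self.boundary
            f.attrs["t0"] = self.t0

    @classmethod
    def from_hdf5(cls, path) -> "SpatioTemporalField":
        with h5py.File(path, "r") as f:
            names = [str(v) for v in f.attrs["variables"]]
            data = {name: f[name][...] for name in names}
            extent = tuple(tuple(row) for row in np.asarray(f.attrs["extent"]))
            return cls(
                data=data,
                dx=tuple(np.atleast_1d(f.attrs["dx"])),
                dt=float(f.attrs["dt"]),
                domain_extent=extent,
                boundary=str(f.attrs["boundary"]),
                t0=float(f.attrs.get("t0", 0.0)),
            )

    def export_csv_slice(self, path, variable: str, t_index: int) -> None:
        """CSV export of a 1-D slice (1-D fields only)."""
        if self.ndim_space != 1:
            raise ValueError("CSV slice export only supported for 1-D fields")
        x = self.spatial_coords()[0]
        u = self.data[variable][t_index]
        np.savetxt(
            path,
            np.column_stack([x, u]),
            delimiter=",",
            header=f"x,{variable}",
            comments="",
        )


@dataclass
class NoiseSpec:
    """Additive Gaussian noise scaled by the empirical variance of the data.

    ``sigma`` is the noise level as a fraction (1% noise = 0.01).  The noise
    added to variable ``u`` is ``sigma * z`` with ``z ~ N(0, Var(u))`` i.i.d.,
    where ``Var(u)`` is the empirical variance of the full clean data vector
    of that variable.
    """

    sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")


def add_noise(field: SpatioTemporalField, spec: NoiseSpec) -> SpatioTemporalField:
    """Corrupt every variable of ``field`` with seeded additive Gaussian noise.

    Each variable uses its own empirical variance; ``sigma=0`` returns a
    copy with identical values.
    """
    if spec.sigma == 0.0:
        return field.copy_with({k: v.copy() for k, v in field.data.items()})
    rng = np.random.default_rng(spec.seed)
    noisy = {}
    for name, arr in field.data.items():
        std = float(np.std(arr))
        noisy[name] = arr + spec.sigma * rng.normal(0.0, std, size=arr.shape)
    return field.copy_with(noisy)
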