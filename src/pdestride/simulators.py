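"""Benchmark simulators producing ground-truth spatio-temporal data.

Four dynamical systems are provided:

* 1-D viscous Burgers equation  u_t + u u_x = D u_xx  (periodic),
* 2-D vorticity transport in a lid-driven cavity (streamfunction-vorticity),
* 3-D Gray-Scott reaction-diffusion (periodic cube),
* the PAR protein reaction network as a per-grid-point ODE system.

All solvers use explicit Euler time stepping with second-order central
differences in space, so a forward time difference of two consecutive stored
frames reproduces the discrete right-hand side exactly.  That property is
what makes clean-data recovery of the governing equation essentially exact
when the downstream dictionary uses the same stencils.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .fields import SpatioTemporalField

__all__ = [
    "BurgersConfig",
    "CavityConfig",
    "GrayScottConfig",
    "ParOdeConfig",
    "simulate_burgers",
    "simulate_cavity_vorticity",
    "simulate_gray_scott",
    "simulate_par_ode",
    "default_par_profiles",
]


# ----------------------------------------------------------------------
# 1-D Burgers
# ----------------------------------------------------------------------

@dataclass
class BurgersConfig:
    """Viscous Burgers run: Gaussian bump on a periodic interval."""

    D: float = 0.1
    nx: int = 256
    nt: int = 1000
    dt: float = 0.01
    extent: Tuple[float, float] = (-8.0, 8.0)

    @property
    def dx(self) -> float:
        return (self.extent[1] - self.extent[0]) / self.nx

    def validate(self) -> None:
        if self.nx < 8 or self.nt < 2:
            raise ValueError("grid too small")
        cfl = self.D * self.dt / self.dx**2
        if cfl > 0.5:
            raise ValueError(
                f"explicit diffusion unstable: D*dt/dx^2 = {cfl:.3f} > 0.5"
            )


def simulate_burgers(cfg: BurgersConfig = BurgersConfig()) -> SpatioTemporalField:
    """Solve u_t + u u_x = D u_xx with explicit Euler and central stencils.

    Initial condition ``u(x,0) = exp(-(x+2)^2)``; all ``nt`` frames (the
    initial condition plus ``nt - 1`` steps) are returned.
    """
    cfg.validate()
    dx = cfg.dx
    # periodic grid: right endpoint excluded
    x = cfg.extent[0] + dx * np.arange(cfg.nx)
    u = np.exp(-((x + 2.0) ** 2))
    out = np.empty((cfg.nt, cfg.nx))
    out[0] = u
    for n in range(1, cfg.nt):
        # advection in conservative (flux) form, d/dx (u^2/2) with a central
        # stencil: conserves discrete mass exactly under periodic BCs
        flux = 0.5 * u * u
        dflux = (np.roll(flux, -1) - np.roll(flux, 1)) / (2 * dx)
        uxx = (np.roll(u, -1) - 2 * u + np.roll(u, 1)) / dx**2
        u = u + cfg.dt * (-dflux + cfg.D * uxx)
        out[n] = u
    if not np.all(np.isfinite(out)):
        raise FloatingPointError("Burgers solution diverged")
    return SpatioTemporalField(
        data={"u": out},
        dx=(dx,),
        dt=cfg.dt,
        domain_extent=(cfg.extent,),
        boundary="periodic",
    )


# ----------------------------------------------------------------------
# 2-D lid-driven cavity, streamfunction-vorticity form
# ----------------------------------------------------------------------

@dataclass
class CavityConfig:
    """Lid-driven cavity on the unit square.

    No-slip walls at left/right/bottom, a lid moving with ``lid_velocity``
    along +x at the top.  Frames at every step between the first and last
    entry of ``snapshot_times`` are stored, so consecutive stored frames are
    one simulation step apart.
    """

    mu: float = 0.025
    n: int = 128
    lid_velocity: float = 2.0
    dt: float = 5.0e-4
    t_final: float = 1.004
    snapshot_times: Tuple[float, float] = (1.0, 1.004)

    def validate(self) -> None:
        if self.mu <= 0:
            raise ValueError("viscosity must be positive")
        if not all(0.0 <= t <= self.t_final for t in self.snapshot_times):
            raise ValueError("snapshot_times must lie within [0, t_final]")
        h = 1.0 / (self.n - 1)
        if self.mu * self.dt / h**2 > 0.25:
            raise ValueError("explicit diffusion step too large for this grid")


def _interior_poisson(n: int, h: float) -> spla.SuperLU:
    """Prefactorized 5-point Laplacian on the (n-2)^2 interior nodes."""
    m = n - 2
    lap1 = sp.diags([1.0, -2.0, 1.0], [-1, 0, 1], shape=(m, m), format="csr")
    eye = sp.identity(m, format="csr")
    lap = (sp.kron(lap1, eye) + sp.kron(eye, lap1)) / h**2
    return spla.splu(lap.tocsc())


def simulate_cavity_vorticity(
    cfg: CavityConfig = CavityConfig(),
) -> SpatioTemporalField:
    """Transient lid-driven cavity flow; returns vorticity and velocities.

    The vorticity transport equation is advanced with explicit Euler; each
    step the streamfunction Poisson problem grad^2 psi = -omega is solved by
    a prefactorized sparse direct solve, which keeps the velocity field
    discretely divergence-free (u = psi_y, v = -psi_x with central stencils).
    Wall vorticity uses Thom's first-order formula.
    """
    cfg.validate()
    n = cfg.n
    h = 1.0 / (n - 1)
    lu = _interior_poisson(n, h)

    # arrays indexed [ix, iy]; y increases with the second index, lid at iy=n-1
    omega = np.zeros((n, n))
    psi = np.zeros((n, n))
    u = np.zeros((n, n))
    v = np.zeros((n, n))
    u[:, -1] = cfg.lid_velocity

    t_lo, t_hi = min(cfg.snapshot_times), max(cfg.snapshot_times)
    n_steps = int(round(cfg.t_final / cfg.dt))
    k_lo = int(np.floor(t_lo / cfg.dt))
    k_hi = min(int(np.ceil(t_hi / cfg.dt)), n_steps)
    n_save = k_hi - k_lo + 1
    W = np.empty((n_save, n, n))
    U = np.empty((n_save, n, n))
    V = np.empty((n_save, n, n))

    inner = slice(1, -1)

    def apply_wall_vorticity(om, ps):
        om[0, :] = 2.0 * (ps[0, :] - ps[1, :]) / h**2          # left
        om[-1, :] = 2.0 * (ps[-1, :] - ps[-2, :]) / h**2       # right
        om[:, 0] = 2.0 * (ps[:, 0] - ps[:, 1]) / h**2          # bottom
        om[:, -1] = (
            2.0 * (ps[:, -1] - ps[:, -2]) / h**2
            - 2.0 * cfg.lid_velocity / h
        )                                                      # moving lid

    # initial impulsive start: omega from the lid discontinuity
    apply_wall_vorticity(omega, psi)

    for k in range(n_steps + 1):
        if k_lo <= k <= k_hi:
            i = k - k_lo
            W[i] = omega.copy()
            U[i] = u.copy()
            V[i] = v.copy()
        if k == n_steps:
            break

        # advance interior vorticity
        om = omega
        om_x = (om[2:, 1:-1] - om[:-2, 1:-1]) / (2 * h)
        om_y = (om[1:-1, 2:] - om[1:-1, :-2]) / (2 * h)
        lap = (
            om[2:, 1:-1] + om[:-2, 1:-1] + om[1:-1, 2:] + om[1:-1, :-2]
            - 4.0 * om[1:-1, 1:-1]
        ) / h**2
        new = om.copy()
        new[inner, inner] = om[1:-1, 1:-1] + cfg.dt * (
            -u[1:-1, 1:-1] * om_x - v[1:-1, 1:-1] * om_y + cfg.mu * lap
        )
        omega = new

        # streamfunction solve with psi = 0 on the boundary
        rhs = -omega[1:-1, 1:-1].ravel()
        sol = lu.solve(rhs)
        if not np.all(np.isfinite(sol)):
            raise FloatingPointError("Poisson solve produced non-finite values")
        psi = np.zeros((n, n))
        psi[inner, inner] = sol.reshape(n - 2, n - 2)

        # velocities from the streamfunction
        u = np.zeros((n, n))
        v = np.zeros((n, n))
        u[1:-1, 1:-1] = (psi[1:-1, 2:] - psi[1:-1, :-2]) / (2 * h)
        v[1:-1, 1:-1] = -(psi[2:, 1:-1] - psi[:-2, 1:-1]) / (2 * h)
        u[:, -1] = cfg.lid_velocity

        apply_wall_vorticity(omega, psi)

    if not np.all(np.isfinite(W)):
        raise FloatingPointError("cavity solution diverged")
    field = SpatioTemporalField(
        data={"w": W, "u": U, "v": V},
        dx=(h, h),
        dt=cfg.dt,
        domain_extent=((0.0, 1.0), (0.0, 1.0)),
        boundary="lid-driven",
        t0=k_lo * cfg.dt,
    )
    return field


# ----------------------------------------------------------------------
# 3-D Gray-Scott
# ----------------------------------------------------------------------

@dataclass
class GrayScottConfig:
    """Gray-Scott reaction-diffusion in a periodic cube [0, L]^3.

    Initial condition: the uniform trivial state (u=1, v=0) with a centered
    cube perturbation (u=0.5, v=0.25) modulated by a small seeded uniform
    jitter to break symmetry.  The last ``n_save`` consecutive frames are
    stored.
    """

    Du: float = 2.0e-5
    Dv: float = 1.0e-5
    f: float = 0.014
    k: float = 0.053
    n: int = 128
    dt: float = 5.0e-4
    t_final: float = 5.0
    L: float = 2.5
    n_save: int = 16
    # scale of the centered-cube perturbation (0 leaves the uniform state)
    perturbation_amplitude: float = 1.0
    # relative uniform jitter applied inside the perturbed cube
    jitter: float = 0.01
    seed: int = 0

    @property
    def dx(self) -> float:
        return self.L / self.n

    def validate(self) -> None:
        if min(self.Du, self.Dv, self.f, self.k) < 0:
            raise ValueError("rates and diffusivities must be non-negative")
        if max(self.Du, self.Dv) * self.dt / self.dx**2 > 1.0 / 6.0:
            raise ValueError("diffusion CFL violated for 3-D explicit Euler")


def _laplacian_periodic(a: np.ndarray, dx: float) -> np.ndarray:
    lap = -6.0 * a
    for ax in range(3):
        lap += np.roll(a, 1, axis=ax) + np.roll(a, -1, axis=ax)
    return lap / dx**2


def simulate_gray_scott(
    cfg: GrayScottConfig = GrayScottConfig(),
) -> SpatioTemporalField:
    """Explicit-Euler Gray-Scott with central 7-point Laplacians."""
    cfg.validate()
    n, dx = cfg.n, cfg.dx
    u = np.ones((n, n, n))
    v = np.zeros((n, n, n))

    # centered cube covering [0.4L, 0.6L]^3
    lo, hi = int(0.4 * n), int(0.6 * n)
    box = (slice(lo, hi),) * 3
    rng = np.random.default_rng(cfg.seed)
    amp = cfg.perturbation_amplitude
    jitter_u = 1.0 + cfg.jitter * rng.uniform(-1.0, 1.0, size=(hi - lo,) * 3)
    jitter_v = 1.0 + cfg.jitter * rng.uniform(-1.0, 1.0, size=(hi - lo,) * 3)
    u[box] = 1.0 - amp * 0.5 * jitter_u
    v[box] = amp * 0.25 * jitter_v

    n_steps = int(round(cfg.t_final / cfg.dt))
    n_save = min(cfg.n_save, n_steps + 1)
    first_saved = n_steps - n_save + 1
    Uo = np.empty((n_save, n, n, n), dtype=np.float64)
    Vo = np.empty((n_save, n, n, n), dtype=np.float64)

    for k in range(n_steps + 1):
        if k >= first_saved:
            Uo[k - first_saved] = u
            Vo[k - first_saved] = v
        if k == n_steps:
            break
        uvv = u * v * v
        du = cfg.Du * _laplacian_periodic(u, dx) - uvv + cfg.f * (1.0 - u)
        dv = cfg.Dv * _laplacian_periodic(v, dx) + uvv - (cfg.f + cfg.k) * v
        u = u + cfg.dt * du
        v = v + cfg.dt * dv
        if not (np.isfinite(u[0, 0, 0]) and np.isfinite(v[0, 0, 0])):
            raise FloatingPointError("Gray-Scott integration became unstable")

    if not (np.all(np.isfinite(Uo)) and np.all(np.isfinite(Vo))):
        raise FloatingPointError("Gray-Scott integration became unstable")
    return SpatioTemporalField(
        data={"u": Uo, "v": Vo},
        dx=(dx, dx, dx),
        dt=cfg.dt,
        domain_extent=((0.0, cfg.L),) * 3,
        boundary="periodic",
        t0=first_saved * cfg.dt,
    )


# ----------------------------------------------------------------------
# PAR protein reaction ODEs
# ----------------------------------------------------------------------

@dataclass
class ParOdeConfig:
    """Pointwise PAR reaction kinetics on a 1-D profile.

    dP/dt = cP + kP*P + kPA*A*P^2
    dA/dt = cA + kA*A + kAP*P*A^2

    Concentrations in um^-2, time in seconds.  Default rate constants are
    the membrane association/dissociation and mutual-antagonism rates of
    the aPAR/pPAR polarity network.  There is no spatial coupling; the
    spatial axis only carries the initial profiles.
    """

    cP: float = -1.98e-4
    cA: float = 4.13e-3
    kP: float = 1.07e-2
    kA: float = 2.16e-3
    kPA: float = -2.79e-4
    kAP: float = -1.47e-4
    A0: Optional[np.ndarray] = None
    P0: Optional[np.ndarray] = None
    nt: int = 40
    dt: float = 8.0
    L: float = 60.0

    def validate(self) -> None:
        if self.nt < 2 or self.dt <= 0:
            raise ValueError("need nt >= 2 and dt > 0")


def default_par_profiles(nx: int = 256, L: float = 60.0):
    """Nascent anterior/posterior PAR domains: opposing sigmoid plateaus
    with superimposed smooth modulation.

    Amplitudes of order 10 um^-2 put the antagonistic terms kPA*A*P^2 and
    kAP*P*A^2 on the same footing as the linear kinetics, mimicking the
    partially polarized zygote after the advection trigger.  The extra
    long-wavelength modulation decorrelates the mass-action monomials
    (P, P^2, A*P^2, ...) across space, as the uneven cortical fluorescence
    of a real embryo would.
    """
    x = np.linspace(0.0, L, nx)
    w = 0.06 * L
    mid = 0.5 * L
    A0 = 1.0 + 10.0 / (1.0 + np.exp((x - (mid - 0.05 * L)) / w))
    P0 = 1.0 + 9.0 / (1.0 + np.exp(-(x - (mid + 0.08 * L)) / w))
    A0 = A0 * (1.0 + 0.25 * np.sin(2.0 * np.pi * x / L)
               + 0.10 * np.cos(6.0 * np.pi * x / L))
    P0 = P0 * (1.0 + 0.30 * np.cos(2.0 * np.pi * x / L + 1.0)
               + 0.12 * np.sin(4.0 * np.pi * x / L))
    return A0, P0


def simulate_par_ode(cfg: ParOdeConfig = ParOdeConfig()) -> SpatioTemporalField:
    """Explicit-Euler integration of the PAR kinetics at every grid point."""
    cfg.validate()
    if cfg.A0 is None or cfg.P0 is None:
        A0, P0 = default_par_profiles(L=cfg.L)
    else:
        A0, P0 = np.asarray(cfg.A0, float), np.asarray(cfg.P0, float)
    if A0.shape != P0.shape or A0.ndim != 1:
        raise ValueError("A0 and P0 must be 1-D arrays of equal length")
    nx = A0.size
    A = np.empty((cfg.nt, nx))
    P = np.empty((cfg.nt, nx))
    A[0], P[0] = A0, P0
    a, p = A0.copy(), P0.copy()
    for nstep in range(1, cfg.nt):
        dp = cfg.cP + cfg.kP * p + cfg.kPA * a * p**2
        da = cfg.cA + cfg.kA * a + cfg.kAP * p * a**2
        a = a + cfg.dt * da
        p = p + cfg.dt * dp
        if not (np.all(np.isfinite(a)) and np.all(np.isfinite(p))):
            raise FloatingPointError("PAR ODE integration blew up")
        if max(np.abs(a).max(), np.abs(p).max()) > 1e6:
            raise FloatingPointError("PAR ODE concentrations diverging")
        A[nstep], P[nstep] = a, p
    return SpatioTemporalField(
        data={"A": A, "P": P},
        dx=(cfg.L / (nx - 1),),
        dt=cfg.dt,
        domain_extent=((0.0, cfg.L),),
        boundary="dirichlet-noslip",
    )
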