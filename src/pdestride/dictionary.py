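"""Assembly of the sparse-regression design: response Ut and dictionary Theta.

Each dictionary column is a *term*: a product of a polynomial monomial in
the state variables and (optionally) one spatial derivative of one
variable.  Labels follow a canonical grammar, e.g. ``u*u_{xx}``, ``w_{xy}``,
``A^2*P``, ``1``.

Presets reproduce the standard benchmark designs:

* 1-D single species, degree 3, derivative order 4 -> p = 19
* 2-D vorticity + advecting velocities             -> p = 48
* 3-D two species (reaction-diffusion)             -> p = 69
* two-species reaction network (stoichiometry <=2) -> p = 20

The exact 48/69 term lists are a reconstruction: they are parameterized,
contain the true model terms, and match the published column counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import h5py
import numpy as np

from .fields import SpatioTemporalField
from .preprocess import (
    spatial_derivative_multi,
    time_derivative,
)

__all__ = [
    "Term",
    "DictionarySpec",
    "ReactionDictionarySpec",
    "DesignSystem",
    "terms_from_spec",
    "burgers_terms",
    "vorticity_terms",
    "gray_scott_terms",
    "par_reaction_terms",
    "build_design",
    "build_reaction_design",
    "standardize",
]

_AXIS_NAMES = "xyz"


@dataclass(frozen=True)
class Term:
    """monomial * (one spatial derivative), e.g. u^2 * u_{xx}.

    ``monomial`` maps variable name -> power; ``derivative`` is
    ``(variable, per-axis orders)`` or None.  An empty monomial with no
    derivative is the constant term.
    """

    monomial: Tuple[Tuple[str, int], ...] = ()
    derivative: Optional[Tuple[str, Tuple[int, ...]]] = None

    @property
    def label(self) -> str:
        parts = []
        for var, power in self.monomial:
            parts.append(var if power == 1 else f"{var}^{power}")
        if self.derivative is not None:
            var, orders = self.derivative
            sub = "".join(
                _AXIS_NAMES[ax] * o for ax, o in enumerate(orders)
            )
            parts.append(f"{var}_{{{sub}}}")
        return "*".join(parts) if parts else "1"

    @property
    def is_constant(self) -> bool:
        return not self.monomial and self.derivative is None

    @property
    def max_derivative_order(self) -> int:
        if self.derivative is None:
            return 0
        return max(self.derivative[1])


def _mono(**powers: int) -> Tuple[Tuple[str, int], ...]:
    return tuple((v, p) for v, p in powers.items() if p > 0)


# ----------------------------------------------------------------------
# Specs and generic enumeration
# ----------------------------------------------------------------------

@dataclass
class DictionarySpec:
    """Generic product dictionary: monomials and monomial-times-derivative.

    With one variable, ``max_poly_degree=3`` and ``max_derivative_order=4``
    this yields the 19-column 1-D design {u, u^2, u^3} plus
    {d^k u * u^j : k=1..4, j=0..3}.
    """

    variables: Sequence[str] = ("u",)
    max_poly_degree: int = 3
    max_derivative_order: int = 4
    include_constant: bool = False
    ndim_space: int = 1


def terms_from_spec(spec: DictionarySpec) -> List[Term]:
    if spec.ndim_space != 1 or len(spec.variables) != 1:
        raise ValueError(
            "the generic builder covers the 1-D single-variable family; "
            "use the vorticity/gray-scott/reaction presets otherwise"
        )
    (var,) = spec.variables
    terms: List[Term] = []
    if spec.include_constant:
        terms.append(Term())
    for j in range(1, spec.max_poly_degree + 1):
        terms.append(Term(monomial=_mono(**{var: j})))
    for k in range(1, spec.max_derivative_order + 1):
        for j in range(0, spec.max_poly_degree + 1):
            terms.append(
                Term(monomial=_mono(**{var: j}), derivative=(var, (k,)))
            )
    _check_unique(terms)
    return terms


def burgers_terms() -> List[Term]:
    """The default 1-D design, p = 19."""
    return terms_from_spec(DictionarySpec())


def vorticity_terms() -> List[Term]:
    """2-D vorticity-transport preset, p = 48.

    Pure columns: powers of the vorticity w up to degree 3 and velocity
    monomials (u, v) up to degree 2.  Derivative columns: the five first
    and second derivatives of w times multipliers {1, w, w^2, u, v, u^2,
    uv, v^2}.  Contains the truth {w_xx, w_yy, u*w_x, v*w_y}.
    """
    terms: List[Term] = []
    for j in (1, 2, 3):
        terms.append(Term(monomial=_mono(w=j)))
    for mono in (_mono(u=1), _mono(v=1), _mono(u=2), _mono(u=1, v=1), _mono(v=2)):
        terms.append(Term(monomial=mono))
    derivs = [(1, 0), (0, 1), (2, 0), (1, 1), (0, 2)]
    mults = [
        (), _mono(w=1), _mono(w=2),
        _mono(u=1), _mono(v=1), _mono(u=2), _mono(u=1, v=1), _mono(v=2),
    ]
    for d in derivs:
        for m in mults:
            terms.append(Term(monomial=m, derivative=("w", d)))
    _check_unique(terms)
    assert len(terms) == 48
    return terms


def gray_scott_terms() -> List[Term]:
    """3-D two-species preset, p = 69.

    Constant + all (u, v) monomials of total degree 1..4 (14 columns) +
    all first and second (incl. mixed) derivatives of both species
    (18 operators) times multipliers {1, u, v} (54 columns).
    """
    terms: List[Term] = [Term()]
    for deg in range(1, 5):
        for i in range(deg, -1, -1):
            j = deg - i
            terms.append(Term(monomial=_mono(u=i, v=j)))
    derivs = [
        (1, 0, 0), (0, 1, 0), (0, 0, 1),
        (2, 0, 0), (0, 2, 0), (0, 0, 2),
        (1, 1, 0), (1, 0, 1), (0, 1, 1),
    ]
    for var in ("u", "v"):
        for d in derivs:
            for m in ((), _mono(u=1), _mono(v=1)):
                terms.append(Term(monomial=m, derivative=(var, d)))
    _check_unique(terms)
    assert len(terms) == 69
    return terms


@dataclass
class ReactionDictionarySpec:
    """Mass-action monomials for a two-species reaction network.

    Monomials ``A^i P^j`` with per-species stoichiometry ``i, j <=
    max_stoichiometry`` and total reaction order ``i + j <= 3`` (reactions
    beyond termolecular are excluded), plus a transport block of first and
    second spatial derivatives of each species times {1, A, P}.
    """

    species: Tuple[str, str] = ("A", "P")
    max_stoichiometry: int = 2
    include_constant: bool = True
    include_transport: bool = True
    max_total_order: int = 3


def par_reaction_terms(
    spec: ReactionDictionarySpec = ReactionDictionarySpec(),
) -> List[Term]:
    """Default reaction dictionary, p = 20 for the PAR system."""
    a, b = spec.species
    terms: List[Term] = []
    smax = spec.max_stoichiometry
    for i in range(smax + 1):
        for j in range(smax + 1):
            if i + j > spec.max_total_order:
                continue
            if i == 0 and j == 0:
                if spec.include_constant:
                    terms.append(Term())
                continue
            terms.append(Term(monomial=_mono(**{a: i, b: j})))
    if spec.include_transport:
        for var in spec.species:
            for order in (1, 2):
                for m in ((), _mono(**{a: 1}), _mono(**{b: 1})):
                    terms.append(Term(monomial=m, derivative=(var, (order,))))
    _check_unique(terms)
    return terms


def _check_unique(terms: Sequence[Term]) -> None:
    labels = [t.label for t in terms]
    if len(set(labels)) != len(labels):
        dupes = sorted({l for l in labels if labels.count(l) > 1})
        raise ValueError(f"duplicate dictionary labels: {dupes}")


# ----------------------------------------------------------------------
# Design system
# ----------------------------------------------------------------------

@dataclass
class DesignSystem:
    """The linear system Ut ~ Theta @ xi at N sampled space-time points."""

    theta: np.ndarray                 # (N, p)
    ut: np.ndarray                    # (N,)
    labels: Tuple[str, ...]
    sample_indices: Optional[np.ndarray] = None   # (N, 1 + ndim_space)
    standardized: bool = False
    column_means: Optional[np.ndarray] = None
    column_scales: Optional[np.ndarray] = None
    ut_mean: Optional[float] = None
    constant_index: Optional[int] = None          # column of the raw constant

    def __post_init__(self) -> None:
        self.theta = np.asarray(self.theta, float)
        self.ut = np.asarray(self.ut, float)
        if self.theta.ndim != 2 or self.ut.shape != (self.theta.shape[0],):
            raise ValueError("theta must be (N, p) with matching ut")
        if len(self.labels) != self.theta.shape[1]:
            raise ValueError("labels must align with columns")
        if not (np.all(np.isfinite(self.theta)) and np.all(np.isfinite(self.ut))):
            raise ValueError("non-finite entries in the design system")
        self.labels = tuple(self.labels)

    @property
    def n_samples(self) -> int:
        return self.theta.shape[0]

    @property
    def n_terms(self) -> int:
        return self.theta.shape[1]

    def column(self, label: str) -> np.ndarray:
        return self.theta[:, self.labels.index(label)]

    def to_hdf5(self, path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("theta", data=self.theta)
            f.create_dataset("ut", data=self.ut)
            f.attrs["labels"] = list(self.labels)
            f.attrs["standardized"] = self.standardized
            if self.sample_indices is not None:
                f.create_dataset("sample_indices", data=self.sample_indices)

    @classmethod
    def from_hdf5(cls, path) -> "DesignSystem":
        with h5py.File(path, "r") as f:
            idx = f["sample_indices"][...] if "sample_indices" in f else None
            return cls(
                theta=f["theta"][...],
                ut=f["ut"][...],
                labels=tuple(str(s) for s in f.attrs["labels"]),
                sample_indices=idx,
                standardized=bool(f.attrs["standardized"]),
            )


def _evaluate_terms(
    field: SpatioTemporalField,
    terms: Sequence[Term],
    samples: np.ndarray,
) -> np.ndarray:
    """Evaluate every term at the sampled indices; returns (N, p)."""
    samples = np.asarray(samples)
    idx = tuple(samples.T)
    deriv_cache: Dict[Tuple[str, Tuple[int, ...]], np.ndarray] = {}

    def deriv_at(var: str, orders: Tuple[int, ...]) -> np.ndarray:
        key = (var, orders)
        if key not in deriv_cache:
            d = spatial_derivative_multi(field, var, orders)
            deriv_cache[key] = d.values
        return deriv_cache[key][idx]

    n = samples.shape[0]
    cols = np.empty((n, len(terms)))
    for j, term in enumerate(terms):
        col = np.ones(n)
        for var, power in term.monomial:
            col = col * field.data[var][idx] ** power
        if term.derivative is not None:
            col = col * deriv_at(*term.derivative)
        cols[:, j] = col
    if not np.all(np.isfinite(cols)):
        raise ValueError(
            "non-finite dictionary entries: sampled points touch an "
            "invalid stencil margin"
        )
    return cols


def build_design(
    field: SpatioTemporalField,
    terms: Sequence[Term],
    samples: np.ndarray,
    target: str,
) -> DesignSystem:
    """Assemble Theta and the forward-difference response for ``target``.

    ``samples`` are (t, space...) index rows; every sampled point must have
    a complete stencil for all derivative terms and a successor frame.
    """
    if len(samples) == 0:
        raise ValueError("empty sample set")
    _check_unique(terms)
    theta = _evaluate_terms(field, terms, samples)
    ut_field = time_derivative(field, target)
    ut = ut_field.values[tuple(np.asarray(samples).T)]
    if not np.all(np.isfinite(ut)):
        raise ValueError("sampled points include the last (invalid) frame")
    labels = tuple(t.label for t in terms)
    const_idx = next(
        (i for i, t in enumerate(terms) if t.is_constant), None
    )
    return DesignSystem(
        theta=theta,
        ut=ut,
        labels=labels,
        sample_indices=np.asarray(samples),
        constant_index=const_idx,
    )


def build_reaction_design(
    field: SpatioTemporalField,
    spec: ReactionDictionarySpec,
    samples: np.ndarray,
    target_species: str,
) -> DesignSystem:
    """Reaction-network design: mass-action monomials + transport terms."""
    return build_design(field, par_reaction_terms(spec), samples, target_species)


# ----------------------------------------------------------------------
# Standardization
# ----------------------------------------------------------------------

def standardize(system: DesignSystem) -> DesignSystem:
    """Center columns and the response, scale columns to unit mean square.

    The constant column (if any) carries no information once the response
    is centered; it is dropped here and restored at refit time.  Applying
    ``standardize`` twice is a no-op.
    """
    theta = system.theta
    labels = list(system.labels)
    const_idx = system.constant_index
    if not system.standardized and const_idx is not None:
        keep = [j for j in range(theta.shape[1]) if j != const_idx]
        theta = theta[:, keep]
        labels = [labels[j] for j in keep]
    means = theta.mean(axis=0)
    centered = theta - means
    scales = np.sqrt(np.mean(centered**2, axis=0))
    bad = np.flatnonzero(scales <= 1e-300)
    if bad.size:
        names = [labels[j] for j in bad]
        raise ValueError(f"zero-variance column(s): {names}")
    ut_mean = float(system.ut.mean())
    return DesignSystem(
        theta=centered / scales,
        ut=system.ut - ut_mean,
        labels=tuple(labels),
        sample_indices=system.sample_indices,
        standardized=True,
        column_means=means,
        column_scales=scales,
        ut_mean=ut_mean,
        constant_index=None,
    )
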