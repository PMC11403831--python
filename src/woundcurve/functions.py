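"""Healing-rate functions f(t; rho).

A healing-rate function maps days post-randomisation to the *proportionate*
wound area — current mean area divided by true baseline area.  Eleven
families are supported, covering exponential/Gompertz decay, polynomial and
square-root trends (on the natural and log scale), two compactly supported
Wendland functions that reach exactly zero area at a finite horizon, and a
penalised B-spline semiparametric form.

All families except the three ``log_*`` ones satisfy f(0) = 1; the log
families start at f(0) = e because their printed form carries a constant
``1`` inside the exponential (absorbed by the model intercept, but retained
for fidelity — see the methods note).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.interpolate import BSpline


class Family(str, enum.Enum):
    """Canonical names of the supported healing-rate function families."""

    EXPONENTIAL = "exponential"
    GOMPERTZ = "gompertz"
    LINEAR = "linear"
    QUADRATIC = "quadratic"
    SQUARE_ROOT = "square_root"
    WENDLAND0 = "wendland0"
    WENDLAND1 = "wendland1"
    SEMIPARAMETRIC = "semiparametric"
    LOG_LINEAR = "log_linear"
    LOG_QUADRATIC = "log_quadratic"
    LOG_SQUARE_ROOT = "log_square_root"


#: Number of rho components per family; None means "set by the spline basis".
FAMILY_ARITY: dict[Family, int | None] = {
    Family.EXPONENTIAL: 1,
    Family.GOMPERTZ: 1,
    Family.LINEAR: 1,
    Family.QUADRATIC: 2,
    Family.SQUARE_ROOT: 2,
    Family.WENDLAND0: 1,
    Family.WENDLAND1: 1,
    Family.SEMIPARAMETRIC: None,
    Family.LOG_LINEAR: 1,
    Family.LOG_QUADRATIC: 2,
    Family.LOG_SQUARE_ROOT: 2,
}

#: Families whose derivative involves 1/sqrt(t) and is singular at t = 0.
SQRT_FAMILIES = frozenset({Family.SQUARE_ROOT, Family.LOG_SQUARE_ROOT})

#: Compactly supported families (rescaled by t_max, exactly 0 for t >= t_max).
WENDLAND_FAMILIES = frozenset({Family.WENDLAND0, Family.WENDLAND1})


def registry() -> dict[str, int | None]:
    """Map each family name to its rho arity (None = spline-determined)."""
    return {fam.value: FAMILY_ARITY[fam] for fam in Family}


@dataclass(frozen=True)
class SplineBasis:
    """Clamped B-spline basis for the semiparametric family.

    The raw basis columns are shifted by their value at t = 0 so that every
    column vanishes at the origin; with ``f(t) = 1 - sum_m rho_m h_m(t)``
    this anchors f(0) = 1 structurally and keeps the rho_m identifiable
    against the model intercept.
    """

    degree: int
    knots: np.ndarray  # the evenly spaced knot values, including endpoints
    time_range: tuple[float, float]
    basis_count: int = field(init=False)

    def __post_init__(self) -> None:
        knots = np.asarray(self.knots, dtype=float)
        lo, hi = self.time_range
        if not (np.all(np.diff(knots) > 0)):
            raise ValueError("knots must be strictly increasing")
        if knots[0] < lo or knots[-1] > hi:
            raise ValueError("knots must lie within time_range")
        object.__setattr__(self, "knots", knots)
        kv = self._knot_vector()
        object.__setattr__(self, "basis_count", len(kv) - self.degree - 1)

    def _knot_vector(self) -> np.ndarray:
        lo, hi = self.time_range
        return np.r_[[lo] * self.degree, self.knots, [hi] * self.degree]

    def design_matrix(self, t: np.ndarray) -> np.ndarray:
        """Shifted basis matrix H with H[j, m] = h_m(t_j), h_m(0) = 0."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        lo, hi = self.time_range
        tc = np.clip(t, lo, hi)  # constant extrapolation beyond the range
        kv = self._knot_vector()
        raw = BSpline.design_matrix(tc, kv, self.degree).toarray()
        at0 = BSpline.design_matrix(np.array([lo]), kv, self.degree).toarray()
        return raw - at0

    def derivative_matrix(self, t: np.ndarray) -> np.ndarray:
        """H'[j, m] = dh_m/dt at t_j (zero outside the time range)."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        lo, hi = self.time_range
        kv = self._knot_vector()
        eye = np.eye(self.basis_count)
        cols = []
        for m in range(self.basis_count):
            d = BSpline(kv, eye[m], self.degree).derivative()
            vals = d(np.clip(t, lo, hi))
            vals = np.where((t < lo) | (t > hi), 0.0, vals)
            cols.append(vals)
        return np.column_stack(cols)


def build_spline_basis(
    time_range: tuple[float, float] = (0.0, 70.0),
    n_knots: int = 5,
    degree: int = 3,
) -> SplineBasis:
    """Evenly spaced clamped B-spline basis over ``time_range``."""
    lo, hi = float(time_range[0]), float(time_range[1])
    if not hi > lo:
        raise ValueError(f"degenerate time_range {time_range!r}")
    if n_knots < 1:
        raise ValueError("n_knots must be >= 1")
    knots = np.linspace(lo, hi, n_knots)
    return SplineBasis(degree=degree, knots=knots, time_range=(lo, hi))


@dataclass(frozen=True)
class HealingFunctionSpec:
    """A healing-rate function family with its parameter vector.

    Parameters
    ----------
    family
        One of the eleven supported families (enum or its string name).
    rho
        Parameter vector; length must match the family arity (the spline
        basis size for the semiparametric family).
    t_max
        Time-rescaling constant for the compactly supported Wendland
        families (days at which the mean area reaches exactly zero).
        Ignored by the other families.  Default 100.
    basis
        Required for the semiparametric family.
    wendland_as_printed
        Audit flag: evaluate Wendland 1 as ``(1+(p+1)s)(1+s)^{p+1}`` — a
        form that never reaches zero — instead of the compactly supported
        ``(1+(p+1)s)(1-s)_+^{p+1}``.
    """

    family: Family
    rho: np.ndarray
    t_max: float = 100.0
    basis: SplineBasis | None = None
    wendland_as_printed: bool = False

    def __post_init__(self) -> None:
        fam = Family(self.family)
        object.__setattr__(self, "family", fam)
        rho = np.atleast_1d(np.asarray(self.rho, dtype=float))
        arity = FAMILY_ARITY[fam]
        if fam is Family.SEMIPARAMETRIC:
            if self.basis is None:
                raise ValueError("semiparametric family requires a SplineBasis")
            arity = self.basis.basis_count
        if rho.shape != (arity,):
            raise ValueError(
                f"family {fam.value!r} takes {arity} parameter(s), got {rho.shape}"
            )
        if not self.t_max > 0:
            raise ValueError("t_max must be positive")
        object.__setattr__(self, "rho", rho)


def _check_time(t) -> tuple[np.ndarray, bool]:
    arr = np.asarray(t, dtype=float)
    scalar = arr.ndim == 0
    arr = np.atleast_1d(arr)
    if np.any(arr < 0):
        raise ValueError("time must be non-negative")
    return arr, scalar


def evaluate(spec: HealingFunctionSpec, t) -> np.ndarray | float:
    """Evaluate f(t; rho); vectorised over ``t``.

    Wendland families are rescaled by ``s = t / t_max`` and return exactly
    0 for t >= t_max (unless the as-printed audit variant is requested).
    """
    tt, scalar = _check_time(t)
    rho = spec.rho
    fam = spec.family
    if fam is Family.EXPONENTIAL:
        out = np.exp(-rho[0] * tt)
    elif fam is Family.GOMPERTZ:
        out = np.exp(1.0 - np.exp(rho[0] * tt))
    elif fam is Family.LINEAR:
        out = 1.0 + rho[0] * tt
    elif fam is Family.QUADRATIC:
        out = 1.0 + rho[0] * tt + rho[1] * tt**2
    elif fam is Family.SQUARE_ROOT:
        out = 1.0 + rho[0] * tt + rho[1] * np.sqrt(tt)
    elif fam is Family.WENDLAND0:
        s = tt / spec.t_max
        out = np.where(s < 1.0, np.clip(1.0 - s, 0.0, None) ** rho[0], 0.0)
    elif fam is Family.WENDLAND1:
        s = tt / spec.t_max
        p = rho[0]
        if spec.wendland_as_printed:
            out = (1.0 + (p + 1.0) * s) * (1.0 + s) ** (p + 1.0)
        else:
            base = np.clip(1.0 - s, 0.0, None)
            out = np.where(s < 1.0, (1.0 + (p + 1.0) * s) * base ** (p + 1.0), 0.0)
    elif fam is Family.SEMIPARAMETRIC:
        out = 1.0 - spec.basis.design_matrix(tt) @ rho
    elif fam is Family.LOG_LINEAR:
        out = np.exp(1.0 + rho[0] * tt)
    elif fam is Family.LOG_QUADRATIC:
        out = np.exp(1.0 + rho[0] * tt + rho[1] * tt**2)
    elif fam is Family.LOG_SQUARE_ROOT:
        out = np.exp(1.0 + rho[0] * tt + rho[1] * np.sqrt(tt))
    else:  # pragma: no cover
        raise ValueError(f"unknown family {fam!r}")
    return float(out[0]) if scalar else out


def evaluate_derivative(spec: HealingFunctionSpec, t) -> np.ndarray | float:
    """Analytic df/dt; vectorised over ``t``.

    For the square-root families the derivative contains 1/(2 sqrt(t)) and
    is unbounded at the origin, so t = 0 raises a ``ValueError`` rather
    than returning an infinity.
    """
    tt, scalar = _check_time(t)
    rho = spec.rho
    fam = spec.family
    if fam in SQRT_FAMILIES and np.any(tt == 0.0):
        raise ValueError(
            f"derivative of the {fam.value} family is singular at t = 0"
        )
    if fam is Family.EXPONENTIAL:
        out = -rho[0] * np.exp(-rho[0] * tt)
    elif fam is Family.GOMPERTZ:
        out = -rho[0] * np.exp(rho[0] * tt) * np.exp(1.0 - np.exp(rho[0] * tt))
    elif fam is Family.LINEAR:
        out = np.full_like(tt, rho[0])
    elif fam is Family.QUADRATIC:
        out = rho[0] + 2.0 * rho[1] * tt
    elif fam is Family.SQUARE_ROOT:
        out = rho[0] + rho[1] / (2.0 * np.sqrt(tt))
    elif fam is Family.WENDLAND0:
        s = tt / spec.t_max
        p = rho[0]
        base = np.clip(1.0 - s, 0.0, None)
        out = np.where(s < 1.0, -(p / spec.t_max) * base ** (p - 1.0), 0.0)
    elif fam is Family.WENDLAND1:
        s = tt / spec.t_max
        p = rho[0]
        if spec.wendland_as_printed:
            out = (
                (p + 1.0) * (1.0 + s) ** (p + 1.0)
                + (1.0 + (p + 1.0) * s) * (p + 1.0) * (1.0 + s) ** p
            ) / spec.t_max
        else:
            base = np.clip(1.0 - s, 0.0, None)
            out = np.where(
                s < 1.0,
                -(p + 1.0) * (p + 2.0) * s * base**p / spec.t_max,
                0.0,
            )
    elif fam is Family.SEMIPARAMETRIC:
        out = -(spec.basis.derivative_matrix(tt) @ rho)
    elif fam is Family.LOG_LINEAR:
        out = rho[0] * np.exp(1.0 + rho[0] * tt)
    elif fam is Family.LOG_QUADRATIC:
        out = (rho[0] + 2.0 * rho[1] * tt) * np.exp(
            1.0 + rho[0] * tt + rho[1] * tt**2
        )
    elif fam is Family.LOG_SQUARE_ROOT:
        st = np.sqrt(tt)
        out = (rho[0] + rho[1] / (2.0 * st)) * np.exp(1.0 + rho[0] * tt + rho[1] * st)
    else:  # pragma: no cover
        raise ValueError(f"unknown family {fam!r}")
    return float(out[0]) if scalar else out


def make_spec(
    family: str | Family,
    rho: Sequence[float] | np.ndarray,
    t_max: float = 100.0,
    basis: SplineBasis | None = None,
) -> HealingFunctionSpec:
    """Convenience constructor from a family name string."""
    return HealingFunctionSpec(family=Family(family), rho=np.asarray(rho, float),
                               t_max=t_max, basis=basis)
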