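"""Natural-cubic-spline and B-spline basis machinery.

The longitudinal sub-model expresses the true square-root CD4 trajectory as
an intercept plus a natural cubic spline (NCS) of time.  The hazard needs not
only the basis values but their exact first derivative (slope association)
and running integral from zero (cumulative association), so all three are
provided analytically from the same piecewise-cubic representation.  The log
baseline hazard uses an ordinary open-knot B-spline basis.

The NCS is built from a cubic B-spline basis with the two natural boundary
constraints (zero second derivative at each boundary knot) imposed through a
null-space projection; this spans the same function space as the classical
``ns`` parameterization.  Beyond the boundary knots every basis column is
continued linearly, which is required because event times can exceed the last
CD4 measurement time.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.interpolate import BSpline

from .errors import ConfigurationError, DomainError

__all__ = [
    "NcsSpec",
    "BaselineSplineSpec",
    "ncs_basis",
    "ncs_basis_deriv",
    "ncs_basis_integral",
    "bspline_basis",
    "n_baseline_coefs",
]


# ---------------------------------------------------------------------------
# specs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NcsSpec:
    """Knot layout of the natural cubic spline of time (months).

    ``intercept_excluded`` is always true here: the basis columns span the
    non-constant part of the NCS space and the model carries its own
    intercept.  With K interior knots the basis has K+1 columns.
    """

    boundary_knots: tuple[float, float]
    interior_knots: tuple[float, ...]
    intercept_excluded: bool = True

    def __post_init__(self) -> None:
        lo, hi = self.boundary_knots
        ik = np.asarray(self.interior_knots, dtype=float)
        if not np.isfinite([lo, hi]).all() or not lo < hi:
            raise ConfigurationError(f"boundary knots must satisfy lo < hi, got {self.boundary_knots}")
        if ik.size == 0:
            raise ConfigurationError("at least one interior knot is required")
        if np.any(np.diff(ik) <= 0):
            raise ConfigurationError(f"interior knots must be strictly increasing, got {tuple(ik)}")
        if not (lo < ik[0] and ik[-1] < hi):
            raise ConfigurationError("interior knots must lie strictly inside the boundary knots")
        object.__setattr__(self, "interior_knots", tuple(float(t) for t in ik))
        object.__setattr__(self, "boundary_knots", (float(lo), float(hi)))

    @property
    def n_basis(self) -> int:
        return len(self.interior_knots) + 1

    @classmethod
    def from_times(cls, times, n_interior: int = 1) -> "NcsSpec":
        """Knots from observed measurement times: boundary at min/max, one
        interior knot per inner percentile (the default single knot sits at
        the pooled median of measurement times)."""
        t = np.asarray(times, dtype=float)
        lo, hi = float(t.min()), float(t.max())
        qs = np.linspace(0, 100, n_interior + 2)[1:-1]
        interior = np.percentile(t, qs)
        eps = 1e-8 * (hi - lo)
        interior = np.clip(interior, lo + eps, hi - eps)
        return cls((lo, hi), tuple(interior))


@dataclass(frozen=True)
class BaselineSplineSpec:
    """B-spline layout of the log baseline hazard over the follow-up range."""

    degree: int = 3
    interior_knots: tuple[float, ...] = ()
    boundary_knots: tuple[float, float] = (0.0, 1.0)

    def __post_init__(self) -> None:
        if self.degree < 1:
            raise ConfigurationError("baseline spline degree must be >= 1")
        lo, hi = self.boundary_knots
        if not lo < hi:
            raise ConfigurationError("boundary knots must satisfy lo < hi")
        ik = np.asarray(self.interior_knots, dtype=float)
        if ik.size and (np.any(np.diff(ik) <= 0) or ik[0] <= lo or ik[-1] >= hi):
            raise ConfigurationError("interior knots must be strictly increasing and strictly inside the boundary")
        object.__setattr__(self, "interior_knots", tuple(float(t) for t in ik))
        object.__setattr__(self, "boundary_knots", (float(lo), float(hi)))

    @property
    def n_basis(self) -> int:
        # open (clamped) knot vector: Q interior knots + degree + 1 functions
        return len(self.interior_knots) + self.degree + 1

    @classmethod
    def from_event_times(cls, event_times, t_max: float, degree: int = 3,
                         n_interior: int = 5) -> "BaselineSplineSpec":
        """Interior knots at equally spaced percentiles of observed event
        times, support [0, t_max]."""
        ev = np.asarray(event_times, dtype=float)
        if ev.size == 0:
            interior = np.linspace(0.0, t_max, n_interior + 2)[1:-1]
        else:
            qs = np.linspace(0, 100, n_interior + 2)[1:-1]
            interior = np.percentile(ev, qs)
        eps = 1e-6 * t_max
        interior = np.clip(interior, eps, t_max - eps)
        # percentiles of clustered event times may collide; fall back to jitterless spacing
        if np.any(np.diff(interior) <= 0):
            interior = np.linspace(0.0, t_max, n_interior + 2)[1:-1]
        return cls(degree, tuple(interior), (0.0, float(t_max)))


def n_baseline_coefs(spec: BaselineSplineSpec) -> int:
    """Length of the baseline log-hazard coefficient vector k."""
    return spec.n_basis


# ---------------------------------------------------------------------------
# NCS construction
# ---------------------------------------------------------------------------

@lru_cache(maxsize=64)
def _ncs_elements(spec: NcsSpec):
    """Cubic B-spline elements and the natural-constraint projection.

    Returns (splines, proj) where ``splines`` is the list of K+3 cubic
    B-spline elements (intercept column already dropped) and ``proj`` the
    (K+3)x(K+1) matrix whose columns span the null space of the boundary
    second-derivative constraints.
    """
    lo, hi = spec.boundary_knots
    knots = np.concatenate([[lo] * 4, spec.interior_knots, [hi] * 4])
    n_full = len(spec.interior_knots) + 4
    eye = np.eye(n_full)
    splines = [BSpline(knots, eye[j], 3, extrapolate=False) for j in range(n_full)]
    # second derivative of every column at both boundaries: 2 x n_full
    d2 = np.array([[s.derivative(2)(x) for s in splines] for x in (lo, hi)])
    # drop the leading column (absorbed by the model intercept), then project
    splines = splines[1:]
    d2 = d2[:, 1:]
    q, _ = np.linalg.qr(d2.T, mode="complete")
    proj = q[:, 2:]  # (K+3) x (K+1)
    return splines, proj


def _ncs_eval(times, spec: NcsSpec, order: int):
    """Projected NCS design of the given derivative order, with linear tails."""
    t = np.asarray(times, dtype=float)
    if t.ndim != 1:
        t = np.atleast_1d(t).ravel()
    splines, proj = _ncs_elements(spec)
    lo, hi = spec.boundary_knots

    def raw(x, der):
        out = np.empty((x.size, len(splines)))
        for j, s in enumerate(splines):
            out[:, j] = (s if der == 0 else s.derivative(der))(x)
        return np.nan_to_num(out)

    tc = np.clip(t, lo, hi)
    inside = raw(tc, order) if order <= 3 else np.zeros((t.size, len(splines)))
    out = inside @ proj

    below, above = t < lo, t > hi
    for mask, edge in ((below, lo), (above, hi)):
        if not mask.any():
            continue
        e = np.array([edge])
        v0 = (raw(e, 0) @ proj)[0]
        v1 = (raw(e, 1) @ proj)[0]
        dt = t[mask] - edge
        if order == 0:
            out[mask] = v0 + np.outer(dt, v1)
        elif order == 1:
            out[mask] = v1
        else:
            out[mask] = 0.0
    return out


def ncs_basis(times, spec: NcsSpec) -> np.ndarray:
    """NCS design matrix (no intercept column), C2 inside the boundary knots
    and exactly linear outside them.  Shape (n_times, K+1)."""
    return _ncs_eval(times, spec, 0)


def ncs_basis_deriv(times, spec: NcsSpec) -> np.ndarray:
    """Exact first derivative of each NCS basis column."""
    return _ncs_eval(times, spec, 1)


def ncs_basis_integral(times, spec: NcsSpec) -> np.ndarray:
    """Column-wise running integral ∫₀ᵗ of the NCS basis (linear tails
    included), exact for the piecewise-cubic form.  Requires t >= 0."""
    t = np.asarray(times, dtype=float).ravel()
    if np.any(t < 0):
        raise DomainError("ncs_basis_integral requires nonnegative times")
    splines, proj = _ncs_elements(spec)
    lo, hi = spec.boundary_knots
    antis = [s.antiderivative() for s in splines]

    def anti(x):
        x = np.asarray(x, dtype=float)
        xc = np.clip(x, lo, hi)
        out = np.empty((xc.size, len(splines)))
        for j, a in enumerate(antis):
            out[:, j] = a(xc)
        return np.nan_to_num(out) @ proj

    def val_slope(edge):
        e = np.array([edge])
        raw0 = np.empty((1, len(splines)))
        raw1 = np.empty((1, len(splines)))
        for j, s in enumerate(splines):
            raw0[0, j] = s(edge)
            raw1[0, j] = s.derivative(1)(edge)
        return (np.nan_to_num(raw0) @ proj)[0], (np.nan_to_num(raw1) @ proj)[0]

    # integral measured from 0; 0 may sit below, inside or above [lo, hi]
    base = 0.0
    v_lo, s_lo = val_slope(lo)
    v_hi, s_hi = val_slope(hi)

    def integral_from_lo(x):
        """∫_lo^x for scalar-or-array x (x may be anywhere)."""
        x = np.atleast_1d(np.asarray(x, dtype=float))
        res = anti(x) - anti(np.full_like(x, lo))
        blw, abv = x < lo, x > hi
        if blw.any():
            dt = x[blw] - lo
            res[blw] = np.outer(dt, v_lo) + 0.5 * np.outer(dt ** 2, s_lo)
        if abv.any():
            dt = x[abv] - hi
            res[abv] += np.outer(dt, v_hi) + 0.5 * np.outer(dt ** 2, s_hi)
        return res

    zero_part = integral_from_lo(np.array([0.0]))[0]
    return integral_from_lo(t) - zero_part + base


# ---------------------------------------------------------------------------
# baseline-hazard B-splines
# ---------------------------------------------------------------------------

def bspline_basis(times, spec: BaselineSplineSpec) -> np.ndarray:
    """Open-knot B-spline basis of the given degree on the follow-up range.

    Rows sum to one (partition of unity).  Evaluation outside the boundary
    knots is a domain error: the baseline hazard is never needed there.
    """
    t = np.asarray(times, dtype=float).ravel()
    lo, hi = spec.boundary_knots
    if np.any(t < lo - 1e-12) or np.any(t > hi + 1e-12):
        raise DomainError(
            f"baseline spline evaluated outside its support [{lo}, {hi}]")
    t = np.clip(t, lo, hi)
    g = spec.degree
    knots = np.concatenate([[lo] * (g + 1), spec.interior_knots, [hi] * (g + 1)])
    design = BSpline.design_matrix(t, knots, g, extrapolate=False).toarray()
    # design_matrix assigns the right-closed end point to the last interval already
    return design
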