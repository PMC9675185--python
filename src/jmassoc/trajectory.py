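"""Subject-specific longitudinal model and the trajectory functionals.

The true (noise-free) square-root CD4 trajectory of subject i is

    m_i(t) = (beta0 + b_i0) + sum_k (beta_k + b_ik) * B_n(t, lambda_k)

with B_n the natural-cubic-spline basis, b_i ~ N(0, D) subject-level random
effects and independent residuals eps ~ N(0, sigma2_eps).  Four functionals
of m_i enter the hazard: its current value, its slope, its running area and
a weighted running area with a normalized truncated-normal kernel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.polynomial.legendre import leggauss
from scipy.stats import norm

from .errors import ConfigurationError, DataError, DomainError
from .splines import NcsSpec, ncs_basis, ncs_basis_deriv, ncs_basis_integral

__all__ = [
    "TrajectoryParams",
    "SubjectEffects",
    "WeightSpec",
    "m_value",
    "m_slope",
    "m_area",
    "weight_fn",
    "m_weighted_area",
    "weighted_area_design",
    "longitudinal_loglik",
]


@dataclass(frozen=True)
class TrajectoryParams:
    """Population parameters of the longitudinal sub-model (sqrt-cells scale).

    beta: fixed effects (intercept + one per spline column).
    D: random-effects covariance (symmetric positive definite).
    sigma2_eps: residual variance.
    """

    beta: tuple[float, ...]
    D: np.ndarray
    sigma2_eps: float

    def __post_init__(self) -> None:
        beta = np.asarray(self.beta, dtype=float)
        D = np.asarray(self.D, dtype=float)
        if D.shape != (beta.size, beta.size):
            raise ConfigurationError(f"D must be {beta.size}x{beta.size}, got {D.shape}")
        if not np.allclose(D, D.T):
            raise ConfigurationError("D must be symmetric")
        if np.any(np.linalg.eigvalsh(D) <= 0):
            raise ConfigurationError("D must be positive definite")
        if not self.sigma2_eps > 0:
            raise ConfigurationError("sigma2_eps must be positive")
        object.__setattr__(self, "beta", tuple(float(b) for b in beta))
        object.__setattr__(self, "D", D)


@dataclass(frozen=True)
class SubjectEffects:
    """Random-effect vector b_i of one subject."""

    b: tuple[float, ...]

    def __post_init__(self) -> None:
        b = np.asarray(self.b, dtype=float)
        if not np.isfinite(b).all():
            raise ConfigurationError("random effects must be finite")
        object.__setattr__(self, "b", tuple(float(x) for x in b))


@dataclass(frozen=True)
class WeightSpec:
    """Normal weight kernel for the weighted cumulative association.

    sigma_w controls how fast past marker values lose influence; t_max is
    the (single, dataset-wide) upper limit of the normalizing integral.
    """

    sigma_w: float
    t_max: float

    def __post_init__(self) -> None:
        if not self.sigma_w > 0:
            raise ConfigurationError("sigma_w must be positive")
        if not self.t_max > 0:
            raise ConfigurationError("t_max must be positive")


# ---------------------------------------------------------------------------
# design rows: every functional is linear in (beta + b)
# ---------------------------------------------------------------------------

def value_design(times, ncs: NcsSpec) -> np.ndarray:
    """[1 | B_n(t)] rows so that m(t) = row · (beta + b)."""
    t = np.atleast_1d(np.asarray(times, dtype=float))
    return np.column_stack([np.ones(t.size), ncs_basis(t, ncs)])


def slope_design(times, ncs: NcsSpec) -> np.ndarray:
    t = np.atleast_1d(np.asarray(times, dtype=float))
    return np.column_stack([np.zeros(t.size), ncs_basis_deriv(t, ncs)])


def area_design(times, ncs: NcsSpec) -> np.ndarray:
    t = np.atleast_1d(np.asarray(times, dtype=float))
    return np.column_stack([t, ncs_basis_integral(t, ncs)])


def _coef(params: TrajectoryParams, effects: SubjectEffects) -> np.ndarray:
    beta = np.asarray(params.beta)
    b = np.asarray(effects.b)
    if b.size != beta.size:
        raise ConfigurationError("random-effect vector length must match beta")
    return beta + b


def m_value(t, params: TrajectoryParams, effects: SubjectEffects, ncs: NcsSpec):
    """True trajectory level m_i(t), sqrt-cells."""
    out = value_design(t, ncs) @ _coef(params, effects)
    return out if np.ndim(t) else float(out[0])


def m_slope(t, params: TrajectoryParams, effects: SubjectEffects, ncs: NcsSpec):
    """Instantaneous rate of change m_i'(t), sqrt-cells per month."""
    out = slope_design(t, ncs) @ _coef(params, effects)
    return out if np.ndim(t) else float(out[0])


def m_area(t, params: TrajectoryParams, effects: SubjectEffects, ncs: NcsSpec):
    """Running area ∫₀ᵗ m_i(s) ds, closed form."""
    if np.any(np.atleast_1d(t) < 0):
        raise DomainError("m_area requires t >= 0")
    out = area_design(t, ncs) @ _coef(params, effects)
    return out if np.ndim(t) else float(out[0])


# ---------------------------------------------------------------------------
# weighted cumulative functional
# ---------------------------------------------------------------------------

def weight_fn(u, w: WeightSpec):
    """Normal kernel in elapsed time u = t - s, normalized so that the kernel
    integrates to one over [0, t_max]; zero outside [0, t_max]."""
    u_arr = np.atleast_1d(np.asarray(u, dtype=float))
    z = norm.cdf(w.t_max / w.sigma_w) - 0.5
    dens = norm.pdf(u_arr / w.sigma_w) / (w.sigma_w * z)
    dens = np.where((u_arr < 0) | (u_arr > w.t_max), 0.0, dens)
    return dens if np.ndim(u) else float(dens[0])


def _weighted_panels(t: float, w: WeightSpec) -> np.ndarray:
    """Panel boundaries on [0, t] for the weighted integral.

    The kernel peaks at s = t; when it is narrow relative to t the panels are
    graded towards the peak (widths ~ sigma_w) so a fixed-order rule stays
    accurate for concentrated weights.
    """
    if w.sigma_w >= t / 10 or t == 0.0:
        return np.linspace(0.0, t, 3)
    offs = np.array([0.0, 1.0, 2.0, 4.0, 8.0]) * w.sigma_w
    pts = t - offs
    pts = pts[pts > 0.0]
    pts = np.unique(np.concatenate([[0.0], pts, [t]]))
    return pts


_GL_NODES, _GL_WEIGHTS = leggauss(15)


def _panel_quadrature(panels: np.ndarray):
    """Gauss–Legendre nodes/weights over a sequence of panels."""
    a, b = panels[:-1], panels[1:]
    half = 0.5 * (b - a)
    mid = 0.5 * (a + b)
    nodes = (mid[:, None] + half[:, None] * _GL_NODES[None, :]).ravel()
    wts = (half[:, None] * _GL_WEIGHTS[None, :]).ravel()
    return nodes, wts


def weighted_area_design(t: float, ncs: NcsSpec, w: WeightSpec) -> np.ndarray:
    """Design row v(t) with ∫₀ᵗ ϖ(t-s) m(s) ds = v(t) · (beta + b)."""
    t = float(t)
    if t < 0:
        raise DomainError("weighted area requires t >= 0")
    if t == 0.0:
        return np.zeros(len(ncs.interior_knots) + 2)
    nodes, wts = _panel_quadrature(_weighted_panels(t, w))
    kern = weight_fn(t - nodes, w)
    return (wts * kern) @ value_design(nodes, ncs)


def m_weighted_area(t, params: TrajectoryParams, effects: SubjectEffects,
                    ncs: NcsSpec, w: WeightSpec):
    """Weighted running integral ∫₀ᵗ ϖ(t−s) m_i(s) ds (Gauss–Legendre)."""
    coef = _coef(params, effects)
    ts = np.atleast_1d(np.asarray(t, dtype=float))
    out = np.array([weighted_area_design(ti, ncs, w) @ coef for ti in ts])
    return out if np.ndim(t) else float(out[0])


# ---------------------------------------------------------------------------
# longitudinal likelihood (conditional on random effects)
# ---------------------------------------------------------------------------

def longitudinal_loglik(dataset, params: TrajectoryParams, effects_all,
                        ncs: NcsSpec) -> float:
    """Gaussian log-likelihood of all measurements around the subject curves.

    ``effects_all`` maps subject id -> SubjectEffects (or a b-vector).
    Full normalizing constants are included.
    """
    long = dataset.longitudinal
    y = long["sqrt_cd4"].to_numpy(dtype=float)
    if not np.isfinite(y).all():
        raise DataError("non-finite longitudinal measurements")
    times = long["time_months"].to_numpy(dtype=float)
    X = value_design(times, ncs)
    beta = np.asarray(params.beta)
    ids = long["subject_id"].to_numpy()
    mu = np.empty_like(y)
    for sid in np.unique(ids):
        eff = effects_all[sid]
        b = np.asarray(eff.b if isinstance(eff, SubjectEffects) else eff, dtype=float)
        mask = ids == sid
        mu[mask] = X[mask] @ (beta + b)
    v = params.sigma2_eps
    r = y - mu
    return float(-0.5 * (y.size * np.log(2 * np.pi * v) + r @ r / v))
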