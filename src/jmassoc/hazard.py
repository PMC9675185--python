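"""Relative-risk survival sub-model under the four association structures.

The hazard of subject i is

    h_i(t) = h0(t) * exp{ gamma1*Arm + gamma2*Age + gamma3*Gender + assoc(t) }

with log h0(t) a B-spline in t and assoc(t) one of:

    current_value        alpha * m_i(t)
    slopes               alpha1 * m_i(t) + alpha2 * m_i'(t)
    cumulative           alpha * ∫₀ᵗ m_i(s) ds
    weighted_cumulative  alpha * ∫₀ᵗ ϖ(t−s) m_i(s) ds

All functions here are the straightforward reference path (per-subject,
quadrature on demand); the sampler keeps its own vectorized cache that is
tested against these.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.stats import multivariate_normal

from .data import SubjectCovariates, TrialDataset
from .errors import ConfigurationError, DataError, DomainError
from .splines import BaselineSplineSpec, NcsSpec, bspline_basis, n_baseline_coefs
from .trajectory import (SubjectEffects, TrajectoryParams, WeightSpec,
                         _panel_quadrature, longitudinal_loglik, m_area,
                         m_slope, m_value, m_weighted_area)

__all__ = [
    "AssociationStructure",
    "SurvivalParams",
    "STRUCTURE_TAGS",
    "log_hazard",
    "cumulative_hazard",
    "survival_loglik",
    "joint_loglik",
]

STRUCTURE_TAGS = ("current_value", "slopes", "cumulative", "weighted_cumulative")


@dataclass(frozen=True)
class AssociationStructure:
    """Which functional of the trajectory drives the hazard."""

    tag: str
    weight: Optional[WeightSpec] = None

    def __post_init__(self) -> None:
        if self.tag not in STRUCTURE_TAGS:
            raise ConfigurationError(f"unknown association structure {self.tag!r}")
        if (self.tag == "weighted_cumulative") != (self.weight is not None):
            raise ConfigurationError(
                "weight spec must be supplied exactly for the weighted_cumulative structure")


@dataclass(frozen=True)
class SurvivalParams:
    """Survival sub-model coefficients.

    gamma: (arm, age, gender) log-hazard-ratios; alpha1 the association
    coefficient (alpha, or alpha1 for the slopes structure); alpha2 only for
    the slopes structure; k the baseline log-hazard spline coefficients.
    """

    gamma: tuple[float, float, float]
    alpha1: float
    k: tuple[float, ...]
    alpha2: Optional[float] = None

    def __post_init__(self) -> None:
        vals = list(self.gamma) + [self.alpha1] + list(self.k)
        if self.alpha2 is not None:
            vals.append(self.alpha2)
        if not np.isfinite(vals).all():
            raise ConfigurationError("survival parameters must be finite")
        object.__setattr__(self, "gamma", tuple(float(g) for g in self.gamma))
        object.__setattr__(self, "k", tuple(float(x) for x in self.k))

    def require_match(self, structure: AssociationStructure,
                      baseline: BaselineSplineSpec) -> None:
        if (structure.tag == "slopes") != (self.alpha2 is not None):
            raise ConfigurationError(
                "alpha2 must be present exactly for the slopes structure")
        if len(self.k) != n_baseline_coefs(baseline):
            raise ConfigurationError(
                f"baseline coefficient vector must have length "
                f"{n_baseline_coefs(baseline)}, got {len(self.k)}")


def log_baseline(t, surv_params: SurvivalParams, baseline: BaselineSplineSpec):
    return bspline_basis(t, baseline) @ np.asarray(surv_params.k)


def _association(t, structure: AssociationStructure, surv: SurvivalParams,
                 traj: TrajectoryParams, effects: SubjectEffects, ncs: NcsSpec):
    tag = structure.tag
    if tag == "current_value":
        return surv.alpha1 * np.atleast_1d(m_value(t, traj, effects, ncs))
    if tag == "slopes":
        return (surv.alpha1 * np.atleast_1d(m_value(t, traj, effects, ncs))
                + surv.alpha2 * np.atleast_1d(m_slope(t, traj, effects, ncs)))
    if tag == "cumulative":
        return surv.alpha1 * np.atleast_1d(m_area(t, traj, effects, ncs))
    return surv.alpha1 * np.atleast_1d(
        m_weighted_area(t, traj, effects, ncs, structure.weight))


def log_hazard(t, structure: AssociationStructure, surv_params: SurvivalParams,
               traj_params: TrajectoryParams, effects: SubjectEffects,
               covs: SubjectCovariates, *, ncs: NcsSpec,
               baseline: BaselineSplineSpec):
    """log h_i(t) (per month) at one or many times t."""
    surv_params.require_match(structure, baseline)
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    out = (log_baseline(t_arr, surv_params, baseline)
           + np.asarray(surv_params.gamma) @ covs.as_array()
           + _association(t_arr, structure, surv_params, traj_params, effects, ncs))
    return out if np.ndim(t) else float(out[0])


def cumulative_hazard(T, structure: AssociationStructure,
                      surv_params: SurvivalParams, traj_params: TrajectoryParams,
                      effects: SubjectEffects, covs: SubjectCovariates, *,
                      ncs: NcsSpec, baseline: BaselineSplineSpec,
                      n_panels: Optional[int] = None) -> float:
    """H_i(T) = ∫₀ᵀ h_i(s) ds by panelized 15-point Gauss–Legendre."""
    T = float(T)
    if T < 0:
        raise DomainError("cumulative hazard requires T >= 0")
    if T == 0.0:
        return 0.0
    lo, hi = baseline.boundary_knots
    if T > hi + 1e-9:
        raise DomainError(f"T={T} beyond baseline spline support [{lo}, {hi}]")
    if n_panels is None:
        n_panels = 7 if T > 12.0 else 1
    nodes, wts = _panel_quadrature(np.linspace(0.0, T, n_panels + 1))
    lh = log_hazard(nodes, structure, surv_params, traj_params, effects, covs,
                    ncs=ncs, baseline=baseline)
    return float(wts @ np.exp(lh))


def survival_loglik(dataset: TrialDataset, structure: AssociationStructure,
                    surv_params: SurvivalParams, traj_params: TrajectoryParams,
                    effects_all, *, ncs: NcsSpec, baseline: BaselineSplineSpec,
                    n_panels: Optional[int] = None) -> float:
    """Sum over subjects of delta_i * log h_i(T_i) - H_i(T_i), given b_i."""
    surv = dataset.survival
    if (surv["time_months"] < 0).any():
        raise DataError("negative survival times")
    total = 0.0
    for row in surv.itertuples(index=False):
        sid, T, delta = row.subject_id, float(row.time_months), int(row.event)
        eff = effects_all[sid]
        if not isinstance(eff, SubjectEffects):
            eff = SubjectEffects(tuple(np.asarray(eff, dtype=float)))
        covs = SubjectCovariates(int(row.arm), float(row.age), int(row.gender))
        H = cumulative_hazard(T, structure, surv_params, traj_params, eff, covs,
                              ncs=ncs, baseline=baseline, n_panels=n_panels)
        total -= H
        if delta:
            total += log_hazard(T, structure, surv_params, traj_params, eff,
                                covs, ncs=ncs, baseline=baseline)
    return float(total)


def joint_loglik(dataset: TrialDataset, structure: AssociationStructure,
                 surv_params: SurvivalParams, traj_params: TrajectoryParams,
                 effects_all, *, ncs: NcsSpec, baseline: BaselineSplineSpec,
                 n_panels: Optional[int] = None) -> float:
    """Conditional joint log-density: longitudinal + survival + b-prior."""
    ll = longitudinal_loglik(dataset, traj_params, effects_all, ncs)
    ll += survival_loglik(dataset, structure, surv_params, traj_params,
                          effects_all, ncs=ncs, baseline=baseline,
                          n_panels=n_panels)
    D = np.asarray(traj_params.D)
    mvn = multivariate_normal(mean=np.zeros(D.shape[0]), cov=D)
    for sid in dataset.subject_ids:
        eff = effects_all[sid]
        b = np.asarray(eff.b if isinstance(eff, SubjectEffects) else eff, dtype=float)
        ll += float(mvn.logpdf(b))
    return float(ll)
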