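"""Bayesian estimation of the joint model by adaptive Metropolis-within-Gibbs.

The posterior is proportional to

    exp{ longitudinal loglik + survival loglik + sum_i log N(b_i; 0, D) }
      x priors(beta, gamma, alpha, k, sigma2_eps, D, sigma_w)

Updates are blocked: beta | rest, all b_i | rest (vectorized across subjects,
accepted per subject), (gamma, alpha) | rest, k | rest; sigma2_eps is drawn
exactly from its conditional Inverse-Gamma; the random-effects covariance is
parameterized as scales + correlations and updated by scalar random walks;
log sigma_w (weighted structure only) by a scalar random walk.  Proposal
scales and block covariances adapt during a dedicated adaptation phase and
are frozen afterwards, so the chain is a valid Markov chain when draws are
collected.

Everything expensive (spline designs at quadrature nodes, per-subject
quadrature weights) is precomputed once per dataset in a cache; the cache is
tested against the plain reference implementations in :mod:`jmassoc.hazard`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
import pandas as pd

from .data import TrialDataset
from .errors import ConfigurationError, DataError, InitializationError
from .hazard import AssociationStructure
from .splines import BaselineSplineSpec, NcsSpec, bspline_basis
from .trajectory import (WeightSpec, area_design, slope_design,
                         value_design, weight_fn)

logger = logging.getLogger(__name__)

__all__ = [
    "PriorSpec",
    "McmcSettings",
    "PosteriorDraws",
    "initialize",
    "fit_joint_model",
    "summarize",
    "diagnostics",
]


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PriorSpec:
    """Priors; the emulated study reports none, so these are package choices
    recorded in every run's metadata."""

    coef_sd: float = 10.0            # beta, gamma, alpha ~ N(0, coef_sd^2)
    sigma2_eps_a: float = 0.01       # Inverse-Gamma shape
    sigma2_eps_b: float = 0.01       # Inverse-Gamma rate
    re_scale_cauchy: float = 2.5     # Half-Cauchy scale for D's scales
    k_sd: float = 10.0               # baseline coefficients ~ N(0, k_sd^2)
    k_rw1_sd: Optional[float] = None  # optional first-order random-walk shrinkage
    log_sigma_w_sd: float = 1.0      # log sigma_w ~ N(log(t_max/4), sd^2)

    def __post_init__(self) -> None:
        for v in (self.coef_sd, self.sigma2_eps_a, self.sigma2_eps_b,
                  self.re_scale_cauchy, self.k_sd, self.log_sigma_w_sd):
            if not v > 0:
                raise ConfigurationError("prior hyperparameters must be positive")


@dataclass(frozen=True)
class McmcSettings:
    n_chains: int = 3
    n_adapt: int = 1000
    n_burnin: int = 1000
    n_iter: int = 2000
    thin: int = 1
    seed: int = 0
    target_accept_block: float = 0.234
    target_accept_scalar: float = 0.44

    def __post_init__(self) -> None:
        for v in (self.n_chains, self.n_adapt, self.n_burnin, self.n_iter, self.thin):
            if v < 1:
                raise ConfigurationError("all MCMC counts must be positive")


@dataclass
class PosteriorDraws:
    """Labelled posterior draws: each entry of ``params`` has shape
    (n_chains, n_kept, ...).  ``subject_loglik`` stores the per-subject
    conditional (on b) log-likelihood of every kept draw for LPML/DIC."""

    params: dict
    subject_loglik: np.ndarray      # (chains, kept, n_subjects)
    cond_loglik: np.ndarray         # (chains, kept)
    b_mean: np.ndarray              # (n_subjects, n_re) posterior mean
    structure_tag: str
    meta: dict = field(default_factory=dict)
    loglik_at: Optional[Callable] = None  # theta-bar likelihood hook (in-session)

    @property
    def n_chains(self) -> int:
        return self.cond_loglik.shape[0]

    @property
    def n_kept(self) -> int:
        return self.cond_loglik.shape[1]

    def flat(self, name: str) -> np.ndarray:
        arr = self.params[name]
        return arr.reshape(-1, *arr.shape[2:])

    def theta_bar(self) -> dict:
        """Componentwise posterior mean of all parameters and random effects."""
        out = {name: self.flat(name).mean(axis=0) for name in self.params}
        out["b"] = self.b_mean
        return out

    def scalar_names(self) -> list[str]:
        names = []
        for name, arr in self.params.items():
            if arr.ndim == 2:
                names.append(name)
            else:
                names.extend(f"{name}[{i}]" for i in range(arr.shape[2]))
        return names

    def scalar_draws(self) -> dict:
        """name -> (chains, kept) for every scalar component."""
        out = {}
        for name, arr in self.params.items():
            if arr.ndim == 2:
                out[name] = arr
            else:
                for i in range(arr.shape[2]):
                    out[f"{name}[{i}]"] = arr[:, :, i]
        return out

    def to_csv(self, path) -> None:
        cols = {name: d.reshape(-1) for name, d in self.scalar_draws().items()}
        df = pd.DataFrame(cols)
        df.insert(0, "chain", np.repeat(np.arange(self.n_chains), self.n_kept))
        df.insert(1, "draw", np.tile(np.arange(self.n_kept), self.n_chains))
        df["cond_loglik"] = self.cond_loglik.reshape(-1)
        df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# vectorized likelihood cache
# ---------------------------------------------------------------------------

_N_PANELS = 7
_QUAD_ORDER = 15
_WGRID_STEP = 0.05  # months; global grid for the weighted-kernel convolution


class _ModelCache:
    """Per-dataset precomputation for fast likelihood evaluation.

    For every subject the cumulative hazard uses a fixed 15-point
    Gauss–Legendre rule on 7 equal panels of [0, T_i]; all spline designs at
    the nodes and at T_i are precomputed.  Every association functional is
    linear in (beta + b_i), so only small matrix products remain per
    likelihood evaluation.
    """

    def __init__(self, dataset: TrialDataset, structure: AssociationStructure,
                 ncs: NcsSpec, baseline: BaselineSplineSpec,
                 n_panels: int = _N_PANELS, quad_order: int = _QUAD_ORDER):
        from numpy.polynomial.legendre import leggauss
        self.structure = structure
        self.ncs = ncs
        self.baseline = baseline
        surv = dataset.survival
        long = dataset.longitudinal

        # longitudinal pieces
        order = {sid: i for i, sid in enumerate(surv["subject_id"])}
        self.n = len(surv)
        self.y = long["sqrt_cd4"].to_numpy(dtype=float)
        self.X = value_design(long["time_months"].to_numpy(dtype=float), ncs)
        self.obs_subject = np.array([order[s] for s in long["subject_id"]])
        self.n_obs_per = np.bincount(self.obs_subject, minlength=self.n)
        self.n_obs = self.y.size
        self.p_re = self.X.shape[1]

        # survival pieces
        self.T = surv["time_months"].to_numpy(dtype=float)
        self.delta = surv["event"].to_numpy(dtype=int)
        self.covw = surv[["arm", "age", "gender"]].to_numpy(dtype=float)
        gl_x, gl_w = leggauss(quad_order)
        edges = np.linspace(0.0, 1.0, n_panels + 1)
        a, b = edges[:-1], edges[1:]
        unit_nodes = (0.5 * (a + b)[:, None] + 0.5 * (b - a)[:, None] * gl_x).ravel()
        unit_wts = (0.5 * (b - a)[:, None] * np.broadcast_to(gl_w, (n_panels, quad_order))).ravel()
        self.nodes = self.T[:, None] * unit_nodes[None, :]           # (n, J)
        self.qw = self.T[:, None] * unit_wts[None, :]                # (n, J)
        J = self.nodes.shape[1]
        flat = self.nodes.ravel()
        self.Bk_nodes = bspline_basis(np.minimum(flat, baseline.boundary_knots[1]),
                                      baseline).reshape(self.n, J, -1)
        self.Bk_T = bspline_basis(np.minimum(self.T, baseline.boundary_knots[1]),
                                  baseline)
        self.n_k = self.Bk_T.shape[1]

        self.t_max = dataset.t_max
        tag = structure.tag
        self.A2_nodes = self.A2_T = None
        if tag == "current_value":
            self.A_nodes = value_design(flat, ncs).reshape(self.n, J, -1)
            self.A_T = value_design(self.T, ncs)
        elif tag == "slopes":
            self.A_nodes = value_design(flat, ncs).reshape(self.n, J, -1)
            self.A_T = value_design(self.T, ncs)
            self.A2_nodes = slope_design(flat, ncs).reshape(self.n, J, -1)
            self.A2_T = slope_design(self.T, ncs)
        elif tag == "cumulative":
            self.A_nodes = area_design(flat, ncs).reshape(self.n, J, -1)
            self.A_T = area_design(self.T, ncs)
        else:  # weighted_cumulative: convolution on a shared uniform grid
            t_end = float(max(self.T.max(), 1.0))
            G = int(np.ceil(t_end / _WGRID_STEP)) + 1
            self.wgrid = np.linspace(0.0, t_end, G)
            self.wgrid_design = value_design(self.wgrid, ncs)        # (G, p)
            # linear-interpolation bookkeeping for nodes and event times
            self._prep_interp()
            self.set_sigma_w(structure.weight.sigma_w)

    # -- weighted structure helpers ----------------------------------------
    def _prep_interp(self):
        du = self.wgrid[1] - self.wgrid[0]

        def locate(x):
            idx = np.clip((x / du).astype(int), 0, self.wgrid.size - 2)
            frac = (x - self.wgrid[idx]) / du
            return idx, frac

        self._nodes_loc = locate(self.nodes.ravel())
        self._T_loc = locate(self.T)

    def set_sigma_w(self, sigma_w: float) -> None:
        """Recompute the weighted-area design rows for a new kernel scale."""
        w = WeightSpec(sigma_w, self.t_max)
        du = self.wgrid[1] - self.wgrid[0]
        kern = weight_fn(self.wgrid, w)
        p = self.wgrid_design.shape[1]
        V = np.empty((self.wgrid.size, p))
        for j in range(p):
            col = self.wgrid_design[:, j]
            conv = np.convolve(kern, col)[:self.wgrid.size] * du
            conv -= 0.5 * du * (kern * col[0] + kern[0] * col)
            conv[0] = 0.0
            V[:, j] = conv
        self._V = V
        idx, frac = self._nodes_loc
        An = V[idx] * (1 - frac)[:, None] + V[idx + 1] * frac[:, None]
        self.A_nodes = An.reshape(self.n, -1, p)
        idx, frac = self._T_loc
        self.A_T = V[idx] * (1 - frac)[:, None] + V[idx + 1] * frac[:, None]
        self.sigma_w = sigma_w

    # -- likelihood pieces --------------------------------------------------
    def long_loglik_subjects(self, beta, b, sigma2) -> np.ndarray:
        coef = beta[None, :] + b                       # (n, p)
        mu = np.einsum("op,op->o", self.X, coef[self.obs_subject])
        r = self.y - mu
        ssr = np.bincount(self.obs_subject, weights=r * r, minlength=self.n)
        return -0.5 * (self.n_obs_per * np.log(2 * np.pi * sigma2) + ssr / sigma2)

    def long_ssr(self, beta, b) -> float:
        coef = beta[None, :] + b
        mu = np.einsum("op,op->o", self.X, coef[self.obs_subject])
        r = self.y - mu
        return float(r @ r)

    def surv_loglik_subjects(self, beta, b, gamma, alpha1, alpha2, k) -> np.ndarray:
        coef = beta[None, :] + b                       # (n, p)
        eta_n = (self.Bk_nodes @ k
                 + (self.covw @ gamma)[:, None]
                 + alpha1 * np.einsum("njp,np->nj", self.A_nodes, coef))
        eta_T = (self.Bk_T @ k + self.covw @ gamma
                 + alpha1 * np.einsum("np,np->n", self.A_T, coef))
        if alpha2 is not None and self.A2_nodes is not None:
            eta_n += alpha2 * np.einsum("njp,np->nj", self.A2_nodes, coef)
            eta_T += alpha2 * np.einsum("np,np->n", self.A2_T, coef)
        H = np.einsum("nj,nj->n", self.qw, np.exp(np.clip(eta_n, -700, 700)))
        return self.delta * eta_T - H


# ---------------------------------------------------------------------------
# initialization
# ---------------------------------------------------------------------------

def initialize(dataset: TrialDataset, structure: AssociationStructure, *,
               ncs: NcsSpec, baseline: BaselineSplineSpec) -> dict:
    """Crude but finite starting state: least-squares longitudinal pass,
    person-time exponential fit for gamma, flat crude-rate baseline, alpha=0."""
    long = dataset.longitudinal
    times = long["time_months"].to_numpy(dtype=float)
    if np.unique(times).size < 3:
        raise DataError("need at least 3 distinct measurement times to place the spline")
    y = long["sqrt_cd4"].to_numpy(dtype=float)
    X = value_design(times, ncs)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    sigma2 = float(max(resid @ resid / max(y.size - X.shape[1], 1), 1e-4))

    # per-subject curves for a D guess
    coefs = []
    for sid, grp in long.groupby("subject_id"):
        if len(grp) < X.shape[1]:
            continue
        Xi = value_design(grp["time_months"].to_numpy(dtype=float), ncs)
        ci, *_ = np.linalg.lstsq(Xi, grp["sqrt_cd4"].to_numpy(dtype=float), rcond=None)
        coefs.append(ci - beta)
    if len(coefs) >= 10:
        D0 = np.atleast_2d(np.cov(np.array(coefs).T))
        w_, V = np.linalg.eigh(D0)
        D0 = (V * np.clip(w_, 0.05, None)) @ V.T
    else:
        D0 = np.eye(X.shape[1])

    surv = dataset.survival
    events = int(surv["event"].sum())
    months = float(surv["time_months"].sum())
    if events > 0:
        import statsmodels.api as sm
        Xg = sm.add_constant(surv[["arm", "age", "gender"]].to_numpy(dtype=float))
        try:
            fit = sm.GLM(surv["event"].to_numpy(), Xg,
                         family=sm.families.Poisson(),
                         offset=np.log(np.maximum(surv["time_months"], 1e-6))).fit()
            gamma = tuple(fit.params[1:4])
            k_level = float(fit.params[0])
        except Exception:  # pragma: no cover - singular designs
            gamma = (0.0, 0.0, 0.0)
            k_level = np.log(events / months)
    else:
        logger.warning("no events observed; gamma and k start at prior means")
        gamma = (0.0, 0.0, 0.0)
        k_level = 0.0

    from .splines import n_baseline_coefs
    state = {
        "beta": np.asarray(beta, dtype=float),
        "sigma2_eps": sigma2,
        "D": D0,
        "gamma": np.asarray(gamma, dtype=float),
        "alpha1": 0.0,
        "alpha2": 0.0 if structure.tag == "slopes" else None,
        "k": np.full(n_baseline_coefs(baseline), k_level, dtype=float),
        "b": np.zeros((dataset.n_subjects, X.shape[1])),
    }
    if structure.tag == "weighted_cumulative":
        state["sigma_w"] = structure.weight.sigma_w
    return state


# ---------------------------------------------------------------------------
# adaptive random-walk kernels
# ---------------------------------------------------------------------------

class AdaptiveRWBlock:
    """Random-walk Metropolis block with Robbins–Monro scale adaptation and
    empirical proposal covariance (Haario-style), frozen after adaptation."""

    def __init__(self, dim: int, target: float = 0.234, init_scale: float = 0.1):
        self.dim = dim
        self.target = target
        self.log_scale = np.log(init_scale)
        self.mean = np.zeros(dim)
        self.m2 = np.eye(dim) * 1e-4
        self.count = 0
        self.chol = np.eye(dim)
        self.frozen = False

    def propose(self, x: np.ndarray, rng) -> np.ndarray:
        return x + np.exp(self.log_scale) * (self.chol @ rng.standard_normal(self.dim))

    def adapt(self, x: np.ndarray, accept_prob: float) -> None:
        if self.frozen:
            return
        self.count += 1
        g = (self.count + 10.0) ** -0.6
        self.log_scale += g * (accept_prob - self.target)
        d = x - self.mean
        self.mean += d / self.count
        self.m2 += np.outer(d, x - self.mean)
        if self.count >= 50 and self.count % 50 == 0:
            cov = self.m2 / (self.count - 1) + 1e-8 * np.eye(self.dim)
            self.chol = np.linalg.cholesky(cov)

    def freeze(self) -> None:
        self.frozen = True


class AdaptiveScalar:
    """Scalar random-walk step with Robbins–Monro adaptation."""

    def __init__(self, target: float = 0.44, init_scale: float = 0.1):
        self.target = target
        self.log_scale = np.log(init_scale)
        self.count = 0
        self.frozen = False

    @property
    def scale(self) -> float:
        return float(np.exp(self.log_scale))

    def adapt(self, accept_prob: float) -> None:
        if self.frozen:
            return
        self.count += 1
        g = (self.count + 10.0) ** -0.6
        self.log_scale += g * (accept_prob - self.target)

    def freeze(self) -> None:
        self.frozen = True


# ---------------------------------------------------------------------------
# the sampler
# ---------------------------------------------------------------------------

def _halfcauchy_logpdf(x: float, scale: float) -> float:
    if x <= 0:
        return -np.inf
    return float(np.log(2.0 / (np.pi * scale)) - np.log1p((x / scale) ** 2))


def _corr_from_offdiag(r: np.ndarray, p: int) -> np.ndarray:
    R = np.eye(p)
    iu = np.triu_indices(p, 1)
    R[iu] = r
    R[(iu[1], iu[0])] = r
    return R


def _k_prior_loglik(k: np.ndarray, priors: PriorSpec) -> float:
    lp = float(-0.5 * np.sum(k ** 2) / priors.k_sd ** 2)
    if priors.k_rw1_sd is not None:
        d = np.diff(k)
        lp += float(-0.5 * np.sum(d ** 2) / priors.k_rw1_sd ** 2)
    return lp


class _Chain:
    def __init__(self, cache: _ModelCache, priors: PriorSpec,
                 settings: McmcSettings, state: dict, rng,
                 likelihood: str, fixed: frozenset):
        self.c = cache
        self.priors = priors
        self.st = settings
        self.rng = rng
        self.likelihood = likelihood  # "full" | "longitudinal" | "none"
        self.fixed = fixed
        self.state = {k: (np.array(v, dtype=float, copy=True) if isinstance(v, np.ndarray)
                          else v) for k, v in state.items()}
        p = cache.p_re
        self.p = p
        self.has_slopes = cache.structure.tag == "slopes"
        self.has_weight = cache.structure.tag == "weighted_cumulative"
        # D decomposition: scales + correlations
        D = np.asarray(self.state["D"])
        self.scales = np.sqrt(np.diag(D))
        self.R = D / np.outer(self.scales, self.scales)
        self._refresh_D()
        # kernels
        self.k_beta = AdaptiveRWBlock(p, settings.target_accept_block, 0.05)
        na = 4 + (1 if self.has_slopes else 0)
        self.k_ga = AdaptiveRWBlock(na, settings.target_accept_block, 0.05)
        self.k_k = AdaptiveRWBlock(cache.n_k, settings.target_accept_block, 0.1)
        self.k_b = np.full(cache.n, np.log(0.5))       # per-subject log scales
        self.k_b_frozen = False
        self.k_scales = [AdaptiveScalar(settings.target_accept_scalar, 0.2)
                         for _ in range(p)]
        self.k_corr = [AdaptiveScalar(settings.target_accept_scalar, 0.1)
                       for _ in range(p * (p - 1) // 2)]
        self.k_sw = AdaptiveScalar(settings.target_accept_scalar, 0.2)
        self.k_shift = [AdaptiveScalar(settings.target_accept_scalar, 0.1)
                        for _ in range(p)]
        self._acc = {}
        # caches of current per-subject logliks
        self._sync()

    # -- current log-density pieces ----------------------------------------
    def _surv_subjects(self, beta=None, b=None, gamma=None, alpha1=None,
                       alpha2="keep", k=None) -> np.ndarray:
        if self.likelihood != "full":
            return np.zeros(self.c.n)
        s = self.state
        a2 = s["alpha2"] if alpha2 == "keep" else alpha2
        return self.c.surv_loglik_subjects(
            s["beta"] if beta is None else beta,
            s["b"] if b is None else b,
            s["gamma"] if gamma is None else gamma,
            s["alpha1"] if alpha1 is None else alpha1,
            a2,
            s["k"] if k is None else k)

    def _long_subjects(self, beta=None, b=None) -> np.ndarray:
        if self.likelihood == "none":
            return np.zeros(self.c.n)
        s = self.state
        return self.c.long_loglik_subjects(
            s["beta"] if beta is None else beta,
            s["b"] if b is None else b,
            s["sigma2_eps"])

    def _b_prior_subjects(self, b=None) -> np.ndarray:
        b = self.state["b"] if b is None else b
        z = np.linalg.solve(self.Lchol, b.T)
        quad = np.einsum("pn,pn->n", z, z)
        return -0.5 * (quad + self.p * np.log(2 * np.pi) + self.logdetD)

    def _refresh_D(self) -> None:
        D = np.outer(self.scales, self.scales) * self.R
        self.state["D"] = D
        self.Lchol = np.linalg.cholesky(D)
        self.logdetD = 2.0 * float(np.sum(np.log(np.diag(self.Lchol))))

    def _sync(self) -> None:
        self.cur_long = self._long_subjects()
        self.cur_surv = self._surv_subjects()
        self.cur_bprior = self._b_prior_subjects()
        if not np.isfinite(self.cur_long.sum() + self.cur_surv.sum()
                           + self.cur_bprior.sum()):
            raise InitializationError("non-finite posterior at the initial state")

    # -- block updates ------------------------------------------------------
    def _coef_prior(self, x) -> float:
        return float(-0.5 * np.sum(np.asarray(x) ** 2) / self.priors.coef_sd ** 2)

    def update_beta(self) -> None:
        if "beta" in self.fixed:
            return
        s = self.state
        prop = self.k_beta.propose(s["beta"], self.rng)
        new_long = self._long_subjects(beta=prop)
        new_surv = self._surv_subjects(beta=prop)
        delta = (new_long.sum() + new_surv.sum() + self._coef_prior(prop)
                 - self.cur_long.sum() - self.cur_surv.sum()
                 - self._coef_prior(s["beta"]))
        ap = float(np.exp(min(delta, 0.0))) if np.isfinite(delta) else 0.0
        if self.rng.random() < ap:
            s["beta"] = prop
            self.cur_long, self.cur_surv = new_long, new_surv
        self.k_beta.adapt(s["beta"], ap)
        self._acc["beta"] = self._acc.get("beta", 0) + ap

    def update_b(self) -> None:
        if "b" in self.fixed:
            return
        s = self.state
        b = s["b"]
        z = self.rng.standard_normal(b.shape)
        step = np.exp(self.k_b)[:, None] * (z @ self.Lchol.T)
        prop = b + step
        new_long = self._long_subjects(b=prop)
        new_surv = self._surv_subjects(b=prop)
        new_bp = self._b_prior_subjects(b=prop)
        delta = (new_long + new_surv + new_bp
                 - self.cur_long - self.cur_surv - self.cur_bprior)
        ap = np.exp(np.minimum(delta, 0.0))
        ap[~np.isfinite(delta)] = 0.0
        acc = self.rng.random(self.c.n) < ap
        b[acc] = prop[acc]
        self.cur_long[acc] = new_long[acc]
        self.cur_surv[acc] = new_surv[acc]
        self.cur_bprior[acc] = new_bp[acc]
        if not self.k_b_frozen:
            self.k_b += 0.05 * (ap - self.st.target_accept_block)
        self._acc["b"] = self._acc.get("b", 0) + float(ap.mean())

    def update_recenter(self) -> None:
        """Translation move along the beta/b ridge: beta_j += d, b[:, j] -= d.

        Both likelihood factors depend on beta and b only through their sum,
        so the Metropolis ratio involves just the beta prior and the
        random-effects prior — a cheap move that decorrelates the fixed
        effects from the random-effect means."""
        if "beta" in self.fixed or "b" in self.fixed:
            return
        s = self.state
        for j, kern in enumerate(self.k_shift):
            d = kern.scale * self.rng.standard_normal()
            beta_p = s["beta"].copy()
            beta_p[j] += d
            b_p = s["b"].copy()
            b_p[:, j] -= d
            new_bp = self._b_prior_subjects(b=b_p)
            delta = (new_bp.sum() + self._coef_prior(beta_p)
                     - self.cur_bprior.sum() - self._coef_prior(s["beta"]))
            ap = float(np.exp(min(delta, 0.0))) if np.isfinite(delta) else 0.0
            if self.rng.random() < ap:
                s["beta"], s["b"] = beta_p, b_p
                self.cur_bprior = new_bp
            kern.adapt(ap)

    def update_gamma_alpha(self) -> None:
        if self.likelihood != "full" or "gamma_alpha" in self.fixed:
            return
        s = self.state
        cur = np.concatenate([s["gamma"], [s["alpha1"]],
                              [s["alpha2"]] if self.has_slopes else []])
        prop = self.k_ga.propose(cur, self.rng)
        gamma_p, a1_p = prop[:3], prop[3]
        a2_p = prop[4] if self.has_slopes else None
        new_surv = self._surv_subjects(gamma=gamma_p, alpha1=a1_p, alpha2=a2_p)
        delta = (new_surv.sum() + self._coef_prior(prop)
                 - self.cur_surv.sum() - self._coef_prior(cur))
        ap = float(np.exp(min(delta, 0.0))) if np.isfinite(delta) else 0.0
        if self.rng.random() < ap:
            s["gamma"], s["alpha1"] = gamma_p, float(a1_p)
            if self.has_slopes:
                s["alpha2"] = float(a2_p)
            self.cur_surv = new_surv
            cur = prop
        self.k_ga.adapt(cur, ap)
        self._acc["gamma_alpha"] = self._acc.get("gamma_alpha", 0) + ap

    def update_k(self) -> None:
        if self.likelihood != "full" or "k" in self.fixed:
            return
        s = self.state
        prop = self.k_k.propose(s["k"], self.rng)
        new_surv = self._surv_subjects(k=prop)
        delta = (new_surv.sum() + _k_prior_loglik(prop, self.priors)
                 - self.cur_surv.sum() - _k_prior_loglik(s["k"], self.priors))
        ap = float(np.exp(min(delta, 0.0))) if np.isfinite(delta) else 0.0
        if self.rng.random() < ap:
            s["k"] = prop
            self.cur_surv = new_surv
        self.k_k.adapt(s["k"], ap)
        self._acc["k"] = self._acc.get("k", 0) + ap

    def update_sigma2(self) -> None:
        if self.likelihood == "none" or "sigma2_eps" in self.fixed:
            return
        s = self.state
        ssr = self.c.long_ssr(s["beta"], s["b"])
        a = self.priors.sigma2_eps_a + 0.5 * self.c.n_obs
        bb = self.priors.sigma2_eps_b + 0.5 * ssr
        s["sigma2_eps"] = float(bb / self.rng.gamma(a))
        self.cur_long = self._long_subjects()

    def update_D(self) -> None:
        if "D" in self.fixed:
            return
        cur_bp_sum = self.cur_bprior.sum()
        # scales on the log scale
        for j, kern in enumerate(self.k_scales):
            prop = self.scales.copy()
            prop[j] = self.scales[j] * np.exp(kern.scale * self.rng.standard_normal())
            old = self.scales[j]
            lp_old = _halfcauchy_logpdf(old, self.priors.re_scale_cauchy) + np.log(old)
            lp_new = _halfcauchy_logpdf(prop[j], self.priors.re_scale_cauchy) + np.log(prop[j])
            self.scales = prop
            self._refresh_D()
            new_bp = self._b_prior_subjects()
            delta = new_bp.sum() + lp_new - cur_bp_sum - lp_old
            ap = float(np.exp(min(delta, 0.0))) if np.isfinite(delta) else 0.0
            if self.rng.random() < ap:
                self.cur_bprior = new_bp
                cur_bp_sum = new_bp.sum()
            else:
                self.scales[j] = old
                self._refresh_D()
            kern.adapt(ap)
        # correlations, uniform prior over PD matrices
        iu = np.triu_indices(self.p, 1)
        for idx, kern in enumerate(self.k_corr):
            r = self.R[iu][idx]
            r_new = r + kern.scale * self.rng.standard_normal()
            offs = self.R[iu].copy()
            offs[idx] = r_new
            R_new = _corr_from_offdiag(offs, self.p)
            ok = abs(r_new) < 1 and np.all(np.linalg.eigvalsh(R_new) > 1e-10)
            if ok:
                R_old = self.R
                self.R = R_new
                self._refresh_D()
                new_bp = self._b_prior_subjects()
                delta = new_bp.sum() - cur_bp_sum
                ap = float(np.exp(min(delta, 0.0))) if np.isfinite(delta) else 0.0
                if self.rng.random() < ap:
                    self.cur_bprior = new_bp
                    cur_bp_sum = new_bp.sum()
                else:
                    self.R = R_old
                    self._refresh_D()
            else:
                ap = 0.0
            kern.adapt(ap)

    def update_sigma_w(self) -> None:
        if (not self.has_weight or self.likelihood != "full"
                or "sigma_w" in self.fixed):
            return
        s = self.state
        cur = s["sigma_w"]
        mu0 = np.log(self.c.t_max / 4.0)
        prop = float(np.exp(np.log(cur) + self.k_sw.scale * self.rng.standard_normal()))
        lp_old = -0.5 * ((np.log(cur) - mu0) / self.priors.log_sigma_w_sd) ** 2
        lp_new = -0.5 * ((np.log(prop) - mu0) / self.priors.log_sigma_w_sd) ** 2
        old_surv_sum = self.cur_surv.sum()
        self.c.set_sigma_w(prop)
        new_surv = self._surv_subjects()
        delta = new_surv.sum() + lp_new - old_surv_sum - lp_old
        ap = float(np.exp(min(delta, 0.0))) if np.isfinite(delta) else 0.0
        if self.rng.random() < ap:
            s["sigma_w"] = prop
            self.cur_surv = new_surv
        else:
            self.c.set_sigma_w(cur)
        self.k_sw.adapt(ap)
        self._acc["sigma_w"] = self._acc.get("sigma_w", 0) + ap

    def sweep(self) -> None:
        self.update_beta()
        self.update_b()
        self.update_recenter()
        self.update_gamma_alpha()
        self.update_k()
        self.update_sigma2()
        self.update_D()
        self.update_sigma_w()

    def freeze(self) -> None:
        for kern in ([self.k_beta, self.k_ga, self.k_k, self.k_sw]
                     + self.k_scales + self.k_corr + self.k_shift):
            kern.freeze()
        self.k_b_frozen = True


def fit_joint_model(dataset: TrialDataset, structure: AssociationStructure,
                    priors: PriorSpec = PriorSpec(),
                    settings: McmcSettings = McmcSettings(), *,
                    ncs: Optional[NcsSpec] = None,
                    baseline: Optional[BaselineSplineSpec] = None,
                    init_state: Optional[dict] = None,
                    likelihood: str = "full",
                    fixed: frozenset = frozenset(),
                    store_random_effects: bool = False) -> PosteriorDraws:
    """Fit the joint model; reproducible given ``settings.seed``.

    ``likelihood`` can be "full", "longitudinal" (survival factor removed,
    for conjugate cross-checks) or "none" (prior-only sampling); ``fixed``
    names blocks to hold at their initial values.
    """
    if ncs is None:
        ncs = dataset.meta.get("ncs") or NcsSpec.from_times(
            dataset.longitudinal["time_months"].to_numpy(dtype=float))
    if baseline is None:
        ev = dataset.survival.loc[dataset.survival["event"] == 1, "time_months"]
        baseline = dataset.meta.get("baseline") or \
            BaselineSplineSpec.from_event_times(ev.to_numpy(dtype=float), dataset.t_max)
    if structure.tag == "weighted_cumulative" and structure.weight is None:
        structure = AssociationStructure(
            "weighted_cumulative", WeightSpec(dataset.t_max / 4.0, dataset.t_max))

    cache = _ModelCache(dataset, structure, ncs, baseline)
    base_state = init_state or initialize(dataset, structure, ncs=ncs,
                                          baseline=baseline)

    ss = np.random.SeedSequence(settings.seed)
    chain_seeds = ss.spawn(settings.n_chains)
    n_kept = settings.n_iter // settings.thin
    p = cache.p_re

    param_store: dict[str, np.ndarray] = {
        "beta": np.empty((settings.n_chains, n_kept, p)),
        "sigma2_eps": np.empty((settings.n_chains, n_kept)),
        "re_scales": np.empty((settings.n_chains, n_kept, p)),
        "re_corr": np.empty((settings.n_chains, n_kept, p * (p - 1) // 2)),
        "gamma": np.empty((settings.n_chains, n_kept, 3)),
        "alpha1": np.empty((settings.n_chains, n_kept)),
        "k": np.empty((settings.n_chains, n_kept, cache.n_k)),
    }
    if structure.tag == "slopes":
        param_store["alpha2"] = np.empty((settings.n_chains, n_kept))
    if structure.tag == "weighted_cumulative":
        param_store["sigma_w"] = np.empty((settings.n_chains, n_kept))
    if store_random_effects:
        param_store["b"] = np.empty((settings.n_chains, n_kept, cache.n * p))
    subject_ll = np.empty((settings.n_chains, n_kept, cache.n))
    cond_ll = np.empty((settings.n_chains, n_kept))
    b_mean = np.zeros((cache.n, p))
    iu = np.triu_indices(p, 1)

    for ci in range(settings.n_chains):
        rng = np.random.default_rng(chain_seeds[ci])
        st0 = {key: (v.copy() if isinstance(v, np.ndarray) else v)
               for key, v in base_state.items()}
        if ci > 0:  # overdispersed starts
            st0["beta"] = st0["beta"] + 0.1 * rng.standard_normal(p)
        if structure.tag == "weighted_cumulative":
            cache.set_sigma_w(st0.get("sigma_w", structure.weight.sigma_w))
        chain = _Chain(cache, priors, settings, st0, rng, likelihood, fixed)
        for _ in range(settings.n_adapt):
            chain.sweep()
        chain.freeze()
        for _ in range(settings.n_burnin):
            chain.sweep()
        kept = 0
        for it in range(settings.n_iter):
            chain.sweep()
            if (it + 1) % 100 == 0 and logger.isEnabledFor(logging.DEBUG):
                total_so_far = settings.n_adapt + settings.n_burnin + it + 1
                logger.debug("chain %d iter %d block acceptance: %s", ci, it + 1,
                             {kk: round(v / total_so_far, 3)
                              for kk, v in chain._acc.items()})
            if (it + 1) % settings.thin:
                continue
            s = chain.state
            param_store["beta"][ci, kept] = s["beta"]
            param_store["sigma2_eps"][ci, kept] = s["sigma2_eps"]
            param_store["re_scales"][ci, kept] = chain.scales
            param_store["re_corr"][ci, kept] = chain.R[iu]
            param_store["gamma"][ci, kept] = s["gamma"]
            param_store["alpha1"][ci, kept] = s["alpha1"]
            param_store["k"][ci, kept] = s["k"]
            if "alpha2" in param_store:
                param_store["alpha2"][ci, kept] = s["alpha2"]
            if "sigma_w" in param_store:
                param_store["sigma_w"][ci, kept] = s["sigma_w"]
            if store_random_effects:
                param_store["b"][ci, kept] = s["b"].ravel()
            sl = chain.cur_long + chain.cur_surv
            subject_ll[ci, kept] = sl
            cond_ll[ci, kept] = sl.sum()
            b_mean += s["b"]
            kept += 1
        total = settings.n_adapt + settings.n_burnin + settings.n_iter
        for name, tot in chain._acc.items():
            rate = tot / total
            if not 0.05 <= rate <= 0.95:
                logger.warning("chain %d block %s acceptance rate %.3f outside [0.05, 0.95]",
                               ci, name, rate)
        logger.info("chain %d done; acceptance rates: %s", ci,
                    {kk: round(v / total, 3) for kk, v in chain._acc.items()})

    b_mean /= settings.n_chains * n_kept

    def loglik_at(theta: dict) -> tuple[float, np.ndarray]:
        """Conditional (on b) likelihood at an arbitrary parameter point."""
        if structure.tag == "weighted_cumulative":
            cache.set_sigma_w(float(theta["sigma_w"]))
        ll_long = cache.long_loglik_subjects(
            np.asarray(theta["beta"]), np.asarray(theta["b"]),
            float(theta["sigma2_eps"]))
        ll_surv = cache.surv_loglik_subjects(
            np.asarray(theta["beta"]), np.asarray(theta["b"]),
            np.asarray(theta["gamma"]), float(theta["alpha1"]),
            float(theta["alpha2"]) if "alpha2" in theta and theta["alpha2"] is not None else None,
            np.asarray(theta["k"]))
        per = ll_long + ll_surv
        return float(per.sum()), per

    meta = {
        "structure": structure.tag,
        "priors": priors,
        "settings": settings,
        "ncs": ncs,
        "baseline": baseline,
        "likelihood": likelihood,
        "n_subjects": cache.n,
        "seed": settings.seed,
        "dataset_hash": _dataset_hash(dataset),
    }
    return PosteriorDraws(param_store, subject_ll, cond_ll, b_mean,
                          structure.tag, meta, loglik_at)


def _dataset_hash(dataset: TrialDataset) -> str:
    import hashlib
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(
        dataset.longitudinal[["time_months", "sqrt_cd4"]].to_numpy(dtype=float)).tobytes())
    h.update(np.ascontiguousarray(
        dataset.survival[["time_months", "event"]].to_numpy(dtype=float)).tobytes())
    return h.hexdigest()[:16]


# ---------------------------------------------------------------------------
# summaries and diagnostics
# ---------------------------------------------------------------------------

_HR_PARAMS = ("gamma[0]", "gamma[1]", "gamma[2]", "alpha1", "alpha2")
_HR_LABELS = {"gamma[0]": "Integrated therapy", "gamma[1]": "Age",
              "gamma[2]": "Women", "alpha1": "alpha1", "alpha2": "alpha2"}


def summarize(draws: PosteriorDraws, transform=np.exp) -> pd.DataFrame:
    """Posterior summary table; log-hazard coefficients additionally reported
    as hazard ratios with transformed 2.5/97.5% quantiles."""
    rows = []
    for name, arr in draws.scalar_draws().items():
        flat = arr.reshape(-1)
        lo, hi = np.quantile(flat, [0.025, 0.975])
        row = {
            "param": name,
            "mean": flat.mean(),
            "sd": flat.std(ddof=1),
            "q2.5": lo,
            "q97.5": hi,
        }
        if transform is not None and name in _HR_PARAMS:
            row["label"] = _HR_LABELS.get(name, name)
            row["HR"] = transform(flat.mean())
            row["HR_lo"] = transform(lo)
            row["HR_hi"] = transform(hi)
        rows.append(row)
    return pd.DataFrame(rows)


def _split_chains(arr: np.ndarray) -> np.ndarray:
    c, n = arr.shape
    half = n // 2
    return np.concatenate([arr[:, :half], arr[:, half:2 * half]], axis=0)


def rhat(arr: np.ndarray, split: bool = True) -> float:
    """Potential-scale-reduction factor across chains of shape (chains, draws)."""
    x = _split_chains(arr) if split else arr
    m, n = x.shape
    means = x.mean(axis=1)
    W = x.var(axis=1, ddof=1).mean()
    B = n * means.var(ddof=1)
    if W <= 0:
        return 1.0
    var_plus = (n - 1) / n * W + B / n
    return float(np.sqrt(var_plus / W))


def ess(arr: np.ndarray) -> float:
    """Effective sample size via Geyer's initial-positive-sequence estimator."""
    x = arr.reshape(-1) - arr.mean()
    n = x.size
    if np.allclose(x, 0):
        return float(n)
    acf = np.correlate(x, x, mode="full")[n - 1:] / (np.arange(n, 0, -1) * x.var())
    # sum pairs of consecutive autocorrelations while positive
    s = 0.0
    t = 1
    while t + 1 < min(n, 1000):
        pair = acf[t] + acf[t + 1]
        if pair < 0:
            break
        s += pair
        t += 2
    return float(n / (1.0 + 2.0 * s))


def diagnostics(draws: PosteriorDraws) -> pd.DataFrame:
    """Split-chain R-hat and ESS per scalar parameter; flags R-hat > 1.1."""
    rows = []
    single = draws.n_chains == 1
    if single:
        logger.warning("single chain: R-hat omitted")
    for name, arr in draws.scalar_draws().items():
        r = np.nan if single else rhat(arr)
        rows.append({"param": name, "rhat": r, "ess": ess(arr),
                     "flag": (not single) and r > 1.1})
    return pd.DataFrame(rows)
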