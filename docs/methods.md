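# Methods

## The model

`jmassoc` implements a shared-random-effects joint model for a repeatedly
measured biomarker (square-root CD4 count, cells^1/2) and a time-to-event
outcome (death), together with the classical analyses it is usually compared
against.

**Longitudinal sub-model.** The observed marker of subject *i* at time *t*
(months since randomisation) is

    y_i(t) = m_i(t) + eps_i(t),
    m_i(t) = (beta0 + b_i0) + (beta1 + b_i1) B1(t) + (beta2 + b_i2) B2(t),

where (B1, B2) is a natural-cubic-spline (NCS) basis of time with one
interior knot at the pooled median of the observed measurement times and
boundary knots at the minimum and maximum observed measurement time,
`eps ~ N(0, sigma2_eps)` independent, and `b_i ~ N(0, D)` with D an
unstructured 3x3 covariance. The NCS is built from a cubic B-spline basis
with the two natural constraints (zero second derivative at the boundary
knots) imposed by a null-space projection; the column *space*, not a
particular column parameterization, is the contract, and the basis is
continued linearly beyond the boundary knots because event times can exceed
the last measurement time. First derivative and running integral of every
basis column are available in closed form, so the slope and area functionals
below are exact.

**Survival sub-model.** The hazard is a relative-risk model

    h_i(t) = h0(t) exp{gamma1 Arm_i + gamma2 Age_i + gamma3 Gender_i + f_i(t)},

with `log h0(t)` an open-knot B-spline in t (default: cubic, 5 interior
knots at percentiles of the observed event times, support [0, t_max]). The
basis satisfies partition of unity, so the constant is inside its span and
the baseline intercept is absorbed into the coefficient vector k. The
association term `f_i(t)` is one of four functionals of the true trajectory:

| tag                  | f_i(t)                                      |
|----------------------|---------------------------------------------|
| `current_value`      | alpha * m_i(t)                               |
| `slopes`             | alpha1 * m_i(t) + alpha2 * m_i'(t)           |
| `cumulative`         | alpha * Int_0^t m_i(s) ds                    |
| `weighted_cumulative`| alpha * Int_0^t w(t-s) m_i(s) ds             |

The weight kernel is a normal density in elapsed time, truncated and
normalized over `[0, t_max]` (a single, dataset-wide t_max = largest
observed event/censoring time): `w(u) = phi(u/sigma_w) / integral_0^{t_max}
phi(x/sigma_w) dx`. The normalizer deliberately integrates over the fixed
window `[0, t_max]` rather than `[0, t]`; as a consequence the weights at an
early time t need not sum to one over the subject's own history. The kernel
scale sigma_w is estimated from the data (sampled on the log scale).

## Numerics

* Trajectory value/slope/area are exact (closed-form spline algebra).
* The weighted area has no closed form; it uses 15-point Gauss–Legendre
  panels. When the kernel is concentrated (sigma_w < t/10) the panel
  boundaries are graded towards the kernel peak at s = t (offsets
  sigma_w * {0, 1, 2, 4, 8} plus the remainder), which keeps fixed-order
  quadrature accurate down to sigma_w ~ t_max/1000.
* The cumulative hazard uses 15-point Gauss–Legendre panels on [0, T]
  (1 panel for T <= 12 months, 7 panels otherwise in the reference path; the
  sampler always uses 7). Doubling the panel count changes the survival
  log-likelihood of a simulated trial by < 1e-6.
* The sampler's likelihood cache precomputes every spline design at the
  quadrature nodes once per dataset; all four association functionals are
  linear in `beta + b_i`, so each likelihood evaluation is a handful of
  small matrix products. For the weighted structure the inner integral is a
  discrete convolution of the kernel with the basis on a uniform 0.05-month
  grid (linear interpolation to the outer nodes); this grid approximation is
  tested against the reference quadrature path at 0.5% relative tolerance.
* Event-time simulation inverts `H_i(T) = -log U` by bracketing the target
  on a tabulated cumulative hazard (0.02-month trapezoid grid) and solving
  inside the bracketing cell; the sampled distribution matches the
  independently quadrature-integrated `S(t)` to KS distance < 0.02 under all
  four structures.

## Estimation

Posterior sampling is adaptive random-walk Metropolis-within-Gibbs:

* blocked updates with Haario-style empirical proposal covariance for beta,
  (gamma, alpha), and k (target acceptance 0.234);
* all `b_i` proposed simultaneously (vectorized) and accepted per subject;
* a translation move `beta_j += d, b[:, j] -= d` whose Metropolis ratio
  involves only the priors (both likelihood factors depend on beta and b
  through their sum) — this decorrelates fixed effects from the
  random-effect means, the classic slow direction of shared-effect models;
* sigma2_eps drawn exactly from its conditional Inverse-Gamma;
* D parameterized as scales (Half-Cauchy(2.5) priors, log-scale random
  walks) and correlations (uniform over positive-definite matrices,
  random walks with PD rejection);
* log sigma_w by scalar random walk (weighted structure only).

Adaptation (scales and proposal covariances) runs for a dedicated phase and
is frozen before burn-in ends, so collected draws come from a fixed kernel.
Priors: N(0, 10^2) for all regression-type coefficients and baseline spline
coefficients (an optional first-order random-walk shrinkage on k is
available), Inverse-Gamma(0.01, 0.01) for sigma2_eps, and
N(log(t_max/4), 1) for log sigma_w. The emulated study reports no priors or
chain settings; these are package choices and are recorded in each run's
metadata. Defaults: 3 chains, 1,000 adaptation, 1,000 burn-in, 2,000 kept
draws, thin 1. Reported experiments in the test-suite and the acceptance
script use shorter single chains (500/400/1,500) at n = 300, which keeps a
full four-structure comparison under a few minutes on one CPU.

Per kept draw the sampler stores every scalar parameter, the per-subject
conditional (on b) log-likelihood, and running means of the random effects.

## Model comparison

Deviance is `D(theta) = -2 log p(y | theta)` with the constant fixed to 0
and the *conditional-on-random-effects* likelihood (longitudinal + survival
given b, excluding the b prior); `pD = mean posterior deviance - D(theta_bar)`
with theta_bar the componentwise posterior mean including the random
effects, and `DIC = D(theta_bar) + 2 pD`. This is the usual hierarchical
"conditional DIC" focus; the marginal-likelihood alternative is
computationally prohibitive and the choice is recorded here because the
emulated study does not state which was used. LPML is the sum of log CPOs,
each CPO the harmonic mean over draws of the subject's conditional
likelihood, computed with a max-shift in log space. The DIC identity
`DIC = D(theta_bar) + 2 pD` holds to 1e-9 by construction and is asserted,
as is `pD >= 0` on fixtures.

## Synthetic trials

The generator draws complete trials from exactly this generative model with
design defaults emulating a three-point ART-initiation trial cohort:
n = 642, 2:1 allocation to the combined integrated therapy arm, age ~
N(34.2, 8.3^2) truncated at 18 years, 49.7% male, administrative censoring
at 60 months, exponential dropout at 0.045/month (mean follow-up ~18.5
months, ~1,000 person-years per trial). CD4 visits default to 0, 2, 6, 12,
18, 24 months — the source cohort's schedule is not public, so this is a
plausible trial-like cadence, configurable. The trajectory defaults start
at sqrt-CD4 ~ 12 (median CD4 ~ 144 cells/mm^3) rising to ~17 by two years;
the baseline log hazard declines linearly at -0.06/month, and the
per-structure baseline levels are calibrated once so the marginal death
fraction is ~10.7% with the bulk of deaths in the first year. Association
coefficients default to alpha = -0.22 on the current-value scale (HR ~ 0.80
per unit sqrt-CD4) with area/weighted analogues of comparable effect. Arm
affects the hazard directly (gamma1) but not the trajectory, keeping the
covariate-free longitudinal sub-model exactly the generating model; an
arm-effect-on-trajectory variant can be built by overriding the scenario's
trajectory parameters and is a deliberate misspecification stressor.

What the generator does **not** emulate: informative dropout, visit-time
irregularity, interval-censored deaths, measurement below detection limits,
or any trajectory-covariate interaction. Passing tests therefore demonstrate
internal correctness of the machinery under the model's own assumptions, not
robustness to the ways real cohort data violate them.

### Known limitation: weak structure discriminability

Under the calibrated emulation, deaths concentrate in the first 12 months
while the area functional at early t is nearly `t * m_i(0)` — almost
perfectly collinear with the current value — and the flexible B-spline
baseline absorbs any shared time trend. A maximum-likelihood oracle given
the true random effects separates the four structures' survival
log-likelihoods by less than one unit at n = 300 (~32 deaths). DIC
differences between structures on such data are therefore Monte Carlo noise
and the DIC ranking cannot reliably recover the generating structure at
this scale; the structure-selection machinery is exercised and internally
consistent, but its selection-consistency experiment demands either far
more events or a design whose measurements extend across the event-rich
period. This is documented here rather than silently re-tuned away because
the emulation targets (early deaths, ~10.7% mortality, 0–24-month visit
schedule) are the package's stated study conditions.

## Degenerate inputs and tie-breaks

* Datasets must pair every longitudinal subject with exactly one survival
  row, have no measurements after the subject's event/censoring time, and
  use 0/1 event codes; violations raise `DataError` listing offending ids.
* Initialization requires >= 3 distinct measurement times (otherwise the
  spline is unidentifiable); with zero events, gamma and k start at prior
  means and a warning is logged.
* `compare_structures` breaks exact DIC ties by the declared order of the
  fits mapping and refuses to compare fits whose dataset hashes differ.
* The baseline hazard is never evaluated outside its support in the
  reference path; the simulator holds it at the boundary value beyond
  t_max when the censoring horizon exceeds the spline support.
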