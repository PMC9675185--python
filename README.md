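# jmassoc

Joint modelling of longitudinal CD4 count and the risk of death, with
selectable association structures.

## The problem

In HIV/TB cohorts the question is how a repeatedly measured biomarker (CD4
count) relates to the hazard of death. A time-varying Cox model with
last-observation-carried-forward (LOCF) treats the marker as a step function
and as exogenous — both wrong for an endogenous, noisily measured biomarker,
and known to attenuate the estimated association. A joint model instead
links a mixed-effects model for the true marker trajectory `m_i(t)` to a
relative-risk survival model, sharing the subject-level random effects.

The package is for biostatisticians who want to *choose the functional form
of that link* rather than assume it. The longitudinal sub-model is a
natural-cubic-spline mixed model on the square-root CD4 scale,

    y_i(t) = (β₀+b_i0) + (β₁+b_i1)B₁(t) + (β₂+b_i2)B₂(t) + ε_i(t),
    b_i ~ N(0, D),   ε_i(t) ~ N(0, σ²_ε),

and the hazard is

    h_i(t) = h₀(t) exp{γ₁Arm + γ₂Age + γ₃Gender + f_i(t)},
    log h₀(t) = B-spline in t,

with four association structures:
current value `f = α·m_i(t)`; time-dependent slopes
`f = α₁·m_i(t) + α₂·m_i'(t)`; cumulative effect (area)
`f = α·∫₀ᵗ m_i(s)ds`; and weighted cumulative effect
`f = α·∫₀ᵗ ϖ(t−s)m_i(s)ds` with a normalized normal kernel whose scale σ is
estimated from the data. Models are fitted by adaptive
Metropolis-within-Gibbs MCMC, compared by DIC (and LPML), and summarized as
hazard ratios with 95% credible intervals. Classical comparators —
Kaplan–Meier, log-rank, person-years mortality rates, and the LOCF
time-varying Cox model on a counting-process table — are included, as is a
calibrated synthetic trial generator (the real cohort data are restricted),
so the entire pipeline runs out of the box.

## Worked example

```python
from jmassoc import RunConfig, run_pipeline

cfg = RunConfig(out_dir="out", seed=1, scenario="current_value",
                n_subjects=200, structures=("current_value", "cumulative"),
                mcmc=dict(n_chains=2, n_adapt=500, n_burnin=400, n_iter=1000))
bundle = run_pipeline(cfg)
print(bundle["comparison"])
print(bundle["hr_table"][["param", "label", "HR (95% CI)"]])
```

This simulates a 200-subject trial under the current-value structure
(19 deaths, 9.5%), fits two candidate structures, and prints:

```
    structure  n_params  D_at_mean     pD     DIC     LPML  rank
current_value        23    2267.38 270.71 2808.81 -1442.01     1
   cumulative        23    2273.72 267.58 2808.89 -1456.45     2

   param              label      HR (95% CI)
gamma[0] Integrated therapy 1.33 (0.48-3.55)
gamma[1]                Age 0.97 (0.92-1.04)
gamma[2]              Women 0.91 (0.39-2.24)
  alpha1             alpha1 0.83 (0.72-0.96)
```

The DIC-preferred structure here is the generating one; the `alpha1` row
says each unit of square-root CD4 reduces the hazard of death by ~17%
(posterior HR 0.83, 95% CrI 0.72–0.96; the generating value was
HR = exp(−0.22) ≈ 0.80). The LOCF time-varying Cox comparator on the same
data gives HR 0.81 (0.69–0.94) per unit sqrt-CD4 (`bundle["tv_cox"]`).

The same steps are available as shell commands:

```sh
jmassoc simulate --scenario current_value --seed 1 --n-subjects 642 --out data/
jmassoc describe --data data/
jmassoc cox --data data/ --time-varying
jmassoc fit --data data/ --structure cumulative --out fits/
jmassoc run --config config.yaml       # full pipeline
```

## Layout

| module | contents |
|---|---|
| `jmassoc.splines` | NCS basis with exact derivative/integral, baseline B-splines |
| `jmassoc.trajectory` | `m_i(t)` and its slope/area/weighted-area functionals |
| `jmassoc.hazard` | relative-risk model, cumulative hazard, joint likelihood |
| `jmassoc.synthetic_data` | calibrated trial generator (design, covariates, event times) |
| `jmassoc.inference` | adaptive MCMC, posterior container, summaries, diagnostics |
| `jmassoc.model_selection` | deviance, pD, DIC, LPML, structure ranking |
| `jmassoc.comparators` | KM, log-rank, person-years rates, LOCF tv-Cox, attenuation experiment |
| `jmassoc.pipeline` / `jmassoc.cli` | config, IO, end-to-end runs, CLI |

See `docs/methods.md` for the model details, numerical choices, priors, and
known limitations of the synthetic emulation.
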