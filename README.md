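# emadsem

Two-level Bayesian **dynamic structural equation modelling (DSEM)** of
ecological momentary assessment (EMA) data, built for one scientific
question: are between-person differences in ADHD traits associated with
differences in the moment-to-moment coupling of perceived stress and
negative affect, and do those dynamics in turn carry an indirect
(mediated) association with internalising problems?

The package is aimed at researchers in biostatistics and psychiatric
epidemiology who work with intensive longitudinal smartphone data: it
contains the full analysis pipeline (time-gridding, measurement model,
Bayesian estimation, standardised reporting with credible-interval
mediation) **and** a synthetic-study generator that emulates a two-week,
four-prompts-per-day EMA design, so every stage is testable without any
participant data.

## The model

For person *i* at 4-hour grid occasion *t*, observed stress and negative
affect sum scores decompose into a stable person mean and a latent
momentary deviation, and the deviations follow a person-specific bivariate
VAR(1):

```
y_it = mu_i + d_it
d_it = Phi_i d_{i,t-1} + eps_it,   eps_it ~ N(0, Sigma_w)
```

with `Phi_i = [[phi_SS, phi_AS], [phi_SA, phi_AA]]_i` — two inertias
(autoregressions) and two cross-lagged couplings.  The six person-specific
quantities `(mu_S, mu_A, phi_SS, phi_AA, phi_AS, phi_SA)_i` are **random
effects**, regressed on a latent ADHD factor `eta_i` (plus optional
covariates sex / caregiver origin / childhood SES):

```
re_i = alpha + gamma * eta_i + u_i,           u_i ~ N(0, diag(tau^2))
xi_i = beta_0 + beta' re_i + beta_A eta_i + e_i
```

where `xi_i` is a latent internalising factor.  Both factors are measured
by 1-5 Likert items (9 ADHD, 14 internalising, one cross-loading), each
identified by a reference loading fixed at 1.  Indirect (mediation)
effects are per-draw products `gamma_k * beta_k`.  Estimation is a fully
conjugate Gibbs sampler (missing grid states are sampled as unknowns);
convergence is monitored by the Potential Scale Reduction (PSR) with
iteration doubling after first convergence.

## Worked example

```python
from emadsem import (DesignConfig, simulate_dataset, align_dataset,
                     missingness_fraction, DynamicSEM, standardize_draws,
                     make_table)
from emadsem.report import render_text

ds = simulate_dataset(DesignConfig(n_persons=100, seed=5))   # 14-day study
series = align_dataset(ds.ema)                               # 4-hour grid
print(round(missingness_fraction(series), 3))

est = DynamicSEM(max_iterations=2000, min_iterations=2000,
                 check_every=1000, seed=1)
est.fit(series, ds.persons)
table = make_table(est.draws_, standardize_draws(est.draws_, ds.persons),
                   ds.persons)
print(render_text(table.head(6)))
```

This prints `0.539` — the pooled fraction of grid cells that are missing
under a 67%-compliance four-prompt design — and then the first blocks of
the standardised results table from a short demonstration run:

```
Means (M)
  M: Stress                                        5.098 (0.417) [4.309, 5.940]*
  M: Affect                                        6.008 (0.505) [4.996, 7.080]*
Autoregressive effects (AR)
  AR: Stress → Stress                              0.225 (0.018) [0.194, 0.263]*
  AR: Affect → Affect                              0.196 (0.019) [0.158, 0.231]*
Cross-lagged effects (CL)
  CL: Affect → Stress                              0.054 (0.018) [0.019, 0.089]*
  CL: Stress → Affect                              0.130 (0.019) [0.095, 0.167]*
```

Each row is a standardised posterior summary: the point estimate
(posterior median), posterior SD, and the equal-tailed 95% credible
interval; a `*` marks intervals excluding zero.  Here stress inertia
(`AR: Stress → Stress` ≈ 0.22) means a momentary stress elevation carries
about a fifth of itself to the next 4-hour occasion, and the
`CL: Stress → Affect` row is affective stress reactivity — elevated
stress predicting elevated negative affect four hours later.  (With only
100 persons and 2,000 iterations this is a demonstration, not a converged
analysis — the run itself warns about PSR; the generating values were
0.277, 0.183, 0.032 and 0.115, recovered to this precision at full study
scale by `scripts/acceptance.py`.)

A command-line interface wraps the same stages:

```bash
emadsem simulate --n-persons 262 --seed 1 --out data/
emadsem grid data/ema.csv --out gridded/
emadsem cfa data/persons.csv
emadsem fit data/ema.csv data/persons.csv --model baseline --seed 1 --out fit/
emadsem pipeline config.yaml
```

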