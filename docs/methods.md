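# Methods

This note documents the statistical model, the sampler, the synthetic
study generator, and the numerical choices made where the design was
genuinely open.  Nothing here states an empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## 1. The two-level dynamic structural equation model

**Within level.**  Observed stress (4-20) and negative-affect (7-35) sum
scores on an equidistant grid (default spacing 240 min) decompose as
`y_it = mu_i + d_it`.  The latent deviations follow a person-specific
bivariate VAR(1), `d_it = Phi_i d_{i,t-1} + eps_it` with innovation
covariance `Sigma_w` shared across persons (free off-diagonal by default;
a diagonal constraint is available via `sigma_w_diagonal=True`).
Observed slots determine `d_it = y_it - mu_i` exactly — the model places
no measurement error on the momentary sum scores; latent states at
missing slots are unknowns sampled from their full conditionals.

**Between level.**  The six random effects (two means, two
autoregressions, two cross-lagged couplings) are linear in a latent ADHD
factor (plus covariates in the adjusted variant) with independent normal
residuals `tau_k^2`.  Free residual covariances among six random effects
would be weakly identified at a few hundred persons, so the diagonal
structure is the default and only option.  A latent internalising factor
is regressed on the six random effects, the ADHD factor and any
covariates.  Both factors are measured by their 1-5 Likert items treated
as continuous, one reference loading per factor fixed at 1, and a single
configurable cross-loading (default: the fourth ADHD item, the "restless
inside" indicator, loading also on internalising — which factor carries
the primary loading is configurable because the assignment is a
substantive choice, not a statistical one).

**Mediation.**  Indirect ADHD-to-internalising effects are formed inside
every retained draw as the product of the unstandardised a-path
(`gamma_k`) and b-path (`beta_k`), then summarised; they are reported
unstandardised with percentile intervals.  Equal-tailed 2.5/97.5%
credible intervals are used throughout, and "significant" means exactly
that this interval excludes zero — no p-values are computed anywhere.

## 2. Priors and the Gibbs sampler

All location parameters (intercepts, regression weights, loadings,
item intercepts) carry Normal(0, 1e6) priors.  Variances carry the flat
prior p(tau^2) ∝ 1 (the Inverse-Gamma(-1, 0) limit) and `Sigma_w` the
flat improper Inverse-Wishart IW(0, -(p+1)) — the default
"uninformative" priors of the standard Bayesian DSEM software.  The
popular proper alternative IG(eps, eps) was rejected deliberately: its
density ∝ (tau^2)^(-1-eps) piles prior mass at zero exactly where the
likelihood for a weakly identified random-effect variance is flat, which
depresses those variances and in turn inflates the standardised
trait-moderation paths.  The flat priors yield proper posteriors once a
handful of persons (or transitions) inform each component.  Every full
conditional is an exact conjugate draw:

1. missing latent states — per-slot bivariate normal conditionals,
   updated in a checkerboard (even/odd slot) scan, vectorised across
   persons;
2. person VAR coefficients `phi_i` — 4-dimensional normal;
3. person means `mu_i` — bivariate normal (the means enter both sides of
   the transition residuals; the update collects all linear terms);
4. `Sigma_w` — inverse-Wishart;
5. the two factor scores (eta_i, xi_i) — one **joint bivariate** normal
   draw per person (they are coupled through the cross-loading item and
   the structural ADHD path; the joint block mixes the
   direct-versus-mediated direction far better than alternating scalar
   updates);
6. loadings, between-level regressions, variances — normal /
   inverse-gamma.

The internalising equation carries no free structural intercept: with
every item intercept free, the endogenous factor's location would
otherwise be unidentified (the intercept and the item intercepts trade
off along a flat ridge), so it is fixed at 0, the usual convention for
endogenous latent variables; `beta_int[const]` is recorded as the
constant 0.

**Initial states.**  Each person's first latent state has a fixed diffuse
N(0, 100 I) prior rather than the stationary VAR distribution.  A
stationary initial density would make the `phi_i` and `Sigma_w`
conditionals non-conjugate (the stationary covariance depends on both),
so exact conjugacy and a coherent joint model could not both hold; with
~80 slots per person the influence of one initial term is negligible.
The standalone imputation helper (`sample_latent_states`) defaults to the
stationary prior, which is the natural choice when dynamics are known.

**Factor-scale parameter expansion.**  A reference-loading-identified
factor model has a narrow scale ridge (`eta -> c*eta`, loadings `/c`)
that blocks a plain Gibbs sampler: development runs reproducibly
collapsed into a degenerate mode with the factor variance near zero and
loadings of the non-reference items inflated by the reciprocal scale.
The sampler therefore works in the unidentified parametrisation — all
loadings free, standard-normal working priors on loadings, free working
factor variances — and rescales each recorded draw to the reference
metric (`lambda_ref = 1` exactly, with `gamma`, `beta`, `psi` transformed
consistently).  Identified quantities are unaffected by the working-prior
choice up to a weakly informative induced prior on loading ratios
(Cauchy-like, since the common prior scale cancels in the ratio).

**Convergence.**  Two chains (seeds spawned from one `SeedSequence`) run
in lock-step.  Every `check_every` iterations (default 2,500) the
split-free PSR `sqrt(((n-1)/n W + B/n)/W)`, floored at 1, is computed on
the second half of the thinned draws of every monitored parameter.  On
the first pass below 1.05 the completed iteration count is doubled and
the run stops at that target (never beyond `max_iterations`, default
50,000); the first half of each chain is discarded as burn-in and every
10th iteration is retained.  If the threshold is never met the draws are
returned with `converged=False` — there is no silent success.  Identical
configuration and seed give bit-identical draws (PCG64 generators; no
thread-dependent paths).

**Point estimates** are posterior medians (means available via
`summary(point="mean")`).

## 3. Standardisation

Computed per retained draw so intervals propagate:

* within level — autoregressions are scale-free; cross-lagged paths are
  multiplied by the ratio of the person's model-implied stationary SDs
  (from the discrete Lyapunov equation of `Phi_i, Sigma_w`); the
  person-specific standardised values are averaged over persons.  Person
  draws with spectral radius >= 0.999 (possible because the estimator
  imposes no stationarity constraint) are excluded from the average and a
  warning is emitted if they exceed 1%;
* between level — model-implied SDs: `SD(eta) = sqrt(psi_eta)`,
  `Var(re_k) = gamma_k' Sigma_x gamma_k + tau_k^2`, and the internalising
  SD from the full model-implied predictor covariance plus the residual.
  Covariate variances use the sample covariance (SES is z-scored on
  entry; sex and caregiver origin are 0/1 codes).

## 4. The synthetic study generator

The generator emulates a two-week EMA protocol: 262 persons, 14 days,
four prompts per day between 10:00 and 22:00, each answered independently
with probability 0.67.  "Quasi-random" timing is implemented as
stratified sampling — one uniform draw per 3-hour stratum of the 12-hour
window, with a 30-minute minimum gap enforced by redrawing the day —
which matches common EMA practice and guarantees the prompt count.

Person-level traits: latent ADHD ~ N(0,1); covariates drawn from the
emulated cohort's margins (38.7% male, 37.5% non-Swiss primary caregiver,
childhood SES ~ N(49.09, 17.58^2) truncated to [16, 88]).  Items arise
from a continuous linear factor model discretised at fixed thresholds
(-1.5, -0.5, 0.5, 1.5 on the standardised propensity scale); loadings of
0.66 give omega reliabilities near 0.87 (9 items) and 0.92 (14 items).

Structural truths are specified on the **standardised** scale (the scale
on which the analysis reports them) and converted to the raw sum-score
metric through documented scale choices: person-mean distributions
N(9.5, 1.8^2) for stress and N(14.0, 2.2^2) for affect; within-person
stationary SDs 1.8 and 2.6; dynamics random-effect SDs 0.22 (AR), 0.15
and 0.18 (cross-lagged) — values typical of EMA emotion dynamics, and
large enough that person-specific coefficients are distinguishable from
their single-person estimation error, reproducing the order of posterior
precision such a study reports for the trait-moderation paths.
`Sigma_w` is chosen so the latent deviations have unit stationary
variance at the population-mean transition matrix, making raw and
standardised within-person coefficients coincide at the population mean.
The internalising residual makes the latent outcome's model-implied
variance exactly 1.

Momentary responses: each answered prompt observes the latent state of
the 4-hour grid slot it occupies after the "approximately equidistant"
forcing (two prompts in one slot push the later one forward — the same
deterministic rule the gridder applies, so generator and estimator agree
on which state each record measures).  Sum scores are rounded to integers
and clipped to the scale ranges (~2-3% of observations touch a bound);
item columns are a deterministic decomposition of the sum, since the
dynamic model operates on sum scores.

**What the generator does not emulate** — and hence what passing recovery
tests do not show about real data: continuous-time dynamics between
prompts (values are grid-slot states, not interpolations), time-of-day or
weekday structure in either the dynamics or compliance, floor-heavy
skewness of real momentary stress reports beyond the mild clipping,
response styles or careless responding in the questionnaires, and any
model misspecification (the fitted model is the generating model, which
is precisely what a parameter-recovery design requires).

## 5. Time-gridding

Records are assigned to absolute bins `floor((t - origin)/delta)` with
the origin at 10:00 of the first study day, shared across persons so the
day structure stays aligned; bins without a record (including the
overnight stretch) become explicit missing slots, and the grid ends at
the bin containing the person's last record.  Collisions are resolved by
the forward shift described above ("shift", default); "earlier",
"latest" and "mean" are available and logged.  Dropping collisions
instead of shifting raises the pooled missingness of the reference design
from ~54% to ~63%, because at most three of the six daily bins can then
ever be occupied.  A sum score is missing if any constituent item is
missing (no proration).

## 6. Problem sizes and runtimes

The acceptance script and the heavy recovery test simulate the full
design (262 persons, ~82 grid slots, ~54% missing) and fit 2 chains with
`max_iterations=30,000`, `min_iterations=10,000`, checks every 2,500 —
with doubling this typically terminates at 20,000-30,000 iterations and
retains >= 2,000 draws after burn-in and thinning, about 5-10 minutes on
one CPU.  Unit tests use 15-100 persons and a few hundred iterations.
The CFA uses n = 2,000 simulated persons for recovery checks.

## 7. Known limitations

* The estimator fits ordinal trait items as continuous; the resulting
  attenuation is mostly absorbed by the factor metric (standardised
  coefficients are metric-invariant) but a small residual attenuation of
  factor correlations remains.
* Within-level measurement error (e.g. item noise in momentary sum
  scores) is not modelled, matching the analysis model's assumption.
* One lag, two within-person variables, one moderator factor and one
  outcome factor: the sampler is specialised, not a general DSEM engine.
* The direct ADHD path and the mediated paths through weakly separated
  random effects can be strongly correlated a posteriori when the
  random-effect spread is small relative to single-person estimation
  error; credible intervals then widen honestly rather than failing.
* The `two_step` mode (outcome feedback cut from the random-effect and
  factor updates) is for debugging comparisons only; it is not a valid
  posterior for the joint model.
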