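# Methods

## Model structure

Days are indexed `i = 1..D`, day 1 being the first post-release collection
day.  Five parameters can appear: abundance `U` (unmarked adults at
release), daily trap-network capture efficiency `beta0`, daily survival of
the marked cohort `phi` and of the unmarked population `phi_u`, and the
daily recruitment rate `b` (newly emerged or immigrating adults per day).

**Marked cohort (all models).**  The total recaptured is
`m_c ~ Binomial(N, P)` with `P = sum_i p_i`, and the daily split is
`m ~ Multinomial(p/P, m_c)`.  The product collapses to a single multinomial
over the categories {captured day 1, ..., captured day D, never captured},
which is how the likelihood is evaluated.  Parameter vectors with `P > 1`
are invalid; the likelihood returns `-inf` and the sampler rejects the
proposal (no renormalization — the posterior never visits that region in
practice, because the data pin `P` near the observed recapture fraction).

**Capture probabilities.**  The marked cohort is released once and never
replenished, so survival decay applies to it in every model that has a
survival parameter: `p_i = beta0 * phi**i` under MS (no removal) and
`p_i = beta0 * (1-beta0)**(i-1) * phi**i` under MB/MRSU/MRP (removal: a
mosquito must escape trapping on days `1..i-1`).  The unmarked population
is assumed stationary — recruitment balancing mortality — so its capture
probability carries **no** survival factor: `beta0` under M0/MS, and
`beta0 * (1-beta0)**(i-1)` under MB, where trap removal depletes the
population without replacement.  This asymmetry is what drives the
characteristic biases: M0 ignores marked mortality entirely and grossly
overestimates abundance, MS corrects the marked series only and
underestimates, MB corrects both.

**Recruitment models.**  MRSU/MRP describe the unmarked population at day
`i` as latent Poisson survivors `U_i ~ Poisson(U (1-beta0)^{i-1} phi_x^i)`
plus accumulated recruits
`V_i ~ Poisson(b sum_{j<=i} (1-beta0)^{j-1} phi_x^j)`, observed through
binomial thinning `u_i ~ Binomial(U_i + V_i, beta0)`; `phi_x` is `phi`
under MRSU (equal-survival assumption) and `phi_u` under MRP.  A binomial
thinning of a Poisson sum is Poisson, so the latents are marginalized
analytically and never sampled; a truncated-enumeration test verifies the
identity to 10+ significant figures.  MRP adds the pupal-survey likelihood
`n_pupae ~ Binomial(round(tau*U/s), f_a*(1-phi_u))`: at steady state,
pupae maturing over a window of `tau` days balance adult deaths
`(1-phi_u)` of the whole-population abundance `U/s`, and the survey covers
a fraction `f_a` of the area.  This term is what separates `phi_u` from
`phi` and stabilizes `b`.

## Priors and parameterization conventions

`U ~ Gamma(shape 0.001, rate 0.001)` (scale-free), `beta0 ~ Beta(2, 4)`
(mass at low capture efficiencies, as observed in the field),
`phi, phi_u ~ Beta(4, 2)` (mass at high daily survival), and
`b ~ Lognormal(meanlog 10, precision 0.25)`.  The Gamma is (shape, rate)
and the Lognormal is (mean of log, **precision** of log) — the BUGS-dialect
conventions.  The Lognormal prior is only sensible under this reading: it
has log-scale sd `1/sqrt(0.25) = 2`, i.e. a very diffuse prior spanning
roughly `e^6` to `e^14` recruits/day; read as a variance it would be
absurdly tight around `e^10`.

Abundance is treated as continuous inside the Poisson/binomial means
(consistent with its Gamma prior); the pupal-survey binomial size rounds
`tau*U/s` to the nearest integer.  An optional Poisson approximation of the
pupal term (mean `f_a*(1-phi_u)*tau*U/s`) is available for gradient-based
backends; at the usual small success probabilities the two are numerically
indistinguishable (< 0.01 log-units in the tests).

One ambiguity in the source material: the survivor equation for MRP is
written with a symbol distinct from `beta0` in one place; it is read as
`beta0`, consistent with MRSU and with the thinning construction.

## Simulator

The simulator is individual-faithful but drawn at the cohort level: daily
counts are exact binomial draws over the currently alive cohort, so it is
equivalent to simulating every mosquito independently.  Within a day the
order is **survive, then capture**: this is the only ordering whose day-`i`
marked capture probability is exactly `beta0 (1-beta0)^{i-1} phi^i`
(survival enters with exponent `i`, escape from trapping with `i-1`), i.e.
the simulator and the inference models agree *exactly* in their marginal
moments — a property the test suite checks day-by-day against 1,000
replicates.  Recruits arrive as Poisson(`b`) counts at the start of each
day and are exposed to that day's survival and capture, matching the
latent-recruit construction.  The pupal survey draws the collectable count
`Binomial(round(tau*U/s), f_a*(1-phi_u))` and thins it by the search
efficiency `mu`.

Default generator parameters are the reference study conditions: `U=4000`,
`N=2000`, `beta0=0.05`, `phi=0.78`, `phi_u=0.85`, `b=600`, `D=10`, `J=64`,
`f_a=0.1`, `tau=2`, `s=0.5`, `mu=1`.

What the simulator does *not* emulate: spatial structure (traps are
aggregated into one daily network efficiency; `J` is metadata), weather and
seasonality, senescence (survival is age-independent), marking mortality or
marking loss, and multi-cohort releases.  Passing recovery tests therefore
demonstrate correctness of the inference machinery under the models' own
generative assumptions, not robustness to the field phenomena those
assumptions idealize away.

## Sampler

Adaptive random-walk Metropolis on transformed parameters (`log U`,
`log b`, logit probabilities), with the transform Jacobian included in the
target.  Warmup adapts a global step size by Robbins-Monro recursion toward
25% acceptance and the proposal covariance by a Haario-style running
estimate scaled by `2.38^2/d`, which handles the strong `U`-`beta0`
posterior correlation.  Both freeze at the end of warmup, so retained draws
come from a fixed-kernel chain.

**Initialization** is data-informed and overdispersed: `U` starts at a
jittered Lincoln-Petersen estimate (or, when the model uses the pupal
survey, at the pupal-consistent value `n_pupae*s/(tau*f_a*(1-phi0))`),
survival at the Fisher-Ford decay estimate `phi0`, `beta0` at the value
matching the observed recapture fraction, and `b` at the stable-population
heuristic `U*(1-phi0)`.  Pure prior draws are a poor choice here: the
recruitment prior is so diffuse that chains started from it routinely land
in the basin of a spurious local mode (small `U`, implausibly low `phi_u`,
recruitment in the tens of thousands) that sits 10–15 log-units below the
dominant mode and that random-walk moves cannot leave.

**Warmup mode check.**  Even with good starts, roughly one chain in sixty
wandered into that inferior basin during early warmup.  After independent
per-chain warmup, any chain whose end-of-warmup mean log posterior sits
more than 7 units below the best chain's is moved to a jittered copy of the
best chain's state and re-warmed before sampling begins.  The 7-unit gap
cleanly separates within-mode log-posterior fluctuation (~d/2, a few
units) from the mode gap; the intervention touches warmup only and leaves
the sampling kernel and its invariant distribution untouched.  Chains that
all sit in one mode are unaffected.  Residual disagreement still surfaces
through split-chain R-hat.

**Budgets.**  The reference protocol of the original analyses is 3 chains
of 360,000 iterations (320,000 burn-in) under a Gibbs engine; this
package's default is 3 × 20,000 (10,000 burn-in), which on 10-day datasets
yields R-hat ≤ 1.01 and bulk ESS in the hundreds-to-thousands per
parameter.  The full budget remains available through `MCMCConfig`.
Replicate studies in the test suite use 2 × 6,000 (3,000 burn-in) where
only directional contrasts are needed.

**Summaries.**  Pooled mean, median and equal-tailed 95% interval
(linear-interpolation percentiles); rank-normalized split-chain R-hat and
bulk ESS via ArviZ.  `check_convergence` flags R-hat strictly above 1.1
(the threshold itself passes) or ESS below 200 — conventional defaults, as
the original analyses state no criterion.

## Classical estimators

`lincoln_petersen` returns `u_c * N / m_c`.  `fisher_ford` estimates
survival from the least-squares slope of `log m_i` on `i` (days with
`m_i > 0`, at least two required) and abundance as the day-wise average of
`u_i * N * phi_hat^i / m_i`.  The classical literature leaves the
implementation details open; this conventional log-linear variant serves
only as a baseline and as the sampler's initializer, never as an inference
surface.  Survival estimates above 1 (rising captures) are reported with a
warning rather than clipped.

## Numerical choices and degenerate inputs

- All log-densities return `-inf` (never NaN, never raise) outside the
  support; `0 * log 0` terms are handled explicitly.
- `sum(p) = 1` with unrecaptured individuals remaining, a day with
  `p_i = 0` but `m_i > 0`, and `n_pupae > round(tau*U/s)` all score `-inf`.
- MRP requires a pupal count; requesting it on a dataset without one is an
  error at fit time, not at dataset construction.
- Datasets with no recaptures fall back to prior-based initialization.
- Ties in `check_convergence` pass (strict inequality).

## Replication harness problem sizes

`run_study` rows carry posterior mean/median, 95% interval, R-hat, ESS and
a coverage flag against the simulating value (always judged on unrounded
intervals).  Within a replicate all models see the same dataset, so model
contrasts are paired.  The recovery studies shipped in the test suite use
one full-budget fit of all five models on a reference dataset, 20
full-budget MRP replicates for coverage and bias, and 10-replicate paired
contrasts at the reduced budget for the directional findings
(release-number effect on interval width, pupal-search-efficiency effect on
abundance bias, survival-gap effect on MRSU's recruitment bias).
`scripts/acceptance.py` averages 32 full-budget MRP replicates.

## Known limitations

- Single-release, single-cohort designs only; no spatial or distance-to-trap
  modelling; no covariates; no senescence; no overdispersed observation
  models.
- The recruitment models assume a stationary population over the experiment
  window; abundance trends (weather, control interventions) bias them.
- The pupal survey links `phi_u` and `U` through a steady-state argument;
  an imperfect survey (`mu < 1`) that the model treats as complete biases
  abundance, survival and recruitment jointly (the harness quantifies
  this).
- Random-walk Metropolis is adequate for these 2–5 parameter posteriors but
  would need replacing (the backend seam is `make_log_posterior`) for
  extensions with many more parameters.
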