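# mrrbayes

Bayesian estimation of **abundance, survivorship and recruitment** of
mosquito populations from **mark-release-recapture (MRR)** experiments.

In a typical mosquito MRR trial, *N* marked mosquitoes are released into a
wild population and, on each of *D* post-release days, traps across the
study area collect `m_i` marked and `u_i` unmarked mosquitoes.  Mosquito
trials are hard on classical capture-recapture theory: individuals die fast,
capture removes them permanently, recapture rates are 5–10%, and cohorts
(not individuals) are marked.  Deterministic indexes (Lincoln-Petersen,
Fisher-Ford) ignore some or all of mortality, trap removal and recruitment,
and give point estimates without uncertainty.

`mrrbayes` implements a ladder of five hierarchical count models of
increasing realism, an individual-faithful forward simulator for validating
them, an adaptive-Metropolis MCMC engine, and a replication harness for
parameter-recovery studies.  It targets vector-control researchers and
biostatisticians who design or analyze MRR trials for *Aedes*, *Culex* or
*Anopheles* populations.

## The models

All five models share the marked-cohort likelihood
(β₀ = daily trap capture efficiency, φ = marked daily survival):

    m_c ~ Binomial(N, Σᵢ pᵢ),    m ~ Multinomial(p / Σᵢ pᵢ, m_c)

| model | marked capture prob `pᵢ` | unmarked observation model | estimates |
|-------|--------------------------|----------------------------|-----------|
| M0    | β₀                        | `uᵢ ~ Poisson(U β₀)` | U, β₀ |
| MS    | β₀ φⁱ                     | `uᵢ ~ Poisson(U β₀)` | U, β₀, φ |
| MB    | β₀ (1−β₀)^{i−1} φⁱ        | `uᵢ ~ Poisson(U β₀ (1−β₀)^{i−1})` | U, β₀, φ |
| MRSU  | β₀ (1−β₀)^{i−1} φⁱ        | latent survivors/recruits, φᵤ ≡ φ | U, β₀, φ, b |
| MRP   | β₀ (1−β₀)^{i−1} φⁱ        | latent survivors/recruits + pupal survey | U, β₀, φ, φᵤ, b |

M0 and MS are Bayesian counterparts of the Lincoln-Petersen and Fisher-Ford
indexes; MB adds removal of trapped individuals.  The recruitment models
treat the daily unmarked population as latent Poisson counts of surviving
residents `Uᵢ ~ Poisson(U (1−β₀)^{i−1} φ•ⁱ)` plus accumulated recruits
`Vᵢ ~ Poisson(b Σ_{j≤i} (1−β₀)^{j−1} φ•ʲ)` observed through binomial
thinning `uᵢ ~ Binomial(Uᵢ + Vᵢ, β₀)`; the package marginalizes the latents
analytically (a thinned Poisson sum is Poisson).  MRP separates unmarked
from marked survival by adding a pre-release pupal survey,
`n_pupae ~ Binomial(round(τU/s), f_a (1−φᵤ))`, where `f_a` is the surveyed
area fraction, τ the pupal maturation time and `s` the targeted-sex
fraction.

Priors: `U ~ Gamma(0.001, 0.001)`, `β₀ ~ Beta(2, 4)`, `φ, φᵤ ~ Beta(4, 2)`,
`b ~ Lognormal(meanlog 10, precision 0.25)` (i.e. sdlog 2 — see
`docs/methods.md` for parameterization conventions).

## Worked example

```bash
python examples/02_fit_models.py
```

simulates the reference experiment (true abundance 4,000; 2,000 released;
β₀ = 0.05; φ = 0.78; φᵤ = 0.85; b = 600/day; 10 days) and fits three of the
models:

```
classical baselines
  Lincoln-Petersen abundance: 11,326
  Fisher-Ford survival 0.727, abundance 3,057

model M0: abundance 10,890 (95% CI 9,764-12,152)  [convergence: pass]
  beta0     0.015 (0.014-0.017)
model MB: abundance 4,094 (95% CI 3,618-4,703)  [convergence: pass]
  beta0     0.050 (0.043-0.058)
  phi       0.775 (0.746-0.806)
model MRP: abundance 3,190 (95% CI 2,540-3,930)  [convergence: pass]
  beta0     0.059 (0.050-0.069)
  phi       0.754 (0.722-0.784)
  phi_u     0.827 (0.782-0.864)
  b       673.780 (519.255-871.329)
```

M0 ignores mortality and trap removal, so it reads the low recapture rate as
a huge population (~2.7× the truth).  MB corrects for both and lands on the
truth.  MRP additionally separates unmarked survival (0.83 vs true 0.85)
from marked survival (0.75 vs true 0.78) and estimates the recruitment rate
(674 vs true 600/day); on any one simulated experiment its 95% interval can
still miss the true abundance, as here — across replicates it covers it
about nine times in ten (see `examples/03_replication_study.py`).

The other examples cover simulation (`01`), replicate recovery studies
(`03`) and the effect of release numbers on precision (`04`).  The same
functionality is scriptable from the shell:

```bash
mrrbayes simulate --seed 3 --out data.csv
mrrbayes fit --model MRP --data data.csv --seed 4 --out posterior.csv
mrrbayes study --config grid.yaml --seed 5 --out results.csv
```

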