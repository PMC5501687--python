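"""Fit the Bayesian MRR models to a simulated experiment.

Compares the naive constant-capture model (M0, a Bayesian Lincoln-Petersen
counterpart), the removal model (MB) and the full recruitment-plus-pupal
model (MRP) on the same dataset, alongside the classical deterministic
estimators.  The true abundance is 4,000.
"""

from mrrbayes import (
    MCMCConfig,
    SimulationConfig,
    check_convergence,
    fisher_ford,
    fit,
    lincoln_petersen,
    simulate_dataset,
    summarize,
)

dataset = simulate_dataset(SimulationConfig(seed=42))

print("classical baselines")
print(f"  Lincoln-Petersen abundance: {lincoln_petersen(dataset):,.0f}")
phi_hat, ff_abundance = fisher_ford(dataset)
print(f"  Fisher-Ford survival {phi_hat:.3f}, abundance {ff_abundance:,.0f}")
print()

mcmc = MCMCConfig(n_chains=3, n_iter=8000, n_burnin=4000, seed=1)
for model in ("M0", "MB", "MRP"):
    draws = fit(model, dataset, mcmc=mcmc)
    summary = summarize(draws)
    u = summary["U"]
    print(f"model {model}: abundance {u['mean']:,.0f} "
          f"(95% CI {u['q2.5']:,.0f}-{u['q97.5']:,.0f})  "
          f"[{check_convergence(summary)}]")
    for name in summary.parameters:
        if name != "U":
            row = summary[name]
            print(f"  {name:6s} {row['mean']:8.3f} "
                  f"({row['q2.5']:.3f}-{row['q97.5']:.3f})")

# Expected pattern: M0 grossly overestimates the true abundance because it
# ignores mortality and removal of captured mosquitoes; MB and MRP land near
# the truth, and MRP additionally recovers the unmarked survival (0.85) and
# the recruitment rate (600/day).  On any single simulated experiment the
# 95% interval can still miss the truth — across replicates it covers it
# about nine times in ten.
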