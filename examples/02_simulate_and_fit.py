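"""Simulate a heterogeneous genome and recover its parameters.

Draws 300 genes of 500 codons with per-gene lognormal scatter in
nucleotide frequencies, gBGC and fitness (fly-like preset), pools the
counts, fits them by MCMC under the 23-category amino-acid mapping, and
compares the posterior-mean coefficients with the gene-wide mean truths.
"""

import numpy as np

from codonmuse import MCMCSettings, fit, fly_like, simulate_genome

config = fly_like(n_genes=300, codons_per_gene=500)
truth = simulate_genome(config, seed=11)
result = fit(truth.pooled, settings=MCMCSettings(n_iter=12_000), seed=13)

print(f"pooled {truth.pooled.total:,} codons from {config.n_genes} genes")
print(f"max split-R-hat: {result.max_rhat:.3f} (2 chains)")

beta_truth = truth.beta_summary()
print("\nmutational coefficients (estimate vs gene-wide mean):")
for name in ("T", "C", "G"):
    est = result.posterior_mean(f"beta_{name}")
    print(f"  beta_{name}: {est:.3f} vs {beta_truth[name]['mean']:.3f}")

phi_truth = truth.phi_category_mean()
estimates = result.phi_posterior_means()
errors = {
    label: 100 * abs(estimates[label] - phi_truth[label]) / phi_truth[label]
    for label in estimates
}
worst = max(errors, key=errors.get)
print("\nfitness coefficients: median relative error "
      f"{np.median(list(errors.values())):.1f}% "
      f"(worst: {worst} at {errors[worst]:.1f}%)")
print("errors well below 20% mean the pooled fit captures gene-wide averages")
print("despite the per-gene heterogeneity the model itself cannot see.")
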