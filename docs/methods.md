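# Methods

## Model

Codon frequencies are the stationary law of a Moran model with
reversible GTR-like mutation, gBGC and selection, reduced to fixed
differences between species. For codon *I* = *i₁i₂i₃*,

ψ_I ∝ π_{i1} π_{i2} π_{i3} · γ^{(N−1)·#GC(I)} · φ_I^{N−1},

where π are nucleotide stationary frequencies, γ > 0 the gBGC
coefficient acting once per G/C nucleotide, N the Moran population size
and φ_I the raw codon fitness. These primitives are not separately
identifiable from codon counts; the estimable composites are

- β_T = π_T/π_A, β_{C/G} = (π_{C/G}/π_A)·γ^{N−1} (mutational
  coefficients; β_A ≡ 1 because adenine is unaffected by gBGC),
- Φ_I = (φ_I/φ_ATG)^{N−1} (fitness coefficients; Φ_ATG ≡ 1 because
  methionine is single-codon and cannot be confounded with codon usage),

giving ψ_I = β_{i1}β_{i2}β_{i3}·Φ_I / K with K normalizing over the 64
codons. The package verifies algebraically (to 1e−10 on random
primitives) that composing primitives and applying the β/Φ form equals
direct evaluation of the generative form. ψ is always computed in log
space (log-sum-exp normalization), so extreme coefficients cannot
under- or overflow.

A **mapping** partitions the 64 codons into categories sharing one Φ.
The coarsest mapping of interest has 23 categories: one per amino acid
plus one per stop codon, with {ATG} the immutable singleton reference.
Refinement only ever splits single codons out of synonymous families, so
any reachable mapping respects the genetic code. Category counts are
reported *including* the ATG reference throughout; a convention counting
only free coefficients would read one lower (the literature uses both).

## Inference

- **Likelihood.** Multinomial over a species' pooled genome-wide counts
  with cell probabilities ψ(θ). The combinatorial constant is omitted
  from the sampled kernel (it cancels in MCMC and DIC) and restored when
  absolute BIC values are reported. Zero observed counts are retained
  without pseudocounts; ψ_I > 0 always holds for positive parameters.
- **Priors.** Independent Normal(0, σ²) on each free log parameter,
  σ = 2 by default: proper, weakly informative, centered on the
  reference values β = Φ = 1. The posterior is proper for any counts.
- **Sampler.** Componentwise adaptive random-walk Metropolis on the log
  scale. Each parameter contributes a fixed 64-vector to the
  unnormalized log weights (nucleotide multiplicities for β, category
  indicators for Φ), so a componentwise proposal updates the likelihood
  in O(64). Step sizes follow a Robbins–Monro recursion toward 44%
  acceptance during burn-in and are frozen afterwards, preserving
  detailed balance. Defaults: 2 chains × 50,000 sweeps, 50% burn-in,
  thinning 10, all configurable. All randomness is pre-drawn from a
  seeded generator, so a (seed, settings, data) triple reproduces the
  trace bit-for-bit; per-species seeds derive from the global seed plus
  a CRC of the species id, so adding a species never perturbs others.
- **Diagnostics.** Split-R̂ (each chain halved; values below 1, a
  small-sample artifact of the variance ratio, are clipped to 1) and a
  combined-chain effective sample size using Geyer's initial positive
  monotone sequence. Two chains minimum.
- **Identifiability guard.** Mappings with more than 53 fitness
  categories are refused unless forced: with only 63 free frequencies
  and 3 mutational coefficients, simulation shows coefficient sets
  beyond that size are no longer identifiable. The guard is a hard cap
  with an explicit override, not an estimate of the boundary.

## Model expansion

- **Posterior predictive check.** For each posterior draw, a replicate
  count vector of the observed total is simulated from ψ(θ); per codon,
  the 0.05–0.95 quantile interval of replicate frequencies is formed and
  the codon is flagged when its empirical frequency falls outside. The
  per-codon *error* is the fraction of species flagged.

  Checking the same counts that informed the posterior is conservative
  by construction — the interval is centered near the data and widened
  by posterior spread — and measures roughly a 2% flag rate on
  well-specified data here, not the nominal 10%. This conservatism is
  deliberate where the check drives refinement: it suppresses spurious
  splits. The nominal 10% rate of a 90% interval is a statement about
  data *independent* of the fit, and that is how the calibration test
  verifies it: fit one simulated dataset, flag a second dataset drawn
  from the same truth.
- **Refinement.** Starting from the amino-acid mapping: fit every
  species, aggregate errors, and for each synonymous family holding a
  splittable codon with error above 20%, split the family's
  highest-error splittable codon (ties broken lexicographically — the
  choice is arbitrary and documented, and matters only when errors
  saturate). A richer mapping is retained only if a majority of species
  improve DIC by more than 10; otherwise the trajectory stops. Stops are
  labelled `threshold met`, `identifiability cap` or `criterion
  plateau`. Final selection walks each species' DIC sequence with the
  same ΔDIC > 10 parsimony rule and takes the majority choice.
- **Information criteria.** DIC = D̄ + p_D with D = −2·log L (kernel)
  and p_D evaluated at the posterior mean of the log parameters;
  BIC = k·log n − 2·log L̂ at the maximum-posterior retained sample,
  with n the species' total codon count and the multinomial constant
  included.

## Simulator

The generator emulates pooled genome-wide counts arising from many genes
with heterogeneous forces. Per gene, π is perturbed by componentwise
lognormal noise and renormalized, γ^{N−1} by lognormal noise (or, for a
hotspot gene, drawn from a heavier lognormal), and φ by one lognormal
factor per fitness category — so each gene follows the model exactly and
only the pooled mixture is misspecified. Defaults: 500 codons per gene
(optionally lognormal lengths), noise scales σ_π = 0.1, σ_φ = 0.25,
σ_γ = 0.1–0.3.

Two presets stand in for empirical genome data. `fly-like`: AT-rich base
composition (π = .29/.21/.21/.29), γ-power 1.2, homogeneous gBGC, no
hotspots. `human-like`: similar composition, γ-power 1.5, 2% of genes in
recombination hotspots drawing γ-power from lognormal(log 8, 0.5). The
base fitness table assigns each amino-acid category a value reflecting
typical metazoan amino-acid usage relative to methionine (0.25–1.3),
with stop codons near 0.03 (one stop per CDS of ~500 codons). Since N
enters only through γ^{N−1} and (φ/φ_ATG)^{N−1}, presets fix N = 2 and
parameterize the exponentiated quantities directly.

What the simulator does *not* emulate: empirical per-gene length and
expression distributions, the literature's measured gBGC distributions,
linkage of hotspots along chromosomes, polymorphism, or annotation
artifacts in real CDS data. Passing validation therefore shows the
estimator recovers gene-wide averages under lognormal heterogeneity of
the modeled forces — not that real genomes satisfy those distributional
choices.

Validation behavior established by the test suite: on fly-like
simulations (1,000 genes × 500 codons) the median relative error of
posterior-mean fitness coefficients against gene-wide mean truths stays
well below 20%; under the human-like hotspot mixture the pooled
estimates of β_C and β_G sit nearer the per-gene median than the mean
(rare extreme-γ genes drag the mean), while fitness coefficients remain
unbiased.

## Sensitivity analysis

The effect of a coefficient on codon usage is summarized by the Shannon
entropy H(ψ) = −Σ ψ_I log ψ_I (natural log; the measure below is
base-invariant) and the relative difference
RD = |H(ψ⁺) − H(ψ⁻)| / H(ψ) under multiplication of one coefficient by
1 ± δ (δ = 0.10 by default). β_A, although the normalization reference,
is perturbable: its implicit value 1 is temporarily unfixed, since a
β_A perturbation is not equivalent to any combination of the others.

## Downstream statistics

Fitness estimates are analyzed on the natural-log scale with stop codons
excluded from GC regressions (their coefficients reflect termination,
not codon usage). Per species: the OLS slope of log Φ on codon GC
content (0–3) over the 61 sense codons (a grouped-means variant is
available), and the mutational contrast mean(log β_G, log β_C) −
mean(log β_A, log β_T). Cross-species association uses Spearman rank
correlation (average ranks; exact permutation p for n ≤ 9, large-sample
approximation above), computed on Felsenstein's independent contrasts
when a rooted bifurcating phylogeny with branch lengths is supplied —
polytomies are an error, never silently resolved — and on raw values
with an explicit warning otherwise. The CpG/TpG test residualizes log Φ
against the per-species GC line ("expected from GC content"), averages
the residuals of the class's sense codons into one summary per species,
and applies a one-sample Wilcoxon signed-rank test (exact null for
n ≤ 25 without zeros, normal approximation with continuity correction
above). Dinucleotides are classified within codons only (positions 1–2
and 2–3); junction dinucleotides cannot be recovered from codon counts.
Benjamini–Hochberg FDR adjustment is applied across tests.

## Problem sizes and numerical choices

The validation experiment runs at 1,000 genes × 500 codons with
2 × 20,000 MCMC sweeps. Multi-fit test batteries (predictive-interval
calibration, refinement power, DIC selection replicates) use 2 × 8,000
sweeps on totals of 50,000–1,000,000 codons, where the 25-parameter
posterior is well identified and short chains suffice; single-fit tests
use the full defaults. The refinement power experiment uses a moderate
distinct-fitness effect (1.25×) at 50,000 codons per species: a much
stronger effect at large totals saturates every codon of the family at
100% error, after which the lexicographic tie-break, not the signal,
decides the split.

Other conventions: stationary frequencies sum to 1 within 1e−12;
frequency vectors passed to the entropy must sum to 1 within 1e−8; ψ = 0
cells contribute 0 to the entropy and −∞ to the likelihood only in the
impossible limit of non-positive parameters; count tables must carry all
64 codon columns (RNA-style U names are normalized with a warning), and
CDS counting truncates partial trailing codons and skips ambiguous ones,
reporting both.

## Limitations

Per-species fits assume pooled counts are one multinomial draw; real
genomes are mixtures over genes, so estimates are gene-wide averages and
within-genome heterogeneity is invisible. The β coefficients confound
mutation-rate bias with gBGC by design; only their composite is
identifiable from counts. Fitness coefficients can absorb unmodeled
forces (context-dependent mutation, dinucleotide effects) beyond
selection. The refinement search is greedy (one split per family per
round, no merges) and its tie-break is arbitrary under saturation.
Alternative genetic codes are not shipped, and cross-codon dinucleotide
statistics are out of scope.
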