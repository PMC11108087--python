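"""Entropy-based sensitivity of codon usage to each coefficient.

Perturbs every mutational and fitness coefficient by +/-10% and reports
the relative entropy difference RD = |H(psi+) - H(psi-)| / H(psi) of the
stationary distribution.  Mutational biases typically dominate codon
fitnesses by one to two orders of magnitude.
"""

from codonmuse import ModelParameters, sensitivity_table
from codonmuse.simulate import _BASE_CATEGORY_PHI
from codonmuse.genetic_code import amino_acid_mapping

mapping = amino_acid_mapping()
params = ModelParameters(
    mapping=mapping,
    beta={"T": 0.95, "C": 0.75, "G": 0.8},
    phi={l: _BASE_CATEGORY_PHI[l] for l in mapping.free_labels},
)
table = sensitivity_table(params, delta=0.10)

betas = table[table["kind"] == "beta"]
stops = table[table["parameter"].str.startswith("phi_T")]  # phi_TAA/TAG/TGA
sense = table[(table["kind"] == "phi") & ~table["parameter"].str.startswith("phi_T")]

print(table.sort_values("rd", ascending=False).head(6).to_string(
    index=False, float_format="%.5f"))
ratio = betas["rd"].mean() / sense["rd"].mean()
print(f"\nmean RD, mutational coefficients: {betas['rd'].mean():.5f}")
print(f"mean RD, sense-codon fitnesses:   {sense['rd'].mean():.5f}")
print(f"mean RD, stop-codon fitnesses:    {stops['rd'].mean():.6f}")
print(f"-> mutational biases reshape codon usage ~{ratio:.0f}x more strongly")
print("   than individual fitness categories under the same 10% perturbation.")
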