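"""Synthetic genome-wide codon counts with per-gene heterogeneity.

The generator works from population-genetic primitives: nucleotide
stationary frequencies pi, a gBGC selection coefficient gamma acting on
G/C alleles in a Moran population of size N, and raw codon fitnesses
phi.  These compose into the coefficients the estimator infers,

    beta_T = pi_T / pi_A,
    beta_C = (pi_C / pi_A) * gamma^(N-1),
    beta_G = (pi_G / pi_A) * gamma^(N-1),
    Phi_I  = (phi_I / phi_ATG)^(N-1),

and a gene's codon counts are drawn multinomially from the stationary
distribution these coefficients induce.  A genome is a collection of
genes whose primitives scatter lognormally around base values, with an
optional fraction of recombination-hotspot genes drawing gamma^(N-1)
from a much heavier distribution; pooled counts plus a full truth record
(per-gene coefficients and their gene-wide means/medians) are returned.

Because N enters only through gamma^(N-1) and (phi ratio)^(N-1), presets
fix N = 2 and parameterize those exponentiated quantities directly.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from typing import Dict, Optional, Tuple

import numpy as np

from .genetic_code import CODONS, CODON_INDEX, REFERENCE_CODON, amino_acid_mapping
from .inference import CodonCounts
from .model import COMPOSITION, log_stationary_from_arrays

_REF = CODON_INDEX[REFERENCE_CODON]
#: number of G/C nucleotides per codon (exponent of gamma^(N-1) in the
#: generative stationary law)
_GC_COUNT = COMPOSITION[:, 1] + COMPOSITION[:, 2]


@dataclass(frozen=True)
class PopulationPrimitives:
    """Per-gene population-genetic inputs of the generative model."""

    pi: np.ndarray            # (4,) nucleotide frequencies, order A C G T
    gamma: float              # gBGC selection coefficient (> 0)
    N: int                    # Moran population size (>= 2)
    phi_raw: np.ndarray       # (64,) raw codon fitnesses (> 0)

    def __post_init__(self) -> None:
        pi = np.asarray(self.pi, dtype=float)
        phi = np.asarray(self.phi_raw, dtype=float)
        if pi.shape != (4,) or np.any(pi <= 0) or abs(pi.sum() - 1) > 1e-8:
            raise ValueError("pi must be a positive 4-simplex (A, C, G, T)")
        if phi.shape != (64,) or np.any(phi <= 0):
            raise ValueError("phi_raw must be 64 positive reals")
        if self.gamma <= 0 or self.N < 2:
            raise ValueError("gamma must be positive and N >= 2")
        object.__setattr__(self, "pi", pi)
        object.__setattr__(self, "phi_raw", phi)


def compose_coefficients(
    prim: PopulationPrimitives,
) -> Tuple[Dict[str, float], np.ndarray]:
    """Compose primitives into (beta dict with keys T/C/G, per-codon Phi)."""
    pi_a, pi_c, pi_g, pi_t = prim.pi
    if pi_a == 0:
        raise ZeroDivisionError("pi_A must be positive")
    g_pow = prim.gamma ** (prim.N - 1)
    beta = {
        "T": pi_t / pi_a,
        "C": (pi_c / pi_a) * g_pow,
        "G": (pi_g / pi_a) * g_pow,
    }
    phi_ref = prim.phi_raw[_REF]
    if phi_ref == 0:
        raise ZeroDivisionError("phi of ATG must be positive")
    phi = (prim.phi_raw / phi_ref) ** (prim.N - 1)
    return beta, phi


def stationary_from_primitives(prim: PopulationPrimitives) -> np.ndarray:
    """Stationary codon frequencies evaluated directly from the primitives.

    psi_I is proportional to pi_{i1} pi_{i2} pi_{i3} *
    gamma^((N-1) * #GC(I)) * phi_I^(N-1), normalized over the 64 codons.
    This is the generative form the composed-coefficient route must
    reproduce; it serves as the oracle in the equivalence tests.
    """
    log_w = (
        COMPOSITION @ np.log(prim.pi)
        + (prim.N - 1) * _GC_COUNT * np.log(prim.gamma)
        + (prim.N - 1) * np.log(prim.phi_raw)
    )
    w = np.exp(log_w - log_w.max())
    return w / w.sum()


def _composed_log_psi(prim: PopulationPrimitives) -> np.ndarray:
    beta, phi = compose_coefficients(prim)
    log_beta4 = np.log([1.0, beta["C"], beta["G"], beta["T"]])
    return log_stationary_from_arrays(log_beta4, np.log(phi))


@dataclass(frozen=True)
class GeneArchitecture:
    """One gene: its primitives, hotspot status and codon count."""

    primitives: PopulationPrimitives
    codons_per_gene: int
    hotspot: bool = False

    def __post_init__(self) -> None:
        if self.codons_per_gene < 1:
            raise ValueError("codons_per_gene must be >= 1")


def simulate_gene_counts(arch: GeneArchitecture, seed: int = 0) -> CodonCounts:
    """Multinomial codon counts from one gene's stationary distribution."""
    rng = np.random.default_rng(seed)
    psi = np.exp(_composed_log_psi(arch.primitives))
    counts = rng.multinomial(arch.codons_per_gene, psi)
    return CodonCounts(counts=counts, species_id="gene")


@dataclass(frozen=True)
class HeterogeneityConfig:
    """Lognormal noise scales for the per-gene primitives.

    Each scale is the SD of a multiplicative lognormal factor: applied
    per nucleotide for pi (renormalized afterwards), per fitness
    category for phi (so the amino-acid mapping stays well specified at
    the gene level) and to gamma^(N-1) for the gBGC power.
    """

    sigma_pi: float = 0.10
    sigma_phi: float = 0.25
    sigma_gamma: float = 0.10

    def __post_init__(self) -> None:
        for v in (self.sigma_pi, self.sigma_phi, self.sigma_gamma):
            if v < 0:
                raise ValueError("noise scales must be non-negative")


@dataclass(frozen=True)
class LognormalSpec:
    """Lognormal distribution given by the mean and SD of the log."""

    mean_log: float
    sd_log: float

    def __post_init__(self) -> None:
        if self.sd_log < 0:
            raise ValueError("sd_log must be non-negative")


@dataclass(frozen=True)
class GenomeConfig:
    """Full configuration of a pooled-genome simulation."""

    n_genes: int
    base: PopulationPrimitives
    heterogeneity: HeterogeneityConfig = field(default_factory=HeterogeneityConfig)
    codons_per_gene: int = 500
    length_sd_log: float = 0.0  # optional lognormal gene-length spread
    hotspot_fraction: float = 0.0
    hotspot_gamma: Optional[LognormalSpec] = None

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if not 0 <= self.hotspot_fraction <= 1:
            raise ValueError("hotspot_fraction must lie in [0, 1]")
        if self.hotspot_fraction > 0 and self.hotspot_gamma is None:
            raise ValueError("hotspot_fraction > 0 requires a hotspot gamma spec")

    def digest(self) -> str:
        payload = {
            "n_genes": self.n_genes,
            "codons_per_gene": self.codons_per_gene,
            "length_sd_log": self.length_sd_log,
            "hotspot_fraction": self.hotspot_fraction,
            "hotspot_gamma": None
            if self.hotspot_gamma is None
            else [self.hotspot_gamma.mean_log, self.hotspot_gamma.sd_log],
            "heterogeneity": asdict(self.heterogeneity),
            "pi": list(self.base.pi),
            "gamma": self.base.gamma,
            "N": self.base.N,
            "phi_raw": list(self.base.phi_raw),
        }
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:16]


@dataclass(frozen=True)
class SimulationTruth:
    """Pooled counts plus the per-gene composed coefficients that made them."""

    config: GenomeConfig
    seed: int
    config_digest: str
    pooled: CodonCounts
    hotspot_flags: np.ndarray          # (n_genes,) bool
    beta_per_gene: np.ndarray          # (n_genes, 3) columns T, C, G
    phi_per_gene: np.ndarray           # (n_genes, 64) per-codon Phi
    per_gene_counts: Optional[np.ndarray] = None

    def beta_summary(self) -> Dict[str, Dict[str, float]]:
        out = {}
        for j, name in enumerate(("T", "C", "G")):
            col = self.beta_per_gene[:, j]
            out[name] = {"mean": float(col.mean()), "median": float(np.median(col))}
        return out

    def phi_codon_mean(self) -> np.ndarray:
        return self.phi_per_gene.mean(axis=0)

    def phi_codon_median(self) -> np.ndarray:
        return np.median(self.phi_per_gene, axis=0)

    def phi_category_mean(self, mapping=None) -> Dict[str, float]:
        """Gene-wide mean Phi per fitness category (mean of codon means)."""
        mapping = mapping or amino_acid_mapping()
        codon_mean = self.phi_codon_mean()
        return {
            label: float(
                np.mean([codon_mean[CODON_INDEX[c]] for c in codons])
            )
            for label, codons in mapping.categories.items()
        }


def simulate_genome(config: GenomeConfig, seed: int = 0) -> SimulationTruth:
    """Draw per-gene primitives, compose, sample and pool a whole genome."""
    rng = np.random.default_rng(seed)
    het = config.heterogeneity
    base = config.base
    mapping = amino_acid_mapping()
    cat_of = np.array(
        [list(mapping.labels).index(mapping.codon_to_label()[c]) for c in CODONS]
    )
    n_cat = mapping.n_categories

    hotspot = rng.random(config.n_genes) < config.hotspot_fraction
    pooled = np.zeros(64, dtype=np.int64)
    beta_per_gene = np.empty((config.n_genes, 3))
    phi_per_gene = np.empty((config.n_genes, 64))
    keep = config.n_genes <= 2000
    per_gene_counts = np.empty((config.n_genes, 64), dtype=np.int64) if keep else None

    base_gamma_pow = base.gamma ** (base.N - 1)
    for g in range(config.n_genes):
        pi = base.pi * np.exp(het.sigma_pi * rng.standard_normal(4))
        pi = pi / pi.sum()
        if hotspot[g]:
            spec = config.hotspot_gamma
            gamma_pow = np.exp(rng.normal(spec.mean_log, spec.sd_log))
        else:
            gamma_pow = base_gamma_pow * np.exp(
                het.sigma_gamma * rng.standard_normal()
            )
        cat_noise = np.exp(het.sigma_phi * rng.standard_normal(n_cat))
        phi_raw = base.phi_raw * cat_noise[cat_of]
        prim = PopulationPrimitives(
            pi=pi, gamma=gamma_pow, N=2, phi_raw=phi_raw
        )
        beta, phi = compose_coefficients(prim)
        beta_per_gene[g] = (beta["T"], beta["C"], beta["G"])
        phi_per_gene[g] = phi
        length = config.codons_per_gene
        if config.length_sd_log > 0:
            length = max(
                1,
                int(round(length * np.exp(rng.normal(0.0, config.length_sd_log)))),
            )
        psi = np.exp(_composed_log_psi(prim))
        counts = rng.multinomial(length, psi)
        pooled += counts
        if keep:
            per_gene_counts[g] = counts

    return SimulationTruth(
        config=config,
        seed=seed,
        config_digest=config.digest(),
        pooled=CodonCounts(counts=pooled, species_id=f"sim-{seed}"),
        hotspot_flags=hotspot,
        beta_per_gene=beta_per_gene,
        phi_per_gene=phi_per_gene,
        per_gene_counts=per_gene_counts,
    )


# ---------------------------------------------------------------------------
# Presets
# ---------------------------------------------------------------------------

#: Base fitness per amino-acid category relative to methionine, chosen to
#: mirror typical metazoan amino-acid usage; stop codons appear once per
#: CDS and sit orders of magnitude below the sense codons.
_BASE_CATEGORY_PHI: Dict[str, float] = {
    "A": 0.90, "C": 0.45, "D": 1.00, "E": 1.30, "F": 0.85,
    "G": 0.80, "H": 0.55, "I": 1.10, "K": 1.30, "L": 0.75,
    "M": 1.00, "N": 0.80, "P": 0.65, "Q": 0.90, "R": 0.25,
    "S": 0.55, "T": 0.65, "V": 0.75, "W": 0.55, "Y": 0.60,
    "TAA": 0.030, "TAG": 0.025, "TGA": 0.035,
}


def base_phi_raw() -> np.ndarray:
    """(64,) raw fitness vector expanding the base category table."""
    mapping = amino_acid_mapping()
    label_of = mapping.codon_to_label()
    return np.array([_BASE_CATEGORY_PHI[label_of[c]] for c in CODONS])


def fly_like(n_genes: int = 10_000, codons_per_gene: int = 500) -> GenomeConfig:
    """Drosophila-style genome: AT-rich base composition, homogeneous gBGC."""
    base = PopulationPrimitives(
        pi=np.array([0.29, 0.21, 0.21, 0.29]),
        gamma=1.2,
        N=2,
        phi_raw=base_phi_raw(),
    )
    return GenomeConfig(
        n_genes=n_genes,
        base=base,
        codons_per_gene=codons_per_gene,
        heterogeneity=HeterogeneityConfig(
            sigma_pi=0.10, sigma_phi=0.25, sigma_gamma=0.10
        ),
        hotspot_fraction=0.0,
        hotspot_gamma=None,
    )


def human_like(n_genes: int = 20_000, codons_per_gene: int = 500) -> GenomeConfig:
    """Human-style genome: 2% of genes in recombination hotspots with
    much stronger gBGC than the genomic background."""
    base = PopulationPrimitives(
        pi=np.array([0.295, 0.205, 0.205, 0.295]),
        gamma=1.5,
        N=2,
        phi_raw=base_phi_raw(),
    )
    return GenomeConfig(
        n_genes=n_genes,
        base=base,
        codons_per_gene=codons_per_gene,
        heterogeneity=HeterogeneityConfig(
            sigma_pi=0.10, sigma_phi=0.25, sigma_gamma=0.30
        ),
        hotspot_fraction=0.02,
        hotspot_gamma=LognormalSpec(mean_log=np.log(8.0), sd_log=0.5),
    )


PRESETS = {"fly-like": fly_like, "human-like": human_like}
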