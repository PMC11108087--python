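"""Stationary codon frequencies of the Moran mutation-selection-gBGC model.

Each codon I = i1 i2 i3 has stationary frequency

    psi_I = beta_I * Phi_I / K,     beta_I = beta_{i1} beta_{i2} beta_{i3},

where beta_i is the mutational coefficient of nucleotide i (beta_A = 1 by
normalization; beta_C and beta_G absorb GC-biased gene conversion), Phi_I
is the fitness coefficient of the codon's category (Phi_ATG = 1), and K
normalizes the 64 frequencies to 1.  All computation is done in log space.

The module also provides the Shannon entropy of a codon distribution and
the entropy-based sensitivity measure: the relative entropy difference
under a +/-10% perturbation of a single coefficient.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy.special import logsumexp

from .genetic_code import (
    CODONS,
    NUCLEOTIDES,
    FitnessMapping,
    amino_acid_mapping,
)

#: (64, 4) matrix of nucleotide multiplicities per codon, columns A, C, G, T.
COMPOSITION = np.array(
    [[c.count(b) for b in NUCLEOTIDES] for c in CODONS], dtype=float
)

BETA_NAMES = ("beta_T", "beta_C", "beta_G")
_BETA_COLUMN = {"beta_A": 0, "beta_C": 1, "beta_G": 2, "beta_T": 3}


class ParameterDomainError(ValueError):
    """Raised for non-positive or non-finite model parameters."""


def category_indicator(mapping: FitnessMapping) -> np.ndarray:
    """(64, n_categories) one-hot matrix of codon -> category membership."""
    labels = mapping.labels
    col = {l: j for j, l in enumerate(labels)}
    codon_label = mapping.codon_to_label()
    out = np.zeros((64, len(labels)))
    for i, codon in enumerate(CODONS):
        out[i, col[codon_label[codon]]] = 1.0
    return out


@dataclass(frozen=True)
class ModelParameters:
    """Mutational coefficients beta_T/C/G (beta_A = 1) and one Phi per category."""

    mapping: FitnessMapping = field(default_factory=amino_acid_mapping)
    beta: Mapping[str, float] = field(
        default_factory=lambda: {"T": 1.0, "C": 1.0, "G": 1.0}
    )
    phi: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        beta = dict(self.beta)
        if set(beta) != {"T", "C", "G"}:
            raise ParameterDomainError("beta must have exactly the keys T, C, G")
        phi = dict(self.phi)
        ref = self.mapping.reference_label
        phi.setdefault(ref, 1.0)
        for label in self.mapping.labels:
            phi.setdefault(label, 1.0)
        if set(phi) != set(self.mapping.labels):
            extra = set(phi) - set(self.mapping.labels)
            raise ParameterDomainError(f"phi keys not in mapping: {sorted(extra)}")
        for name, value in list(beta.items()) + list(phi.items()):
            if not np.isfinite(value) or value <= 0:
                raise ParameterDomainError(
                    f"parameter {name!r} must be positive and finite, got {value}"
                )
        if abs(phi[ref] - 1.0) > 1e-12:
            raise ParameterDomainError("the reference category Phi must equal 1")
        object.__setattr__(self, "beta", beta)
        object.__setattr__(self, "phi", phi)

    # -- array views ---------------------------------------------------
    def beta_array(self) -> np.ndarray:
        """(4,) array in A, C, G, T order, with beta_A = 1."""
        return np.array([1.0, self.beta["C"], self.beta["G"], self.beta["T"]])

    def phi_array(self) -> np.ndarray:
        """(n_categories,) array in mapping label order."""
        return np.array([self.phi[l] for l in self.mapping.labels])

    def phi_by_codon(self) -> np.ndarray:
        """(64,) array expanding category coefficients to codons."""
        codon_label = self.mapping.codon_to_label()
        return np.array([self.phi[codon_label[c]] for c in CODONS])

    def free_log_vector(self) -> np.ndarray:
        """Free parameters on log scale: log beta_T/C/G then free log Phi."""
        logs = [np.log(self.beta["T"]), np.log(self.beta["C"]), np.log(self.beta["G"])]
        logs += [np.log(self.phi[l]) for l in self.mapping.free_labels]
        return np.array(logs)

    @classmethod
    def from_free_log_vector(
        cls, mapping: FitnessMapping, x: np.ndarray
    ) -> "ModelParameters":
        free = mapping.free_labels
        if x.shape != (3 + len(free),):
            raise ValueError("wrong parameter vector length for mapping")
        beta = {"T": float(np.exp(x[0])), "C": float(np.exp(x[1])), "G": float(np.exp(x[2]))}
        phi = {l: float(np.exp(v)) for l, v in zip(free, x[3:])}
        return cls(mapping=mapping, beta=beta, phi=phi)

    @staticmethod
    def parameter_names(mapping: FitnessMapping) -> tuple:
        return tuple(BETA_NAMES) + tuple(f"phi_{l}" for l in mapping.free_labels)


def log_stationary_from_arrays(
    log_beta4: np.ndarray, log_phi_codon: np.ndarray
) -> np.ndarray:
    """Normalized log psi from log(beta_A..T) and per-codon log Phi."""
    u = COMPOSITION @ log_beta4 + log_phi_codon
    return u - logsumexp(u)


def stationary_distribution(params: ModelParameters) -> np.ndarray:
    """(64,) stationary codon frequencies psi (sums to 1)."""
    log_psi = log_stationary_from_arrays(
        np.log(params.beta_array()), np.log(params.phi_by_codon())
    )
    return np.exp(log_psi)


def stationary_frame(params: ModelParameters):
    """Stationary frequencies as a (codon, frequency) table."""
    import pandas as pd

    return pd.DataFrame({"codon": CODONS, "frequency": stationary_distribution(params)})


def shannon_entropy(psi: np.ndarray) -> float:
    """H = -sum psi log psi in nats; zero entries contribute zero.

    The natural logarithm is used throughout; the sensitivity measure
    below is a ratio of entropies and hence base-invariant.
    """
    psi = np.asarray(psi, dtype=float)
    if np.any(psi < 0):
        raise ParameterDomainError("frequencies must be non-negative")
    if abs(psi.sum() - 1.0) > 1e-8:
        raise ParameterDomainError("frequencies must sum to 1")
    nz = psi[psi > 0]
    return float(-(nz * np.log(nz)).sum())


class UndefinedBaselineError(ZeroDivisionError):
    """Raised when the baseline entropy is zero (point-mass distribution)."""


def sensitivity_relative_difference(
    params: ModelParameters, target: str, delta: float = 0.10
) -> float:
    """Relative entropy difference under a +/-delta perturbation of one coefficient.

    RD = |H(psi+) - H(psi-)| / H(psi), where psi+/- recompute the
    stationary distribution with ``target`` multiplied by (1 + delta)
    and (1 - delta).  ``target`` is one of ``beta_A``, ``beta_T``,
    ``beta_C``, ``beta_G`` or a mapping category label.  beta_A is the
    normalization reference, but it can still be perturbed: its implicit
    value 1 is temporarily set to 1 +/- delta before forming the codon
    products.
    """
    if not 0 < delta < 1:
        raise ValueError("delta must lie in (0, 1)")
    log_beta4 = np.log(params.beta_array())
    log_phi = np.log(params.phi_by_codon())
    baseline = shannon_entropy(np.exp(log_stationary_from_arrays(log_beta4, log_phi)))
    if baseline == 0:
        raise UndefinedBaselineError("baseline entropy is zero")

    def perturbed(factor: float) -> float:
        lb, lp = log_beta4.copy(), log_phi.copy()
        if target in _BETA_COLUMN:
            lb[_BETA_COLUMN[target]] += np.log(factor)
        elif target in params.mapping.labels:
            member = np.array(
                [params.mapping.codon_to_label()[c] == target for c in CODONS]
            )
            lp[member] += np.log(factor)
        else:
            raise KeyError(f"unknown parameter {target!r}")
        return shannon_entropy(np.exp(log_stationary_from_arrays(lb, lp)))

    h_plus = perturbed(1.0 + delta)
    h_minus = perturbed(1.0 - delta)
    return abs(h_plus - h_minus) / baseline


def sensitivity_table(params: ModelParameters, delta: float = 0.10):
    """RD for every beta (including beta_A) and every Phi category."""
    import pandas as pd

    rows = []
    for name in ("beta_A", "beta_T", "beta_C", "beta_G"):
        rows.append(
            {"parameter": name, "kind": "beta",
             "rd": sensitivity_relative_difference(params, name, delta)}
        )
    for label in params.mapping.labels:
        if label == params.mapping.reference_label:
            continue
        rows.append(
            {"parameter": f"phi_{label}", "kind": "phi",
             "rd": sensitivity_relative_difference(params, label, delta)}
        )
    return pd.DataFrame(rows)
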