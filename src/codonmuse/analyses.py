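"""Downstream statistics on fitted coefficients across species.

Covers the GC-content regression of codon fitnesses, the GC-AT
mutational-bias difference, Spearman rank correlation (optionally on
Felsenstein's phylogenetically independent contrasts), the CpG/TpG
Wilcoxon signed-rank tests against the GC-content expectation, and
Benjamini-Hochberg FDR adjustment.

All fitness values are handled on the natural-log scale; stop codons
are excluded from the GC regressions because their coefficients reflect
translation termination rather than codon usage.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import dendropy
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .genetic_code import (
    CODONS,
    CODON_INDEX,
    GeneticCodeTable,
    build_standard_code,
    classify_cpg_tpg,
    codon_nucleotide_counts,
)
from .inference import FitResult

_GC = np.array([codon_nucleotide_counts(c).gc_content for c in CODONS], dtype=float)


class DegenerateTestError(ValueError):
    """Raised when a test statistic is undefined on the given data."""


@dataclass(frozen=True)
class SpeciesEstimates:
    """Log-scale coefficient estimates for one species.

    ``log_beta`` holds the four mutational coefficients with the adenine
    reference fixed at 0; ``log_phi_codon`` expands the per-category
    fitness estimates to all 64 codons, with ATG fixed at 0.
    """

    species_id: str
    log_beta: Mapping[str, float]
    log_phi_codon: np.ndarray
    taxon: Optional[str] = None
    code: GeneticCodeTable = field(default_factory=build_standard_code)

    def __post_init__(self) -> None:
        if set(self.log_beta) != {"A", "C", "G", "T"}:
            raise ValueError("log_beta must have keys A, C, G, T")
        if abs(self.log_beta["A"]) > 1e-12:
            raise ValueError("log beta_A is the reference and must equal 0")
        phi = np.asarray(self.log_phi_codon, dtype=float)
        if phi.shape != (64,):
            raise ValueError("log_phi_codon must be a length-64 vector")
        if abs(phi[CODON_INDEX["ATG"]]) > 1e-12:
            raise ValueError("log Phi of ATG is the reference and must equal 0")
        object.__setattr__(self, "log_phi_codon", phi)

    @classmethod
    def from_fit(
        cls, result: FitResult, taxon: Optional[str] = None
    ) -> "SpeciesEstimates":
        mapping = result.mapping
        mean_log = dict(
            zip(result.summary["parameter"], result.summary["mean_log"])
        )
        label_of = mapping.codon_to_label()
        ref = mapping.reference_label
        phi = np.array(
            [
                0.0 if label_of[c] == ref else mean_log[f"phi_{label_of[c]}"]
                for c in CODONS
            ]
        )
        return cls(
            species_id=result.species_id,
            log_beta={
                "A": 0.0,
                "T": mean_log["beta_T"],
                "C": mean_log["beta_C"],
                "G": mean_log["beta_G"],
            },
            log_phi_codon=phi,
            taxon=taxon,
        )

    def sense_mask(self) -> np.ndarray:
        return np.array([not self.code.is_stop(c) for c in CODONS])


def _gc_fit(est: SpeciesEstimates, grouped: bool) -> Tuple[float, float]:
    """(slope, intercept) of log fitness on codon GC content (sense codons)."""
    mask = est.sense_mask()
    x, y = _GC[mask], est.log_phi_codon[mask]
    if grouped:
        classes = sorted(set(x))
        x = np.array(classes)
        y = np.array([y[_GC[mask] == g].mean() for g in classes])
    if np.ptp(x) == 0:
        raise DegenerateTestError("all GC contents identical; slope undefined")
    slope, intercept = np.polyfit(x, y, 1)
    return float(slope), float(intercept)


def gc_fitness_slope(est: SpeciesEstimates, grouped: bool = False) -> float:
    """OLS slope of log fitness on codon GC content (0-3) over sense codons.

    ``grouped=True`` regresses on the four GC-class means instead of the
    61 per-codon points.
    """
    return _gc_fit(est, grouped)[0]


def mutation_gc_at_difference(est: SpeciesEstimates) -> float:
    """mean(log beta_G, log beta_C) - mean(log beta_A, log beta_T)."""
    b = est.log_beta
    return float((b["G"] + b["C"]) / 2.0 - (b["A"] + b["T"]) / 2.0)


def spearman_correlation(x: Sequence[float], y: Sequence[float]) -> Tuple[float, float]:
    """Spearman rank correlation with average ranks; exact p for n <= 9.

    For n <= 9 the two-sided p-value is computed by exhaustive
    permutation of one variable's ranks; above that the standard
    large-sample approximation is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise ValueError("x and y must be equal-length 1-d arrays with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateTestError("constant input; correlation undefined")
    rx, ry = stats.rankdata(x), stats.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    n = x.size
    if n <= 9:
        observed = abs(rho)
        count = 0
        total = 0
        for perm in itertools.permutations(ry):
            r = np.corrcoef(rx, np.asarray(perm))[0, 1]
            count += abs(r) >= observed - 1e-12
            total += 1
        return rho, count / total
    return rho, float(stats.spearmanr(x, y).pvalue)


def phylogenetic_contrasts(
    tree, tip_values: Mapping[str, float]
) -> np.ndarray:
    """Felsenstein's standardized independent contrasts.

    ``tree`` is a dendropy Tree or a Newick string with branch lengths;
    the tree must be rooted and strictly bifurcating and every tip label
    must appear in ``tip_values``.  Returns the n-1 contrasts
    (x_i - x_j) / sqrt(v_i + v_j) in post-order, where ancestral values
    are variance-weighted means and ancestral branch lengths are
    augmented by v_i v_j / (v_i + v_j).
    """
    if isinstance(tree, str):
        tree = dendropy.Tree.get(data=tree, schema="newick")
    contrasts: List[float] = []
    values: Dict[int, float] = {}
    lengths: Dict[int, float] = {}
    for node in tree.postorder_node_iter():
        edge = node.edge_length
        if node.is_leaf():
            label = node.taxon.label if node.taxon else None
            if label not in tip_values:
                raise ValueError(f"missing value for tip {label!r}")
            if edge is None or edge <= 0:
                raise ValueError(f"tip {label!r} lacks a positive branch length")
            values[id(node)] = float(tip_values[label])
            lengths[id(node)] = float(edge)
            continue
        children = node.child_nodes()
        if len(children) != 2:
            raise ValueError(
                f"non-bifurcating node with {len(children)} children; "
                "resolve the tree before computing contrasts"
            )
        a, b = children
        xa, xb = values[id(a)], values[id(b)]
        va, vb = lengths[id(a)], lengths[id(b)]
        contrasts.append((xa - xb) / np.sqrt(va + vb))
        values[id(node)] = (xa / va + xb / vb) / (1.0 / va + 1.0 / vb)
        base = float(edge) if edge else 0.0
        if edge is not None and edge < 0:
            raise ValueError("negative branch length")
        lengths[id(node)] = base + va * vb / (va + vb)
    return np.array(contrasts)


def slope_difference_table(
    estimates: Sequence[SpeciesEstimates], grouped: bool = False
) -> pd.DataFrame:
    """Per-species GC fitness slope and GC-AT mutational difference."""
    return pd.DataFrame(
        {
            "species": [e.species_id for e in estimates],
            "taxon": [e.taxon for e in estimates],
            "gc_fitness_slope": [gc_fitness_slope(e, grouped) for e in estimates],
            "mutation_gc_at_difference": [
                mutation_gc_at_difference(e) for e in estimates
            ],
        }
    )


def slope_vs_mutation_correlation(
    estimates: Sequence[SpeciesEstimates],
    tree=None,
    grouped: bool = False,
) -> Tuple[float, float]:
    """Spearman correlation of GC fitness slopes against GC-AT mutation biases.

    When a tree is supplied both variables are reduced to independent
    contrasts first; otherwise raw cross-species values are correlated
    and a warning notes the unaccounted phylogenetic non-independence.
    """
    table = slope_difference_table(estimates, grouped)
    if tree is None:
        warnings.warn(
            "no phylogeny supplied; correlating raw species values without "
            "correcting for shared ancestry",
            stacklevel=2,
        )
        return spearman_correlation(
            table["mutation_gc_at_difference"], table["gc_fitness_slope"]
        )
    slopes = dict(zip(table["species"], table["gc_fitness_slope"]))
    diffs = dict(zip(table["species"], table["mutation_gc_at_difference"]))
    cs = phylogenetic_contrasts(tree, slopes)
    cd = phylogenetic_contrasts(tree, diffs)
    return spearman_correlation(cd, cs)


def cpg_tpg_test(
    estimates: Sequence[SpeciesEstimates],
    dinucleotide_class: str,
    alternative: str = "two-sided",
) -> Tuple[np.ndarray, float, float]:
    """Wilcoxon signed-rank test of CpG (or TpG) fitness residuals vs 0.

    Per species, the per-codon log fitnesses are residualized against
    codon GC content (the "expected from GC content" baseline) and the
    residuals of the class's sense codons are averaged into one summary
    per species.  Those summaries are tested against zero with a
    one-sample Wilcoxon signed-rank test (exact null for n <= 25,
    normal approximation with continuity correction above).  Returns
    (per-species residual summaries, statistic, p-value); the direction
    of any effect is the sign of the median summary.
    """
    if dinucleotide_class not in ("CpG", "TpG"):
        raise ValueError("class must be 'CpG' or 'TpG'")
    if len(estimates) < 6:
        raise ValueError("need at least 6 species for a meaningful test")
    summaries = []
    member = np.array([classify_cpg_tpg(c) == dinucleotide_class for c in CODONS])
    for est in estimates:
        slope, intercept = _gc_fit(est, grouped=False)
        mask = est.sense_mask() & member
        resid = est.log_phi_codon[mask] - (slope * _GC[mask] + intercept)
        summaries.append(float(resid.mean()))
    summaries = np.array(summaries)
    if np.allclose(summaries, 0.0):
        raise DegenerateTestError("all residual summaries are zero")
    n = summaries.size
    method = "exact" if n <= 25 and not np.any(summaries == 0.0) else "approx"
    res = stats.wilcoxon(
        summaries, alternative=alternative, method=method, correction=True
    )
    return summaries, float(res.statistic), float(res.pvalue)


def fdr_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
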