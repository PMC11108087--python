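"""Stepwise refinement of the fitness mapping from posterior predictive errors.

Starting from the 23-category amino-acid mapping, each round fits every
species, runs the posterior predictive check, aggregates the per-codon
error (fraction of species whose empirical frequency falls outside the
0.05-0.95 predictive interval) and, for every amino-acid family holding
a splittable codon with error above the threshold (20% by default),
splits out the family's highest-error splittable codon.  Rounds continue
until no codon exceeds the threshold, the identifiability cap would be
exceeded, or the richer mapping fails the DIC acceptance rule
(a richer mapping is kept only when Delta-DIC > 10 for a majority of
species).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .genetic_code import CODONS, CODON_INDEX, FitnessMapping, amino_acid_mapping, split_codon
from .inference import (
    IDENTIFIABILITY_CAP,
    CodonCounts,
    FitResult,
    MCMCSettings,
    aggregate_codon_errors,
    fit,
    posterior_predictive_flags,
)

DIC_ACCEPT_MARGIN = 10.0
ERROR_THRESHOLD = 0.20


def species_seed(global_seed: int, species_id: str) -> int:
    """Deterministic per-species seed; independent of other species."""
    import zlib

    return (int(global_seed) * 100_003 + zlib.crc32(species_id.encode())) % (2**31)


def refinement_round(
    errors: np.ndarray,
    mapping: FitnessMapping,
    threshold: float = ERROR_THRESHOLD,
) -> FitnessMapping:
    """One splitting round; returns the mapping unchanged if converged.

    For each synonymous family that contains at least one splittable
    (non-singleton) codon with error above the threshold, the family's
    highest-error splittable codon gains its own category.  Ties are
    broken lexicographically.
    """
    errors = np.asarray(errors, dtype=float)
    if errors.shape != (64,):
        raise ValueError("errors must be a length-64 vector of fractions")
    code = mapping.code
    splittable = set(mapping.splittable_codons())
    chosen: Dict[str, str] = {}
    for codon in CODONS:
        if codon not in splittable:
            continue
        if errors[CODON_INDEX[codon]] <= threshold:
            continue
        family = code.family_label(codon)
        current = chosen.get(family)
        if current is None or errors[CODON_INDEX[codon]] > errors[CODON_INDEX[current]]:
            chosen[family] = codon  # lexicographic tie-break: strict > keeps earlier
    new_mapping = mapping
    for family in sorted(chosen):
        new_mapping = split_codon(new_mapping, chosen[family])
    return new_mapping


@dataclass(frozen=True)
class RefinementRound:
    """One trajectory element: the mapping, its fits, errors and criteria."""

    mapping: FitnessMapping
    fits: Tuple[FitResult, ...]
    flags: Tuple[np.ndarray, ...]
    errors: np.ndarray  # per-codon fraction of species flagged

    def criteria_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "species": [f.species_id for f in self.fits],
                "bic": [f.bic for f in self.fits],
                "dic": [f.dic for f in self.fits],
            }
        )

    def errors_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"codon": CODONS, "error": self.errors})


@dataclass(frozen=True)
class RefinementTrajectory:
    """Ordered rounds of the refinement, with the reason it stopped."""

    rounds: Tuple[RefinementRound, ...]
    stop_reason: str  # "threshold met" | "identifiability cap" | "criterion plateau"

    @property
    def final_mapping(self) -> FitnessMapping:
        return select_mapping(self).mapping

    def category_counts(self) -> List[int]:
        return [r.mapping.n_categories for r in self.rounds]


def _fit_round(
    mapping: FitnessMapping,
    all_counts: Sequence[CodonCounts],
    settings: MCMCSettings,
    seed: int,
    n_reps: int,
    threshold_interval: Tuple[float, float],
) -> RefinementRound:
    fits, flags = [], []
    for counts in all_counts:
        s = species_seed(seed, counts.species_id)
        result = fit(counts, mapping, settings, seed=s)
        flag = posterior_predictive_flags(
            result.trace, counts, n_reps=n_reps, seed=s + 1,
            interval=threshold_interval,
        )
        fits.append(result)
        flags.append(flag)
    return RefinementRound(
        mapping=mapping,
        fits=tuple(fits),
        flags=tuple(flags),
        errors=aggregate_codon_errors(flags),
    )


def refine(
    all_counts: Sequence[CodonCounts],
    threshold: float = ERROR_THRESHOLD,
    cap: int = IDENTIFIABILITY_CAP,
    settings: Optional[MCMCSettings] = None,
    seed: int = 0,
    n_reps: int = 500,
    max_rounds: int = 30,
    interval: Tuple[float, float] = (0.05, 0.95),
) -> RefinementTrajectory:
    """Iterate fit -> posterior predictive check -> split until convergence."""
    if len(all_counts) == 0:
        raise ValueError("need at least one species")
    settings = settings or MCMCSettings()
    current = _fit_round(
        amino_acid_mapping(), all_counts, settings, seed, n_reps, interval
    )
    rounds: List[RefinementRound] = [current]
    stop_reason = "criterion plateau"
    for _ in range(max_rounds):
        proposed = refinement_round(current.errors, current.mapping, threshold)
        if proposed.n_categories == current.mapping.n_categories:
            stop_reason = "threshold met"
            break
        if proposed.n_categories > cap:
            stop_reason = "identifiability cap"
            break
        # DIC acceptance: fit the richer mapping, keep going only if a
        # majority of species improve by more than the margin.
        nxt = _fit_round(proposed, all_counts, settings, seed, n_reps, interval)
        rounds.append(nxt)
        improved = sum(
            1
            for prev, new in zip(current.fits, nxt.fits)
            if prev.dic - new.dic > DIC_ACCEPT_MARGIN
        )
        if improved <= len(all_counts) / 2:
            stop_reason = "criterion plateau"
            break
        current = nxt
    return RefinementTrajectory(rounds=tuple(rounds), stop_reason=stop_reason)


@dataclass(frozen=True)
class MappingSelection:
    """Consensus mapping plus the per-species round choices behind it."""

    mapping: FitnessMapping
    round_index: int
    per_species: Dict[str, int]


def select_mapping(trajectory: RefinementTrajectory) -> MappingSelection:
    """Choose the final mapping by per-species DIC with the Delta > 10 rule.

    Per species, richer mappings are walked in trajectory order and a
    richer one replaces the current choice only when it improves DIC by
    more than the margin; the consensus is the majority choice across
    species (ties favor the simpler mapping).
    """
    if len(trajectory.rounds) == 0:
        raise ValueError("empty trajectory")
    n_rounds = len(trajectory.rounds)
    species = [f.species_id for f in trajectory.rounds[0].fits]
    per_species: Dict[str, int] = {}
    for i, sp in enumerate(species):
        best = 0
        for r in range(1, n_rounds):
            if (
                trajectory.rounds[best].fits[i].dic
                - trajectory.rounds[r].fits[i].dic
                > DIC_ACCEPT_MARGIN
            ):
                best = r
        per_species[sp] = best
    votes = np.bincount(list(per_species.values()), minlength=n_rounds)
    winner = int(np.argmax(votes))  # argmax takes the first (simplest) on ties
    return MappingSelection(
        mapping=trajectory.rounds[winner].mapping,
        round_index=winner,
        per_species=per_species,
    )
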