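"""Genetic-code tables, codon composition and fitness-category mappings.

The 64 codons are kept in a fixed lexicographic order (A < C < G < T) so
that every array in the package indexes codons the same way.  A
:class:`FitnessMapping` partitions the codons into categories that share a
single fitness coefficient; the coarsest mapping of interest assigns one
category per amino acid plus one per stop codon (23 categories), and
refinement only ever splits single codons out of synonymous families.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Dict, Mapping, Tuple

from Bio.Data import CodonTable

NUCLEOTIDES = "ACGT"
#: Fixed codon order used by every 64-vector in the package.
CODONS: Tuple[str, ...] = tuple(
    "".join(p) for p in itertools.product(NUCLEOTIDES, repeat=3)
)
CODON_INDEX: Dict[str, int] = {c: i for i, c in enumerate(CODONS)}
STOP = "*"
#: The methionine codon; reference for all fitness coefficients.
REFERENCE_CODON = "ATG"


class InvalidCodonError(ValueError):
    """Raised for strings that are not trinucleotides over {A, C, G, T}."""


class CannotSplitError(ValueError):
    """Raised when a codon cannot be split out of its category."""


class ReferenceImmutableError(ValueError):
    """Raised on attempts to alter the ATG reference category."""


def _check_codon(codon: str) -> str:
    if not isinstance(codon, str):
        raise InvalidCodonError(f"codon must be a string, got {type(codon)!r}")
    codon = codon.upper().replace("U", "T")
    if len(codon) != 3 or any(b not in NUCLEOTIDES for b in codon):
        raise InvalidCodonError(f"not a valid DNA codon: {codon!r}")
    return codon


@dataclass(frozen=True)
class GeneticCodeTable:
    """A genetic code: the fixed codon ordering plus codon -> amino acid.

    Amino acids are single letters; stop codons translate to ``"*"``.
    Only the standard code (translation table 1) ships, but the type
    permits alternatives.
    """

    translation: Mapping[str, str]
    name: str = "standard"
    codons: Tuple[str, ...] = CODONS

    def __post_init__(self) -> None:
        if tuple(sorted(self.codons)) != tuple(sorted(CODONS)) or len(
            set(self.codons)
        ) != 64:
            raise ValueError("a genetic code table must cover all 64 codons")
        missing = [c for c in self.codons if c not in self.translation]
        if missing:
            raise ValueError(f"codons without translation: {missing}")

    def amino_acid(self, codon: str) -> str:
        return self.translation[_check_codon(codon)]

    def is_stop(self, codon: str) -> bool:
        return self.amino_acid(codon) == STOP

    @property
    def stop_codons(self) -> Tuple[str, ...]:
        return tuple(c for c in self.codons if self.translation[c] == STOP)

    @property
    def sense_codons(self) -> Tuple[str, ...]:
        return tuple(c for c in self.codons if self.translation[c] != STOP)

    def synonymous_family(self, codon: str) -> Tuple[str, ...]:
        """Codons sharing this codon's translation.

        Stop codons are treated as singleton families: each stop codon
        carries its own coefficient throughout.
        """
        codon = _check_codon(codon)
        aa = self.translation[codon]
        if aa == STOP:
            return (codon,)
        return tuple(c for c in self.codons if self.translation[c] == aa)

    def family_label(self, codon: str) -> str:
        """Label of the synonymous family a codon belongs to."""
        codon = _check_codon(codon)
        aa = self.translation[codon]
        return codon if aa == STOP else aa


def build_standard_code() -> GeneticCodeTable:
    """The standard genetic code (NCBI translation table 1)."""
    table = CodonTable.unambiguous_dna_by_id[1]
    translation = {
        c: table.forward_table.get(c, STOP) for c in CODONS
    }
    return GeneticCodeTable(translation=translation, name="standard")


@dataclass(frozen=True)
class CodonComposition:
    """Nucleotide multiplicities of a codon (n_A + n_C + n_G + n_T = 3)."""

    n_A: int
    n_C: int
    n_G: int
    n_T: int

    def __post_init__(self) -> None:
        if self.n_A + self.n_C + self.n_G + self.n_T != 3:
            raise ValueError("codon composition must sum to 3")

    @property
    def gc_content(self) -> int:
        return self.n_C + self.n_G

    def as_array(self):
        import numpy as np

        return np.array([self.n_A, self.n_C, self.n_G, self.n_T])


def codon_nucleotide_counts(codon: str) -> CodonComposition:
    """Count A/C/G/T occurrences in a codon.

    The composition determines the mutational product
    beta_I = beta_{i1} beta_{i2} beta_{i3}.
    """
    codon = _check_codon(codon)
    return CodonComposition(
        n_A=codon.count("A"),
        n_C=codon.count("C"),
        n_G=codon.count("G"),
        n_T=codon.count("T"),
    )


def classify_cpg_tpg(codon: str) -> str:
    """Classify a codon as ``"CpG"``, ``"TpG"`` or ``"neither"``.

    Only within-codon dinucleotides (positions 1-2 and 2-3) are
    considered; junctions across codon boundaries cannot be recovered
    from codon counts alone.  No 3-mer can contain both CG and TG.
    """
    codon = _check_codon(codon)
    if "CG" in codon:
        return "CpG"
    if "TG" in codon:
        return "TpG"
    return "neither"


@dataclass(frozen=True)
class FitnessMapping:
    """A partition of the 64 codons into fitness categories.

    ``categories`` maps a label to the tuple of codons sharing one
    fitness coefficient.  The reference category is the singleton
    ``{ATG}`` (methionine), whose coefficient is fixed at 1.  Category
    insertion order is meaningful: it fixes the parameter ordering, and
    splits append new singleton categories at the end so existing
    parameter positions never move.
    """

    categories: Mapping[str, Tuple[str, ...]]
    code: GeneticCodeTable = field(default_factory=build_standard_code)

    def __post_init__(self) -> None:
        seen: Dict[str, str] = {}
        for label, codons in self.categories.items():
            if len(codons) == 0:
                raise ValueError(f"empty category {label!r}")
            fams = {self.code.family_label(c) for c in codons}
            if len(fams) > 1:
                raise ValueError(
                    f"category {label!r} spans synonymous families {sorted(fams)}"
                )
            for c in codons:
                if c in seen:
                    raise ValueError(f"codon {c} appears in {seen[c]!r} and {label!r}")
                seen[c] = label
        if len(seen) != 64:
            raise ValueError("categories must jointly cover all 64 codons")
        ref = self.categories.get(self.reference_label)
        if ref is None or tuple(ref) != (REFERENCE_CODON,):
            raise ValueError("the reference category must be the singleton {ATG}")

    @property
    def reference_label(self) -> str:
        for label, codons in self.categories.items():
            if REFERENCE_CODON in codons:
                return label
        raise ValueError("no category contains ATG")  # pragma: no cover

    @property
    def labels(self) -> Tuple[str, ...]:
        return tuple(self.categories)

    @property
    def free_labels(self) -> Tuple[str, ...]:
        """Category labels carrying a free coefficient (reference excluded)."""
        ref = self.reference_label
        return tuple(l for l in self.categories if l != ref)

    @property
    def n_categories(self) -> int:
        return len(self.categories)

    def label_of(self, codon: str) -> str:
        codon = _check_codon(codon)
        for label, codons in self.categories.items():
            if codon in codons:
                return label
        raise KeyError(codon)  # pragma: no cover

    def codon_to_label(self) -> Dict[str, str]:
        return {c: label for label, cs in self.categories.items() for c in cs}

    def category_sizes(self) -> Dict[str, int]:
        return {label: len(cs) for label, cs in self.categories.items()}

    def splittable_codons(self) -> Tuple[str, ...]:
        """Codons sitting in a category of size >= 2."""
        return tuple(
            c
            for label, cs in self.categories.items()
            for c in cs
            if len(cs) >= 2
        )

    # -- serialization -------------------------------------------------
    def to_frame(self):
        import pandas as pd

        mapping = self.codon_to_label()
        return pd.DataFrame(
            {"codon": CODONS, "category": [mapping[c] for c in CODONS]}
        )

    @classmethod
    def from_frame(cls, frame, code: GeneticCodeTable | None = None) -> "FitnessMapping":
        code = code or build_standard_code()
        groups: Dict[str, list] = {}
        for codon, label in zip(frame["codon"], frame["category"]):
            groups.setdefault(str(label), []).append(_check_codon(codon))
        return cls(
            categories={l: tuple(cs) for l, cs in groups.items()}, code=code
        )


def amino_acid_mapping(code: GeneticCodeTable | None = None) -> FitnessMapping:
    """The 23-category mapping: one per amino acid, one per stop codon."""
    code = code or build_standard_code()
    groups: Dict[str, list] = {}
    for codon in code.codons:
        groups.setdefault(code.family_label(codon), []).append(codon)
    ordered = {label: tuple(groups[label]) for label in sorted(groups)}
    return FitnessMapping(categories=ordered, code=code)


def split_codon(mapping: FitnessMapping, codon: str) -> FitnessMapping:
    """Give ``codon`` its own singleton category, leaving all else intact.

    The new category is labelled by the codon string and appended after
    the existing categories.
    """
    codon = _check_codon(codon)
    if codon == REFERENCE_CODON:
        raise ReferenceImmutableError("the ATG reference category cannot be split")
    label = mapping.label_of(codon)
    if len(mapping.categories[label]) < 2:
        raise CannotSplitError(f"codon {codon} is already a singleton category")
    new: Dict[str, Tuple[str, ...]] = {}
    for lab, cs in mapping.categories.items():
        if lab == label:
            new[lab] = tuple(c for c in cs if c != codon)
        else:
            new[lab] = cs
    new[codon] = (codon,)
    return FitnessMapping(categories=new, code=mapping.code)
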