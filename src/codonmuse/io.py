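"""Readers and writers: count tables, CDS codon counting, mappings, traces.

Count tables follow the dialect of genome-wide codon-count databases:
one row per species with a species-id column and all 64 codon columns
(DNA alphabet; RNA-style ``U`` column names are normalized to ``T`` with
a warning).  All formats are plain text and round-trip losslessly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, List, Sequence, Tuple, Union

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq

from .genetic_code import CODONS, FitnessMapping, build_standard_code
from .inference import CodonCounts, FitResult, PosteriorTrace


class SchemaError(ValueError):
    """Raised when a table is missing required columns."""


@dataclass(frozen=True)
class CountTableDialect:
    """Column conventions of a codon count table."""

    delimiter: str = ","
    species_column: str = "species"


# ---------------------------------------------------------------------------
# Codon counting from CDS
# ---------------------------------------------------------------------------

@dataclass
class CodonCountingReport:
    """QC summary of codon counting from coding sequences."""

    n_records: int = 0
    n_codons_counted: int = 0
    n_codons_skipped: int = 0
    truncated_records: List[str] = field(default_factory=list)


_DNA_OK = set("ACGTU")
_IUPAC = set("ACGTURYSWKMBDHVN-")


def count_codons_from_cds(
    records: Union[str, Path, Iterable],
    species_id: str = "species",
) -> Tuple[CodonCounts, CodonCountingReport]:
    """Pool codon counts from CDS records (FASTA path or SeqRecord iterable).

    The reading frame starts at position 1 of each record.  Codons with
    non-ACGT characters are skipped and tallied; records whose length is
    not a multiple of 3 are truncated to the last full codon and
    flagged in the report.
    """
    if isinstance(records, (str, Path)):
        records = SeqIO.parse(str(records), "fasta")
    counts = np.zeros(64, dtype=np.int64)
    index = {c: i for i, c in enumerate(CODONS)}
    report = CodonCountingReport()
    for rec in records:
        seq = str(rec.seq).upper().replace("U", "T")
        if not seq:
            continue
        letters = set(seq)
        if not letters <= _IUPAC:
            raise ValueError(
                f"record {rec.id!r} is not a nucleotide sequence "
                f"(unexpected characters {sorted(letters - _IUPAC)})"
            )
        report.n_records += 1
        if len(seq) % 3:
            report.truncated_records.append(rec.id)
            seq = seq[: len(seq) - len(seq) % 3]
        for i in range(0, len(seq), 3):
            codon = seq[i : i + 3]
            j = index.get(codon)
            if j is None:
                report.n_codons_skipped += 1
            else:
                counts[j] += 1
                report.n_codons_counted += 1
    if report.n_records == 0:
        raise ValueError("no sequence records in input")
    if counts.sum() == 0:
        raise ValueError("no countable codons in input")
    return CodonCounts(counts=counts, species_id=species_id), report


# ---------------------------------------------------------------------------
# Count tables
# ---------------------------------------------------------------------------

def read_counts_table(
    path: Union[str, Path],
    dialect: CountTableDialect = CountTableDialect(),
) -> List[CodonCounts]:
    """Read a per-species codon count table (64 codon columns required)."""
    frame = pd.read_csv(path, sep=dialect.delimiter)
    rename = {}
    for col in frame.columns:
        normalized = col.upper().replace("U", "T")
        if normalized in set(CODONS) and normalized != col:
            rename[col] = normalized
    if rename:
        warnings.warn(
            f"normalized RNA-style codon columns to DNA: {sorted(rename)}",
            stacklevel=2,
        )
        frame = frame.rename(columns=rename)
    missing = [c for c in CODONS if c not in frame.columns]
    if missing:
        raise SchemaError(f"count table is missing codon columns: {missing}")
    if dialect.species_column not in frame.columns:
        raise SchemaError(f"missing species column {dialect.species_column!r}")
    out = []
    for _, row in frame.iterrows():
        vec = row[list(CODONS)].to_numpy()
        if np.any(pd.isna(vec)) or np.any(np.asarray(vec, dtype=float) < 0):
            raise ValueError(f"invalid counts for species {row[dialect.species_column]!r}")
        out.append(
            CodonCounts(
                counts=np.asarray(vec, dtype=np.int64),
                species_id=str(row[dialect.species_column]),
            )
        )
    return out


def write_counts_table(
    all_counts: Sequence[CodonCounts],
    path: Union[str, Path],
    dialect: CountTableDialect = CountTableDialect(),
) -> None:
    rows = [
        {dialect.species_column: c.species_id, **dict(zip(CODONS, c.counts))}
        for c in all_counts
    ]
    pd.DataFrame(rows).to_csv(path, sep=dialect.delimiter, index=False)


# ---------------------------------------------------------------------------
# Mappings, fit summaries, traces
# ---------------------------------------------------------------------------

def write_mapping(mapping: FitnessMapping, path: Union[str, Path]) -> None:
    mapping.to_frame().to_csv(path, sep="\t", index=False)


def read_mapping(path: Union[str, Path]) -> FitnessMapping:
    frame = pd.read_csv(path, sep="\t", dtype=str)
    if not {"codon", "category"} <= set(frame.columns):
        raise SchemaError("mapping table needs 'codon' and 'category' columns")
    return FitnessMapping.from_frame(frame, build_standard_code())


def write_fit_summary(result: FitResult, path: Union[str, Path]) -> None:
    summary = result.summary.copy()
    summary.insert(0, "species", result.species_id)
    summary["bic"] = result.bic
    summary["dic"] = result.dic
    summary.to_csv(path, index=False, float_format="%.10g")


def write_trace(trace: PosteriorTrace, path: Union[str, Path]) -> None:
    """Tabular trace plus a YAML sidecar with seed/settings/mapping digest."""
    path = Path(path)
    trace.to_dataframe().to_csv(path, index=False, float_format="%.17g")
    meta = {
        "seed": trace.seed,
        "n_chains": trace.n_chains,
        "acceptance": [list(map(float, a)) for a in trace.acceptance],
        "settings": {
            "n_iter": trace.settings.n_iter,
            "burn_in_fraction": trace.settings.burn_in_fraction,
            "thin": trace.settings.thin,
            "prior_sigma": trace.settings.prior_sigma,
        },
        "mapping": {
            label: list(codons)
            for label, codons in trace.mapping.categories.items()
        },
    }
    path.with_suffix(path.suffix + ".meta.yaml").write_text(
        yaml.safe_dump(meta, sort_keys=False)
    )


def read_trace_dataframe(path: Union[str, Path]) -> pd.DataFrame:
    return pd.read_csv(path)
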