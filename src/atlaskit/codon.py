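"""Codon usage: genome-based CDS counts and expression-weighted transcriptome usage.

Genome-based usage simply pools codon counts over all annotated coding
sequences.  Transcriptome-based usage weights each transcript's longest-ORF
codon counts by that transcript's FPKM in a library, converts the weighted
sums to percentages per library, and averages the percentage tables across
libraries (unweighted), so every library contributes equally regardless of
its depth.  Aggregating synonymous codons to their amino acids lets the
usage profile be correlated with predicted tRNA gene counts per amino acid.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Data.CodonTable import standard_dna_table
from scipy import stats

from .errors import DimensionError, DomainError, InputError

__all__ = [
    "CODONS",
    "STOP_CODONS",
    "SENSE_CODONS",
    "CodonTable",
    "count_codons",
    "count_codons_cds",
    "to_frequency",
    "transcriptome_usage",
    "aggregate_by_aa",
    "correlate_trna",
    "read_trna_counts",
]

CODONS: tuple[str, ...] = tuple("".join(p) for p in itertools.product("ACGT", repeat=3))
STOP_CODONS: tuple[str, ...] = tuple(sorted(standard_dna_table.stop_codons))
SENSE_CODONS: tuple[str, ...] = tuple(c for c in CODONS if c not in STOP_CODONS)
_AA_OF: dict[str, str] = dict(standard_dna_table.forward_table)  # codon -> one-letter aa

AMINO_ACIDS: tuple[str, ...] = tuple(sorted(set(_AA_OF.values())))
__all__.append("AMINO_ACIDS")


@dataclass
class CodonTable:
    """Counts or frequencies over the 64 codons.

    unit is "count", "per-thousand" (sums to 1000) or "percent" (sums to
    100).  n_excluded tallies codons skipped because they contained N.
    """

    values: pd.Series
    basis: str = "genome"
    unit: str = "count"
    n_excluded: int = 0

    def __post_init__(self) -> None:
        v = self.values.reindex(CODONS, fill_value=0.0).astype(float)
        if (v < 0).any():
            raise InputError("codon table contains negative values")
        self.values = v

    @property
    def total(self) -> float:
        return float(self.values.sum())


def count_codons(sequence: str, record_id: str = "<sequence>") -> tuple[pd.Series, int]:
    """In-frame codon counts for one sequence; returns (counts, n with N skipped)."""
    seq = sequence.strip().upper().replace("U", "T")
    if len(seq) % 3 != 0:
        raise InputError(
            f"record {record_id!r}: length {len(seq)} is not divisible by 3"
        )
    counts = pd.Series(0.0, index=CODONS)
    skipped = 0
    for i in range(0, len(seq), 3):
        codon = seq[i:i + 3]
        if codon in counts.index:
            counts[codon] += 1
        elif "N" in codon:
            skipped += 1
        else:
            raise InputError(f"record {record_id!r}: invalid codon {codon!r}")
    return counts, skipped


def count_codons_cds(
    cds_sequences: Mapping[str, str] | Sequence[str],
    basis: str = "genome",
) -> CodonTable:
    """Pool in-frame codon counts over a set of CDS sequences (frame 0).

    Sequences whose length is not a multiple of 3 raise an error naming the
    record; codons containing N are excluded and tallied.
    """
    if isinstance(cds_sequences, Mapping):
        items = list(cds_sequences.items())
    else:
        items = [(f"seq{i + 1}", s) for i, s in enumerate(cds_sequences)]
    total = pd.Series(0.0, index=CODONS)
    skipped = 0
    for rid, seq in items:
        c, s = count_codons(seq, record_id=rid)
        total += c
        skipped += s
    return CodonTable(values=total, basis=basis, unit="count", n_excluded=skipped)


def orf_codon_counts(
    sequences: Mapping[str, str],
    include_stop: bool = False,
) -> pd.DataFrame:
    """Per-transcript codon counts of each transcript's longest ORF.

    Returns a transcripts x 64 DataFrame.  A transcript with no ORF gets an
    all-zero row.  The terminal stop codon of a complete ORF is excluded by
    default (set include_stop=True to count it); genome-based CDS counting
    via count_codons_cds keeps its stops because an annotated CDS includes
    the stop codon.
    """
    from .composition import longest_orf

    rows: dict[str, pd.Series] = {}
    for tid, seq in sequences.items():
        _, orf_nt = longest_orf(seq)
        if orf_nt and not include_stop and orf_nt[-3:] in STOP_CODONS:
            orf_nt = orf_nt[:-3]
        if orf_nt:
            rows[tid], _ = count_codons(orf_nt, record_id=tid)
        else:
            rows[tid] = pd.Series(0.0, index=CODONS)
    return pd.DataFrame(rows).T.reindex(columns=CODONS, fill_value=0.0)


__all__.append("orf_codon_counts")


_UNIT_TOTALS = {"per-thousand": 1000.0, "percent": 100.0}


def to_frequency(table: CodonTable, unit: str = "per-thousand") -> CodonTable:
    """Convert a count table to per-thousand or percent frequencies."""
    if unit not in _UNIT_TOTALS:
        raise DomainError(f"unit must be one of {sorted(_UNIT_TOTALS)}, got {unit!r}")
    total = table.total
    if total <= 0:
        raise DomainError("cannot normalize an all-zero codon table")
    return CodonTable(
        values=table.values / total * _UNIT_TOTALS[unit],
        basis=table.basis, unit=unit, n_excluded=table.n_excluded,
    )


@dataclass
class TranscriptomeUsage:
    """Per-library percent codon tables, their unweighted mean, and flagged libraries."""

    per_library: pd.DataFrame  # 64 codons x libraries, percent
    mean: CodonTable  # unit percent, basis "transcriptome:mean"
    flagged_libraries: list[str] = field(default_factory=list)


__all__.append("TranscriptomeUsage")


def transcriptome_usage(
    codon_counts: pd.DataFrame,
    fpkm: pd.DataFrame,
) -> TranscriptomeUsage:
    """Expression-weighted codon usage per library.

    codon_counts: transcripts x 64 codon counts from each transcript's longest
    ORF (a transcript with no ORF has an all-zero row and contributes
    nothing).  fpkm: transcripts x libraries.  Per library, codon counts are
    weighted by FPKM, summed over transcripts, and expressed as percentages;
    the mean table is the unweighted average of the per-library percentage
    tables.  Libraries whose weighted counts are all zero have undefined
    percentages: they are flagged and excluded from the mean.
    """
    missing = [t for t in fpkm.index if t not in codon_counts.index]
    if missing:
        raise InputError(f"transcript {missing[0]!r} has FPKM but no codon counts")
    counts = codon_counts.reindex(index=fpkm.index, columns=CODONS, fill_value=0.0)
    if counts.isna().to_numpy().any():
        raise InputError("codon counts contain missing values")
    f = fpkm.to_numpy(dtype=float)
    if np.isnan(f).any() or (f < 0).any():
        raise InputError("FPKM values must be nonnegative and complete")
    weighted = counts.to_numpy(dtype=float).T @ fpkm.to_numpy(dtype=float)  # 64 x L
    totals = weighted.sum(axis=0)
    libs = list(fpkm.columns)
    flagged = [lib for lib, t in zip(libs, totals) if t <= 0]
    with np.errstate(invalid="ignore", divide="ignore"):
        percent = np.where(totals > 0, weighted / totals * 100.0, np.nan)
    per_library = pd.DataFrame(percent, index=list(CODONS), columns=libs)
    ok = [lib for lib in libs if lib not in flagged]
    if not ok:
        raise DomainError("every library has zero weighted codon counts")
    mean = CodonTable(
        values=per_library[ok].mean(axis=1),
        basis="transcriptome:mean", unit="percent",
    )
    return TranscriptomeUsage(per_library=per_library, mean=mean, flagged_libraries=flagged)


def aggregate_by_aa(table: CodonTable) -> tuple[pd.Series, float]:
    """Sum synonymous-codon frequencies per amino acid.

    Returns (per-amino-acid series over the 20 standard residues in the
    table's unit, stop-codon mass reported separately).
    """
    aa = pd.Series(0.0, index=AMINO_ACIDS)
    stop_mass = 0.0
    for codon, value in table.values.items():
        if codon in _AA_OF:
            aa[_AA_OF[codon]] += value
        else:
            stop_mass += value
    return aa, float(stop_mass)


def correlate_trna(aa_usage: pd.Series, trna_counts: Mapping[str, float] | pd.Series) -> float:
    """Pearson correlation between amino-acid usage and tRNA gene counts.

    Aligned on the amino acids present in both inputs (at least 3 required).
    Zero variance on either side leaves the correlation undefined.
    """
    trna = pd.Series(trna_counts, dtype=float)
    common = [a for a in aa_usage.index if a in trna.index]
    if len(common) < 3:
        raise DimensionError(
            f"need at least 3 amino acids shared between usage and tRNA counts, got {len(common)}"
        )
    u = aa_usage.loc[common].to_numpy(dtype=float)
    t = trna.loc[common].to_numpy(dtype=float)
    if np.std(u) == 0 or np.std(t) == 0:
        raise DomainError("correlation undefined: zero variance in usage or tRNA counts")
    return float(stats.pearsonr(u, t)[0])


def read_trna_counts(path: str | Path) -> pd.Series:
    """Read a 2-column TSV of amino acid (one-letter or three-letter) and count."""
    df = pd.read_csv(path, sep="\t", header=None, names=["aa", "count"], comment="#")
    three_to_one = {
        "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C", "GLN": "Q",
        "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I", "LEU": "L", "LYS": "K",
        "MET": "M", "PHE": "F", "PRO": "P", "SER": "S", "THR": "T", "TRP": "W",
        "TYR": "Y", "VAL": "V",
    }
    out: dict[str, float] = {}
    for _, row in df.iterrows():
        aa = str(row["aa"]).strip().upper()
        aa = three_to_one.get(aa, aa)
        if len(aa) != 1 or aa not in AMINO_ACIDS:
            raise InputError(f"unknown amino acid {row['aa']!r} in tRNA count table")
        n = float(row["count"])
        if n < 0 or n != int(n):
            raise InputError(f"tRNA count for {aa!r} must be a nonnegative integer")
        out[aa] = out.get(aa, 0.0) + n
    return pd.Series(out, dtype=float)
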