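"""Read-composition classifiers.

Two classification problems arise when auditing what an RNA-seq library
actually sequenced:

* mapped reads land on genes, which fall into four exhaustive, mutually
  exclusive categories — mitochondrial, rRNA, protein-coding, noncoding —
  by scaffold membership and by whether any transcript carries an open
  reading frame longer than 100 residues;
* unmapped reads with nucleotide-database hits are binned into seven
  categories by case-insensitive keyword matching on the hit's subject
  title, with a fixed priority order (so an "M. sexta 18S ribosomal RNA"
  title is rRNA, not M. sexta).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd
from Bio.Seq import Seq

from .errors import DomainError, InputError
from .matrix import FpkmMatrix

__all__ = [
    "GENE_CATEGORIES",
    "HIT_CATEGORIES",
    "HitRecord",
    "CategoryCounts",
    "longest_orf",
    "longest_orf_length",
    "classify_gene",
    "summarize_categories",
    "classify_hit_description",
    "adjust_library_sizes",
    "CODING_ORF_MIN_RESIDUES",
]

GENE_CATEGORIES = ("mitochondrial", "rRNA", "coding", "noncoding")
CODING_ORF_MIN_RESIDUES = 100

_STOPS = frozenset({"TAA", "TAG", "TGA"})

# keyword groups in priority order; matching is case-insensitive substring
HIT_CATEGORIES = ("rRNA", "mitochondrion", "phage", "M. sexta", "E. coli", "Oryza", "others")
_HIT_KEYWORDS: tuple[tuple[str, tuple[str, ...]], ...] = (
    ("rRNA", ("ribosomal rna", "rrna")),
    ("mitochondrion", ("mitochondri",)),
    ("phage", ("phage",)),
    ("M. sexta", ("m. sexta", "manduca", "sexta")),
    ("E. coli", ("escherichia coli", "e.coli", "e. coli")),
    ("Oryza", ("oryza",)),
)


def _frame_best_orf(seq: str, offset: int, require_atg: bool, allow_open_end: bool) -> tuple[int, str]:
    """Longest ORF in one frame; returns (residue count, ORF nucleotides incl. stop)."""
    best_len = 0
    best_nt = ""
    start: int | None = None
    i = offset
    n = len(seq)
    while i + 3 <= n:
        codon = seq[i:i + 3]
        if start is None:
            if codon == "ATG" or (not require_atg and i == offset):
                start = i
        if start is not None and codon in _STOPS:
            length = (i - start) // 3
            if length > best_len:
                best_len = length
                best_nt = seq[start:i + 3]
            start = None
        i += 3
    if start is not None and allow_open_end:
        end = start + 3 * ((n - start) // 3)
        length = (end - start) // 3
        if length > best_len:
            best_len = length
            best_nt = seq[start:end]
    return best_len, best_nt


def longest_orf(
    sequence: str,
    require_atg: bool = True,
    allow_open_end: bool = True,
) -> tuple[int, str]:
    """Longest open reading frame over all six frames of a transcript.

    Returns (length in residues excluding the stop, ORF nucleotide sequence
    including its stop codon when present).  By default an ORF must start at
    ATG but may run off the 3' end of a frame without reaching a stop;
    require_atg=False additionally admits ORFs entering the sequence from
    beyond its 5' edge (the frame's first codon acts as the start).  Codons
    containing N translate to an unknown residue: they extend an ORF but an
    N-containing triplet is never recognized as the ATG start.
    """
    seq = sequence.strip().upper().replace("U", "T")
    if not seq:
        return 0, ""
    bad = set(seq) - set("ACGTN")
    if bad:
        raise InputError(f"transcript contains non-nucleotide characters: {sorted(bad)}")
    best_len, best_nt = 0, ""
    for strand_seq in (seq, str(Seq(seq).reverse_complement())):
        for offset in (0, 1, 2):
            length, nt = _frame_best_orf(strand_seq, offset, require_atg, allow_open_end)
            if length > best_len:
                best_len, best_nt = length, nt
    return best_len, best_nt


def longest_orf_length(
    sequence: str,
    require_atg: bool = True,
    allow_open_end: bool = True,
) -> int:
    """Residue count of the longest six-frame ORF; see longest_orf."""
    return longest_orf(sequence, require_atg=require_atg, allow_open_end=allow_open_end)[0]


def classify_gene(
    scaffold_id: str,
    mito_scaffolds: Iterable[str],
    rrna_scaffolds: Iterable[str],
    max_orf: int,
) -> str:
    """Assign one of the four gene categories.

    Precedence: mitochondrial scaffold, then rRNA scaffold, then coding
    (longest ORF strictly above 100 residues), else noncoding.  Scaffold ids
    are compared by exact string equality after whitespace trimming.
    """
    mito = {s.strip() for s in mito_scaffolds}
    rrna = {s.strip() for s in rrna_scaffolds}
    shared = mito & rrna
    if shared:
        raise InputError(
            f"scaffold(s) {sorted(shared)} listed as both mitochondrial and rRNA"
        )
    sid = scaffold_id.strip()
    if sid in mito:
        return "mitochondrial"
    if sid in rrna:
        return "rRNA"
    if max_orf > CODING_ORF_MIN_RESIDUES:
        return "coding"
    return "noncoding"


@dataclass
class CategoryCounts:
    """Per-library read counts and fractions over a category set."""

    library_id: str
    counts: dict[str, float]
    fractions: dict[str, float]
    total: float
    empty: bool = False


def summarize_categories(
    read_counts: pd.DataFrame | Mapping[str, Mapping[str, float]],
    categories: Mapping[str, str],
) -> list[CategoryCounts]:
    """Sum per-gene read counts into the four categories for every library.

    read_counts: genes x libraries (DataFrame, or mapping gene -> {library:
    count}).  Every counted gene must be categorized.  A library with zero
    total reads is flagged empty and reports all fractions as 0.
    """
    if not isinstance(read_counts, pd.DataFrame):
        read_counts = pd.DataFrame.from_dict(dict(read_counts), orient="index")
    missing = [g for g in read_counts.index if g not in categories]
    if missing:
        raise InputError(f"gene {missing[0]!r} has read counts but no category")
    bad = {g: c for g, c in categories.items() if c not in GENE_CATEGORIES}
    if bad:
        g, c = next(iter(bad.items()))
        raise InputError(f"gene {g!r}: unknown category {c!r}")
    cats = pd.Series({g: categories[g] for g in read_counts.index})
    out: list[CategoryCounts] = []
    for lib in read_counts.columns:
        sums = read_counts[lib].groupby(cats).sum()
        counts = {c: float(sums.get(c, 0.0)) for c in GENE_CATEGORIES}
        total = sum(counts.values())
        if total > 0:
            fractions = {c: counts[c] / total for c in GENE_CATEGORIES}
            empty = False
        else:
            fractions = {c: 0.0 for c in GENE_CATEGORIES}
            empty = True
        out.append(CategoryCounts(
            library_id=str(lib), counts=counts, fractions=fractions,
            total=total, empty=empty,
        ))
    return out


@dataclass(frozen=True)
class HitRecord:
    """One unmapped read's best database hit: free-text subject title + category."""

    read_id: str
    subject_title: str
    category: str = ""


def classify_hit_description(title: str) -> str:
    """Bin a hit subject title into one of the seven keyword categories.

    First match wins in the order rRNA, mitochondrion, phage, M. sexta,
    E. coli, Oryza; anything unmatched is "others".  Matching is plain
    case-insensitive substring search (the "e.coli" dot is literal).
    """
    low = title.lower()
    for category, keywords in _HIT_KEYWORDS:
        if any(kw in low for kw in keywords):
            return category
    return "others"


def classify_hit_table(records: Iterable[HitRecord]) -> list[HitRecord]:
    """Re-classify every record from its title; returns new records."""
    return [
        HitRecord(r.read_id, r.subject_title, classify_hit_description(r.subject_title))
        for r in records
    ]


__all__.append("classify_hit_table")


def adjust_library_sizes(
    matrix: FpkmMatrix,
    excluded_fraction: Mapping[str, float] | pd.Series,
) -> FpkmMatrix:
    """Rescale FPKM after excluding a fraction f of each library's mapped reads.

    Excluding abundant rRNA/mitochondrial reads shrinks the mapped-read total
    a library was normalized by, so remaining genes' FPKM values rise by
    1 / (1 - f).  Within-library rank order is unchanged.  Libraries absent
    from the mapping keep f = 0.
    """
    f = pd.Series(excluded_fraction, dtype=float)
    unknown = [lib for lib in f.index if lib not in matrix.values.columns]
    if unknown:
        raise InputError(f"excluded_fraction names unknown library {unknown[0]!r}")
    f = f.reindex(matrix.library_ids, fill_value=0.0)
    if ((f < 0) | (f >= 1)).any():
        bad = f[(f < 0) | (f >= 1)].index[0]
        raise DomainError(f"excluded fraction for library {bad!r} must be in [0, 1)")
    scaled = matrix.values / (1.0 - f)
    return FpkmMatrix(values=scaled, library_meta=dict(matrix.library_meta))
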