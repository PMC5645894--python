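"""Seeded synthetic atlases with planted ground truth.

Every downstream stage gets a generator whose output carries a known answer:

* FPKM matrices with log-normal baselines and tissue-exclusive planted
  marker genes (a marker's expectation is effect_multiplier x its baseline
  in its home tissue's libraries only);
* per-base depth tracks whose rank-depth profile follows a truncated
  discrete power law, so a small number of top-ranked bases carries most of
  the aligned mass, as in real transcriptomes;
* toy transcriptomes of start-to-stop ORFs drawn from a 64-codon weight
  vector, with realized codon counts recorded;
* database-hit title tables embedding the classification keywords with
  randomized casing and flanking text.

All generators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .codon import CODONS, SENSE_CODONS, STOP_CODONS
from .composition import HIT_CATEGORIES, HitRecord
from .coverage import DepthTrack
from .errors import ConfigurationError
from .matrix import FpkmMatrix, LibraryInfo

__all__ = [
    "AtlasConfig",
    "PlantedTruth",
    "TranscriptSet",
    "default_libraries",
    "generate_fpkm_matrix",
    "generate_depth_track",
    "generate_transcriptome",
    "generate_hit_table",
    "write_transcripts_fasta",
    "write_truth_tsv",
    "write_hit_table_tsv",
]


def default_libraries(
    tissues: Sequence[str] = (
        "head", "fat_body", "midgut", "muscle",
        "testis", "ovary", "malpighian_tubule", "antenna",
    ),
    stages: Sequence[str] = ("L5", "A"),
) -> list[LibraryInfo]:
    """A compact tissue x stage design: 8 tissues x 2 stages = 16 libraries.

    Larval (L5) libraries are labeled paired-end and adult (A) single-end so
    both sequencing modes appear in the metadata.
    """
    libs = []
    for tissue in tissues:
        for stage in stages:
            libs.append(LibraryInfo(
                library_id=f"{tissue}-{stage}",
                tissue=tissue, stage=stage,
                seq_mode="P" if stage == "L5" else "S",
            ))
    return libs


@dataclass
class AtlasConfig:
    """Parameters of the synthetic FPKM atlas.

    baseline_log_mean / baseline_log_sd parametrize the log-normal baseline
    FPKM of each gene (natural-log scale); noise_log_sd is multiplicative
    log-normal noise per cell.  marker_fraction of the genes is planted as
    markers for EACH tissue (tissue-exclusive), boosted by effect_multiplier
    in that tissue's libraries.
    """

    n_genes: int = 2000
    libraries: list[LibraryInfo] = field(default_factory=default_libraries)
    baseline_log_mean: float = 1.0
    baseline_log_sd: float = 1.0
    marker_fraction: float = 0.05
    effect_multiplier: float = 8.0
    noise_log_sd: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ConfigurationError(f"n_genes must be >= 1, got {self.n_genes}")
        if not self.libraries:
            raise ConfigurationError("libraries must be a nonempty list")
        ids = [l.library_id for l in self.libraries]
        if len(ids) != len(set(ids)):
            raise ConfigurationError("libraries: library_ids must be unique")
        if not 0.0 <= self.marker_fraction <= 0.5:
            raise ConfigurationError(
                f"marker_fraction must be in [0, 0.5], got {self.marker_fraction}"
            )
        if self.effect_multiplier < 1.0:
            raise ConfigurationError(
                f"effect_multiplier must be >= 1, got {self.effect_multiplier}"
            )
        if self.baseline_log_sd < 0:
            raise ConfigurationError(
                f"baseline_log_sd must be >= 0, got {self.baseline_log_sd}"
            )
        if self.noise_log_sd < 0:
            raise ConfigurationError(f"noise_log_sd must be >= 0, got {self.noise_log_sd}")
        n_tissues = len({l.tissue for l in self.libraries})
        n_markers = int(round(self.marker_fraction * self.n_genes)) * n_tissues
        if n_markers > self.n_genes:
            raise ConfigurationError(
                f"marker_fraction: {n_markers} planted markers exceed n_genes={self.n_genes}"
            )

    @property
    def tissues(self) -> list[str]:
        seen: dict[str, None] = {}
        for l in self.libraries:
            seen.setdefault(l.tissue, None)
        return list(seen)


@dataclass
class PlantedTruth:
    """Which genes were planted as markers of which tissue."""

    marker_assignment: dict[str, str]
    config: AtlasConfig

    def markers_of(self, tissue: str) -> list[str]:
        return [g for g, t in self.marker_assignment.items() if t == tissue]


def generate_fpkm_matrix(config: AtlasConfig) -> tuple[FpkmMatrix, PlantedTruth]:
    """Draw a synthetic FPKM matrix with tissue-exclusive planted markers."""
    rng = np.random.default_rng(config.seed)
    n_genes = config.n_genes
    libs = config.libraries
    gene_ids = [f"gene{i + 1:05d}" for i in range(n_genes)]
    baseline = rng.lognormal(config.baseline_log_mean, config.baseline_log_sd, n_genes)

    tissues = config.tissues
    per_tissue = int(round(config.marker_fraction * n_genes))
    perm = rng.permutation(n_genes)
    assignment: dict[str, str] = {}
    effect = np.ones((n_genes, len(libs)))
    tissue_cols = {
        t: [j for j, l in enumerate(libs) if l.tissue == t] for t in tissues
    }
    for ti, tissue in enumerate(tissues):
        block = perm[ti * per_tissue:(ti + 1) * per_tissue]
        for g in block:
            assignment[gene_ids[g]] = tissue
            effect[g, tissue_cols[tissue]] = config.effect_multiplier

    noise = rng.lognormal(0.0, config.noise_log_sd, (n_genes, len(libs)))
    values = baseline[:, None] * effect * noise
    df = pd.DataFrame(values, index=gene_ids, columns=[l.library_id for l in libs])
    matrix = FpkmMatrix(values=df, library_meta={l.library_id: l for l in libs})
    return matrix, PlantedTruth(marker_assignment=assignment, config=config)


def generate_depth_track(
    n_scaffolds: int,
    scaffold_len: int,
    total_mapped: int,
    tail_exponent: float,
    seed: int,
    library_id: str = "synthetic",
) -> DepthTrack:
    """Heavy-tailed per-base depths: rank r gets expected mass proportional to r^-a.

    Depths are a multinomial draw of total_mapped bases over a truncated
    discrete power law on ranks, then shuffled onto genome positions, so the
    sum of depths equals total_mapped exactly and the top ranks dominate.
    """
    if n_scaffolds < 1:
        raise ConfigurationError(f"n_scaffolds must be >= 1, got {n_scaffolds}")
    if scaffold_len < 1:
        raise ConfigurationError(f"scaffold_len must be >= 1, got {scaffold_len}")
    if total_mapped < 0:
        raise ConfigurationError(f"total_mapped must be >= 0, got {total_mapped}")
    if tail_exponent <= 0:
        raise ConfigurationError(f"tail_exponent must be > 0, got {tail_exponent}")
    rng = np.random.default_rng(seed)
    n_bases = n_scaffolds * scaffold_len
    flat = np.zeros(n_bases, dtype=np.int64)
    if total_mapped > 0:
        ranks = np.arange(1, n_bases + 1, dtype=float)
        weights = ranks ** -tail_exponent
        p = weights / weights.sum()
        depths_by_rank = rng.multinomial(total_mapped, p)
        positions = rng.permutation(n_bases)
        flat[positions] = depths_by_rank
    width = len(str(n_scaffolds))
    scaffolds = {
        f"scaffold{(i + 1):0{width}d}": flat[i * scaffold_len:(i + 1) * scaffold_len]
        for i in range(n_scaffolds)
    }
    return DepthTrack(scaffolds=scaffolds, library_id=library_id)


@dataclass
class TranscriptSet:
    """Synthetic start-to-stop ORF transcripts with realized codon counts."""

    sequences: dict[str, str]
    codon_counts: pd.DataFrame  # transcripts x 64, realized ground truth

    @property
    def transcript_ids(self) -> list[str]:
        return list(self.sequences)


def generate_transcriptome(
    n_transcripts: int,
    codon_weights: Mapping[str, float] | Sequence[float],
    length_range: tuple[int, int] = (50, 300),
    seed: int = 0,
) -> TranscriptSet:
    """Draw transcripts as ATG ... (internal sense codons) ... stop.

    codon_weights is a 64-entry vector (or codon -> weight mapping); internal
    codons are drawn from the sense entries, the terminator from the stop
    entries (uniform over stops if those weights are all zero).  Stop codons
    act as terminators only and never appear internally.  length_range bounds
    the number of internal sense codons, inclusive.
    """
    if n_transcripts < 0:
        raise ConfigurationError(f"n_transcripts must be >= 0, got {n_transcripts}")
    if isinstance(codon_weights, Mapping):
        w = pd.Series(codon_weights, dtype=float).reindex(CODONS, fill_value=0.0)
    else:
        arr = np.asarray(list(codon_weights), dtype=float)
        if arr.shape != (64,):
            raise ConfigurationError(
                f"codon_weights must have 64 entries, got {arr.shape}"
            )
        w = pd.Series(arr, index=CODONS)
    if (w < 0).any():
        raise ConfigurationError("codon_weights must be nonnegative")
    lo, hi = length_range
    if lo < 0 or hi < lo:
        raise ConfigurationError(f"length_range must satisfy 0 <= lo <= hi, got {length_range}")
    sense_w = w.loc[list(SENSE_CODONS)].to_numpy()
    if sense_w.sum() <= 0:
        raise ConfigurationError("codon_weights: all sense-codon weights are zero")
    sense_p = sense_w / sense_w.sum()
    stop_w = w.loc[list(STOP_CODONS)].to_numpy()
    stop_p = stop_w / stop_w.sum() if stop_w.sum() > 0 else np.full(len(STOP_CODONS), 1 / 3)

    rng = np.random.default_rng(seed)
    sequences: dict[str, str] = {}
    counts = pd.DataFrame(
        0.0, index=[f"tx{i + 1:04d}" for i in range(n_transcripts)], columns=list(CODONS)
    )
    for i in range(n_transcripts):
        tid = f"tx{i + 1:04d}"
        n_internal = int(rng.integers(lo, hi + 1))
        internal = rng.choice(len(SENSE_CODONS), size=n_internal, p=sense_p)
        stop = STOP_CODONS[int(rng.choice(len(STOP_CODONS), p=stop_p))]
        codons = ["ATG"] + [SENSE_CODONS[j] for j in internal] + [stop]
        sequences[tid] = "".join(codons)
        for c in codons:
            counts.loc[tid, c] += 1
    return TranscriptSet(sequences=sequences, codon_counts=counts)


# Title templates per category.  Flanking text is chosen so that no template
# accidentally contains a keyword of an earlier (higher-priority) category.
_TITLE_TEMPLATES: dict[str, list[str]] = {
    "rRNA": [
        "Manduca sexta 18S ribosomal RNA gene, partial sequence",
        "Bombyx mori 28S ribosomal RNA gene, complete sequence",
        "Uncultured organism clone 5.8S rRNA gene",
        "Spodoptera frugiperda large subunit rRNA, partial",
    ],
    "mitochondrion": [
        "Manduca sexta mitochondrion, complete genome",
        "Bombyx mori mitochondrial DNA, cytochrome oxidase subunit I",
        "Insect mitochondrion NADH dehydrogenase subunit 4 gene",
    ],
    "phage": [
        "Enterobacteria phage phiX174, complete genome",
        "Coliphage phi-X174 isolate, whole genome shotgun",
        "Bacteriophage lambda DNA, partial sequence",
    ],
    "M. sexta": [
        "Manduca sexta lysozyme mRNA, complete cds",
        "Manduca sexta apolipophorin gene, partial cds",
        "M. sexta clone BAC-17 genomic sequence",
        "Manduca sexta arylphorin alpha subunit mRNA",
    ],
    "E. coli": [
        "Escherichia coli strain K-12 substrain MG1655, complete genome",
        "Escherichia coli O157:H7 plasmid pO157 DNA",
        "Synthetic construct cloning vector from E.coli host",
    ],
    "Oryza": [
        "Oryza sativa Japonica Group chromosome 1 clone",
        "Oryza sativa mRNA for putative transposase",
        "Oryza rufipogon cultivar genomic scaffold",
    ],
    "others": [
        "Bombyx mori clone fragment, genomic sequence",
        "Spodoptera litura genomic scaffold contig-0042",
        "Uncultured bacterium clone 16S gene region",
        "Heliothis virescens cytochrome P450 mRNA",
        "Synthetic construct adapter sequence",
    ],
}


def _randomize_case(title: str, rng: np.random.Generator) -> str:
    transform = rng.integers(0, 3)
    if transform == 1:
        return title.upper()
    if transform == 2:
        return title.lower()
    return title


def generate_hit_table(n_per_category: int, seed: int = 0) -> list[HitRecord]:
    """Emit n_per_category hit records for each of the seven categories.

    Titles embed the category's keyword with randomized casing and flanking
    text; "others" titles contain no keyword.  The true label is recorded on
    each record.
    """
    if n_per_category < 0:
        raise ConfigurationError(f"n_per_category must be >= 0, got {n_per_category}")
    rng = np.random.default_rng(seed)
    records: list[HitRecord] = []
    counter = 0
    for category in HIT_CATEGORIES:
        templates = _TITLE_TEMPLATES[category]
        for _ in range(n_per_category):
            counter += 1
            base = templates[int(rng.integers(0, len(templates)))]
            title = _randomize_case(base, rng)
            records.append(HitRecord(
                read_id=f"read{counter:06d}", subject_title=title, category=category,
            ))
    return records


def write_transcripts_fasta(tset: TranscriptSet, path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=tid, description="synthetic ORF transcript")
        for tid, seq in tset.sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def write_truth_tsv(truth: PlantedTruth, path: str | Path) -> None:
    rows = [
        {"gene_id": g, "tissue": t} for g, t in sorted(truth.marker_assignment.items())
    ]
    pd.DataFrame(rows, columns=["gene_id", "tissue"]).to_csv(path, sep="\t", index=False)


def write_hit_table_tsv(records: Sequence[HitRecord], path: str | Path) -> None:
    rows = [
        {"read_id": r.read_id, "subject_title": r.subject_title, "category": r.category}
        for r in records
    ]
    pd.DataFrame(rows, columns=["read_id", "subject_title", "category"]).to_csv(
        path, sep="\t", index=False
    )
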