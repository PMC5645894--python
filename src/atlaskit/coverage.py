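"""Per-base coverage analytics: transcribed fraction, BPKM, rank strata.

Depth tracks hold one integer read depth per genome base.  Depths are
normalized to BPKM (bases per kilobase per million mapped bases): the number
of bases mapped to one base out of one billion mapped bases,

    BPKM(base) = depth(base) * 1e9 / total_mapped_bases.

Bases are sorted by BPKM (descending) and divided into 19 geometric rank
groups: group 1 holds the top 400 bases and each later group doubles the
cumulative span, group g covering ranks (400*2^(g-2), 400*2^(g-1)].  Groups
1-4 therefore end at rank 3,200, groups 1-6 at 12,800, and groups 1-12 at
819,200.  Zero-depth bases, and any transcribed bases ranked past
400*2^18, fall into an explicit remainder.  Per-group mean BPKM and the
group's share of all aligned bases summarize how concentrated transcription
is; z-scores of group means across a panel of libraries make the strata
comparable between libraries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import DimensionError, DomainError, InputError

__all__ = [
    "DepthTrack",
    "StrataSummary",
    "RegressionFit",
    "Interval",
    "N_GROUPS",
    "GROUP_BASE",
    "MIN_SCAFFOLD_DEFAULT",
    "transcribed_fraction",
    "filter_scaffolds",
    "bpkm_normalize",
    "group_boundary",
    "stratify",
    "strata_zscores",
    "annotation_coverage",
    "regress_coverage",
    "read_depth_tsv",
    "read_lengths_tsv",
]

N_GROUPS = 19
GROUP_BASE = 400
MIN_SCAFFOLD_DEFAULT = 200_000


@dataclass
class DepthTrack:
    """Per-base depths for one library, keyed by scaffold id."""

    scaffolds: dict[str, np.ndarray]
    library_id: str = ""

    def __post_init__(self) -> None:
        clean: dict[str, np.ndarray] = {}
        for sid, arr in self.scaffolds.items():
            a = np.asarray(arr)
            if a.ndim != 1:
                raise InputError(f"scaffold {sid!r}: depth array must be 1-D")
            if a.size and a.min() < 0:
                raise InputError(f"scaffold {sid!r}: negative depth")
            clean[sid] = a.astype(np.int64, copy=False)
        self.scaffolds = clean

    @property
    def genome_size(self) -> int:
        return int(sum(a.size for a in self.scaffolds.values()))

    @property
    def total_mapped_bases(self) -> int:
        return int(sum(int(a.sum()) for a in self.scaffolds.values()))

    def scaffold_lengths(self) -> dict[str, int]:
        return {sid: int(a.size) for sid, a in self.scaffolds.items()}


def transcribed_fraction(track: DepthTrack) -> float:
    """Fraction of genome bases with nonzero depth."""
    total = track.genome_size
    if total == 0:
        raise InputError("empty depth track")
    nonzero = sum(int((a > 0).sum()) for a in track.scaffolds.values())
    return nonzero / total


def filter_scaffolds(track: DepthTrack, min_len: int = MIN_SCAFFOLD_DEFAULT) -> DepthTrack:
    """Drop scaffolds shorter than min_len bases (strict <).

    Short scaffolds are typically rRNA and mitochondrial fragments whose
    overrepresented reads would distort the stratification.
    """
    kept = {sid: a for sid, a in track.scaffolds.items() if a.size >= min_len}
    return DepthTrack(scaffolds=kept, library_id=track.library_id)


def bpkm_normalize(track: DepthTrack) -> dict[str, np.ndarray]:
    """Per-base BPKM arrays: depth * 1e9 / total mapped bases."""
    total = track.total_mapped_bases
    if total <= 0:
        raise DomainError("BPKM undefined: track has zero mapped bases")
    scale = 1e9 / total
    return {sid: a * scale for sid, a in track.scaffolds.items()}


def group_boundary(g: int) -> int:
    """Cumulative upper rank boundary of groups 1..g: 400 * 2^(g-1)."""
    if not 1 <= g <= N_GROUPS:
        raise DomainError(f"group index must be in 1..{N_GROUPS}, got {g}")
    return GROUP_BASE * 2 ** (g - 1)


@dataclass
class StrataSummary:
    """The 19 rank groups of one library: spans, mean BPKM, aligned-base shares.

    table columns: rank_lo (exclusive), rank_hi (inclusive), n_bases (nonzero
    bases actually in the span), mean_bpkm, share.  remainder_share collects
    aligned bases on ranks beyond group 19; zero-depth bases carry no aligned
    mass but are counted in n_zero_bases.
    """

    library_id: str
    table: pd.DataFrame
    remainder_share: float
    total_mapped_bases: int
    n_zero_bases: int

    def shares_total(self) -> float:
        return float(self.table["share"].sum() + self.remainder_share)


def stratify(track: DepthTrack) -> StrataSummary:
    """Sort bases by BPKM descending and fill the 19 geometric rank groups.

    Ties are broken by (scaffold_id, position) ascending so results are
    deterministic.  The track should already be scaffold-filtered.  Only
    nonzero-depth bases occupy ranks; zero-depth bases join the remainder.
    A group whose span extends past the available nonzero bases is partially
    (or wholly) empty, with mean 0 over no bases.
    """
    total = track.total_mapped_bases
    if total <= 0:
        raise DomainError("cannot stratify a track with zero mapped bases")
    sids = sorted(track.scaffolds)
    depth_parts, scaf_parts, pos_parts = [], [], []
    for rank_id, sid in enumerate(sids):
        a = track.scaffolds[sid]
        nz = np.nonzero(a)[0]
        if nz.size:
            depth_parts.append(a[nz])
            scaf_parts.append(np.full(nz.size, rank_id, dtype=np.int64))
            pos_parts.append(nz)
    depths = np.concatenate(depth_parts)
    scafs = np.concatenate(scaf_parts)
    poss = np.concatenate(pos_parts)
    # primary key: depth descending (equivalently BPKM); then scaffold, position
    order = np.lexsort((poss, scafs, -depths))
    depths_sorted = depths[order]
    cum = np.concatenate(([0], np.cumsum(depths_sorted)))
    n_nonzero = depths_sorted.size
    scale = 1e9 / total

    rows = []
    for g in range(1, N_GROUPS + 1):
        lo = 0 if g == 1 else group_boundary(g - 1)
        hi = group_boundary(g)
        lo_eff = min(lo, n_nonzero)
        hi_eff = min(hi, n_nonzero)
        n_in = hi_eff - lo_eff
        depth_sum = int(cum[hi_eff] - cum[lo_eff])
        mean_bpkm = (depth_sum / n_in) * scale if n_in else 0.0
        rows.append(
            {"group": g, "rank_lo": lo, "rank_hi": hi, "n_bases": n_in,
             "mean_bpkm": mean_bpkm, "share": depth_sum / total}
        )
    table = pd.DataFrame(rows).set_index("group")
    grouped_depth = int(cum[min(group_boundary(N_GROUPS), n_nonzero)])
    remainder_share = (total - grouped_depth) / total
    return StrataSummary(
        library_id=track.library_id,
        table=table,
        remainder_share=remainder_share,
        total_mapped_bases=total,
        n_zero_bases=track.genome_size - n_nonzero,
    )


def strata_zscores(panel: Sequence[StrataSummary], ddof: int = 1) -> pd.DataFrame:
    """z-standardize each group's mean BPKM across the libraries of a panel.

    Returns a group x library DataFrame.  Groups with zero spread across
    libraries get all-zero z-scores, matching the expression-module rule.
    """
    if len(panel) < 2:
        raise DimensionError("z-scores across libraries need at least 2 libraries")
    means = pd.DataFrame(
        {s.library_id or f"library_{i}": s.table["mean_bpkm"] for i, s in enumerate(panel)}
    )
    vals = means.to_numpy(dtype=float)
    mu = vals.mean(axis=1)
    sd = vals.std(axis=1, ddof=ddof)
    z = np.zeros_like(vals)
    ok = sd > 0
    z[ok] = (vals[ok] - mu[ok, None]) / sd[ok, None]
    return pd.DataFrame(z, index=means.index, columns=means.columns)


@dataclass(frozen=True)
class Interval:
    """One annotation row: 1-based inclusive coordinates, GTF-style."""

    scaffold: str
    feature: str  # gene, exon or CDS
    start: int
    end: int
    strand: str = "+"
    gene_id: str = ""


def _union_length(spans: list[tuple[int, int]]) -> int:
    """Total length of the union of 0-based half-open intervals."""
    if not spans:
        return 0
    spans.sort()
    total = 0
    cur_lo, cur_hi = spans[0]
    for lo, hi in spans[1:]:
        if lo > cur_hi:
            total += cur_hi - cur_lo
            cur_lo, cur_hi = lo, hi
        else:
            cur_hi = max(cur_hi, hi)
    return total + (cur_hi - cur_lo)


def annotation_coverage(
    intervals: Iterable[Interval | tuple],
    genome_size: int,
    scaffold_lengths: dict[str, int] | None = None,
) -> dict[str, float]:
    """Fraction of the genome covered by each feature class, strand-agnostic.

    A base counts as covered by a feature class if it falls inside any
    interval of that class on either strand.  Gene spans are derived from
    exon records: per gene, the maximum distance between its exons' edges;
    explicit gene rows are used directly for genes without exon records.
    Coordinates are 1-based inclusive on input.
    """
    if genome_size <= 0:
        raise DomainError(f"genome_size must be positive, got {genome_size}")
    recs: list[Interval] = []
    for r in intervals:
        iv = r if isinstance(r, Interval) else Interval(*r)
        if iv.start < 1 or iv.end < iv.start:
            raise InputError(f"bad coordinates in record {iv}")
        if scaffold_lengths is not None:
            if iv.scaffold not in scaffold_lengths:
                raise InputError(f"unknown scaffold in record {iv}")
            if iv.end > scaffold_lengths[iv.scaffold]:
                raise InputError(f"interval out of scaffold bounds in record {iv}")
        recs.append(iv)

    by_feature: dict[str, dict[str, list[tuple[int, int]]]] = {}
    for iv in recs:
        if iv.feature in ("exon", "CDS"):
            by_feature.setdefault(iv.feature, {}).setdefault(iv.scaffold, []).append(
                (iv.start - 1, iv.end)
            )
    # gene spans: per (scaffold, gene_id), min exon start .. max exon end
    gene_edges: dict[tuple[str, str], tuple[int, int]] = {}
    genes_with_exons: set[str] = set()
    for iv in recs:
        if iv.feature == "exon" and iv.gene_id:
            key = (iv.scaffold, iv.gene_id)
            lo, hi = gene_edges.get(key, (iv.start - 1, iv.end))
            gene_edges[key] = (min(lo, iv.start - 1), max(hi, iv.end))
            genes_with_exons.add(iv.gene_id)
    for iv in recs:
        if iv.feature == "gene" and iv.gene_id not in genes_with_exons:
            key = (iv.scaffold, iv.gene_id or f"__anon_{id(iv)}")
            lo, hi = gene_edges.get(key, (iv.start - 1, iv.end))
            gene_edges[key] = (min(lo, iv.start - 1), max(hi, iv.end))
    gene_spans: dict[str, list[tuple[int, int]]] = {}
    for (scaffold, _), (lo, hi) in gene_edges.items():
        gene_spans.setdefault(scaffold, []).append((lo, hi))
    if gene_spans:
        by_feature["gene"] = gene_spans

    out: dict[str, float] = {}
    for feature in ("gene", "exon", "CDS"):
        per_scaffold = by_feature.get(feature, {})
        covered = sum(_union_length(list(spans)) for spans in per_scaffold.values())
        out[feature] = covered / genome_size
    return out


@dataclass
class RegressionFit:
    """OLS fit of covered fraction on aligned bases for one sequencing mode."""

    mode: str
    slope: float
    intercept: float
    residuals: np.ndarray
    n: int


def regress_coverage(
    points: Iterable[tuple[float, float, str]],
) -> dict[str, RegressionFit]:
    """Per sequencing mode (S/P), ordinary least squares with intercept.

    points are (aligned_bases, covered_fraction, mode).  Residuals are
    reported per library so outliers (libraries far off their mode's line)
    can be inspected.  A mode with fewer than 2 points is skipped with a
    warning.
    """
    by_mode: dict[str, list[tuple[float, float]]] = {}
    for xb, yf, mode in points:
        by_mode.setdefault(mode, []).append((float(xb), float(yf)))
    fits: dict[str, RegressionFit] = {}
    for mode, pts in by_mode.items():
        if len(pts) < 2:
            warnings.warn(f"mode {mode!r}: fewer than 2 points, regression skipped")
            continue
        x = np.array([p[0] for p in pts])
        y = np.array([p[1] for p in pts])
        slope, intercept = np.polyfit(x, y, 1)
        resid = y - (slope * x + intercept)
        fits[mode] = RegressionFit(
            mode=mode, slope=float(slope), intercept=float(intercept),
            residuals=resid, n=len(pts),
        )
    return fits


def read_depth_tsv(
    path: str | Path,
    lengths: dict[str, int],
    library_id: str = "",
) -> DepthTrack:
    """Read a 3-column TSV (scaffold, 1-based position, depth); zero rows optional."""
    scaffolds = {sid: np.zeros(n, dtype=np.int64) for sid, n in lengths.items()}
    df = pd.read_csv(
        path, sep="\t", header=None, names=["scaffold", "position", "depth"],
        dtype={"scaffold": str, "position": np.int64, "depth": np.int64},
        comment="#",
    )
    for sid, grp in df.groupby("scaffold", sort=False):
        sid = str(sid)
        if sid not in scaffolds:
            raise InputError(f"depth record on unknown scaffold {sid!r}")
        pos = grp["position"].to_numpy()
        if pos.min() < 1 or pos.max() > scaffolds[sid].size:
            raise InputError(f"position out of bounds on scaffold {sid!r}")
        scaffolds[sid][pos - 1] = grp["depth"].to_numpy()
    return DepthTrack(scaffolds=scaffolds, library_id=library_id)


def read_lengths_tsv(path: str | Path) -> dict[str, int]:
    """Read a 2-column TSV of scaffold id and length in bases."""
    df = pd.read_csv(path, sep="\t", header=None, names=["scaffold", "length"],
                     dtype={"scaffold": str, "length": np.int64}, comment="#")
    return dict(zip(df["scaffold"], df["length"].astype(int)))


def write_depth_tsv(track: DepthTrack, path: str | Path, include_zero: bool = False) -> None:
    """Write a track as 3-column TSV; by default only nonzero-depth rows."""
    with open(path, "w") as fh:
        for sid in sorted(track.scaffolds):
            a = track.scaffolds[sid]
            idx = range(a.size) if include_zero else np.nonzero(a)[0]
            for i in idx:
                fh.write(f"{sid}\t{i + 1}\t{int(a[i])}\n")


__all__.append("write_depth_tsv")
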