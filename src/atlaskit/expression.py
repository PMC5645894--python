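"""Per-gene standardization and library-correlated gene calling.

For each gene the FPKM values x_i across libraries are standardized to
z_i = (x_i - mu) / s, where mu and s are the gene's mean FPKM and standard
deviation over all libraries.  A gene is "correlated" with a library when
z > 1.5 and FPKM > 1 there: a simple, threshold-based operational definition
of library-specific expression.  The module also prepares heatmap-ready
matrices: top-k expressed gene selections, log2(FPKM + 1) transforms, the
FPKM > 100 "highly expressed" gene subset, and a deterministic
average-linkage ordering of gene rows.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import pdist, squareform

from .errors import DimensionError, DomainError, InputError
from .matrix import FpkmMatrix

__all__ = [
    "ZScoreMatrix",
    "CorrelatedGeneSets",
    "compute_zscores",
    "call_correlated_genes",
    "count_high_expression",
    "select_top_genes",
    "log_transform",
    "select_heatmap_genes",
    "cluster_order",
    "write_sets_tsv",
    "read_sets_tsv",
]

Z_MIN_DEFAULT = 1.5
FPKM_MIN_DEFAULT = 1.0
HIGH_FPKM_DEFAULT = 100.0


@dataclass
class ZScoreMatrix:
    """Standardized expression with the per-gene mean/sd retained as side columns.

    Rows with zero standard deviation carry all-zero z-scores: a constant gene
    has no library preference.
    """

    z: pd.DataFrame
    mean: pd.Series
    sd: pd.Series
    ddof: int = 1

    @property
    def gene_ids(self) -> list[str]:
        return list(self.z.index)

    @property
    def library_ids(self) -> list[str]:
        return list(self.z.columns)


@dataclass
class CorrelatedGeneSets:
    """Per-library sets of genes passing the z and FPKM thresholds."""

    sets: dict[str, set[str]]
    z_min: float = Z_MIN_DEFAULT
    fpkm_min: float = FPKM_MIN_DEFAULT
    gene_universe: list[str] = field(default_factory=list)

    @property
    def library_ids(self) -> list[str]:
        return list(self.sets)

    def sizes(self) -> pd.Series:
        return pd.Series({lib: len(s) for lib, s in self.sets.items()}, name="n_correlated")

    def census(self) -> int:
        """Number of genes correlated with at least one library."""
        out: set[str] = set()
        for s in self.sets.values():
            out |= s
        return len(out)


def compute_zscores(matrix: FpkmMatrix, ddof: int = 1) -> ZScoreMatrix:
    """Standardize each gene row across libraries.

    ddof=1 (sample standard deviation) is the default; ddof=0 switches to the
    population formula.
    """
    if matrix.n_libraries < 2:
        raise DimensionError("z-scores need at least 2 libraries")
    vals = matrix.values.to_numpy(dtype=float)
    mu = vals.mean(axis=1)
    sd = vals.std(axis=1, ddof=ddof)
    z = np.zeros_like(vals)
    ok = sd > 0
    z[ok] = (vals[ok] - mu[ok, None]) / sd[ok, None]
    zdf = pd.DataFrame(z, index=matrix.values.index, columns=matrix.values.columns)
    return ZScoreMatrix(
        z=zdf,
        mean=pd.Series(mu, index=matrix.values.index, name="mean_fpkm"),
        sd=pd.Series(sd, index=matrix.values.index, name="sd_fpkm"),
        ddof=ddof,
    )


def call_correlated_genes(
    matrix: FpkmMatrix,
    z: ZScoreMatrix | None = None,
    z_min: float = Z_MIN_DEFAULT,
    fpkm_min: float = FPKM_MIN_DEFAULT,
) -> CorrelatedGeneSets:
    """Call library-correlated genes: z > z_min and FPKM > fpkm_min, both strict."""
    if z is None:
        z = compute_zscores(matrix)
    if list(z.z.index) != matrix.gene_ids or list(z.z.columns) != matrix.library_ids:
        raise DimensionError("FPKM matrix and z-score matrix axes do not match")
    passing = (z.z.to_numpy() > z_min) & (matrix.values.to_numpy() > fpkm_min)
    genes = np.asarray(matrix.gene_ids, dtype=object)
    sets = {
        lib: set(genes[passing[:, j]])
        for j, lib in enumerate(matrix.library_ids)
    }
    return CorrelatedGeneSets(
        sets=sets, z_min=z_min, fpkm_min=fpkm_min, gene_universe=matrix.gene_ids
    )


def count_high_expression(
    matrix: FpkmMatrix,
    sets: CorrelatedGeneSets,
    threshold: float = HIGH_FPKM_DEFAULT,
) -> pd.Series:
    """Per library, how many of its correlated genes exceed `threshold` FPKM there."""
    counts = {}
    for lib, members in sets.sets.items():
        if lib not in matrix.values.columns:
            raise DimensionError(f"library {lib!r} not present in FPKM matrix")
        col = matrix.values[lib]
        counts[lib] = int((col.loc[sorted(members)] > threshold).sum()) if members else 0
    return pd.Series(counts, name=f"n_fpkm_gt_{threshold:g}")


def select_top_genes(matrix: FpkmMatrix, k: int = 3) -> list[str]:
    """Union of each library's k highest-FPKM genes, deduplicated.

    Order is first appearance, scanning libraries in column order and each
    library's picks from highest FPKM down; ties at the k-th rank are broken
    by gene input order (stable sort).
    """
    if k < 1:
        raise DomainError(f"k must be >= 1, got {k}")
    k = min(k, matrix.n_genes)
    vals = matrix.values.to_numpy(dtype=float)
    genes = matrix.gene_ids
    seen: set[str] = set()
    out: list[str] = []
    for j in range(matrix.n_libraries):
        order = np.argsort(-vals[:, j], kind="stable")[:k]
        for idx in order:
            g = genes[idx]
            if g not in seen:
                seen.add(g)
                out.append(g)
    return out


def log_transform(matrix: FpkmMatrix) -> pd.DataFrame:
    """Elementwise log2(FPKM + 1), the standard heatmap scale for expression."""
    return np.log2(matrix.values + 1.0)


def select_heatmap_genes(matrix: FpkmMatrix, threshold: float = HIGH_FPKM_DEFAULT) -> list[str]:
    """Genes with at least one FPKM value strictly above `threshold`, input order."""
    mask = (matrix.values.to_numpy(dtype=float) > threshold).any(axis=1)
    return [g for g, m in zip(matrix.gene_ids, mask) if m]


def cluster_order(z: ZScoreMatrix | pd.DataFrame) -> np.ndarray:
    """Deterministic average-linkage row ordering under correlation distance.

    Returns a permutation of gene row indices (dendrogram leaf order).  Rows
    with zero variance have undefined correlation; their pairwise distance is
    defined as 0 against an identical constant row and 1 otherwise, so that
    duplicated rows stay adjacent.  Fewer than 2 rows returns the identity.
    """
    zdf = z.z if isinstance(z, ZScoreMatrix) else z
    n = zdf.shape[0]
    if n < 2:
        return np.arange(n)
    x = zdf.to_numpy(dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        d = pdist(x, metric="correlation")
    if np.isnan(d).any():
        sq = squareform(d)
        const = x.std(axis=1) == 0
        for i in np.where(const)[0]:
            for j in range(n):
                if i == j:
                    continue
                if np.isnan(sq[i, j]):
                    sq[i, j] = sq[j, i] = 0.0 if np.array_equal(x[i], x[j]) else 1.0
        sq = np.nan_to_num(sq, nan=1.0)
        d = squareform(sq, checks=False)
    link = linkage(d, method="average")
    return np.asarray(leaves_list(link))


def write_sets_tsv(sets: CorrelatedGeneSets, path: str | Path) -> None:
    """Write correlated sets as two-column TSV rows (library_id, gene_id)."""
    rows = [
        {"library_id": lib, "gene_id": g}
        for lib in sets.sets
        for g in sorted(sets.sets[lib])
    ]
    pd.DataFrame(rows, columns=["library_id", "gene_id"]).to_csv(path, sep="\t", index=False)


def read_sets_tsv(path: str | Path) -> CorrelatedGeneSets:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns[:2]) != ["library_id", "gene_id"]:
        raise InputError("sets TSV must have columns library_id, gene_id")
    sets: dict[str, set[str]] = {}
    for lib, grp in df.groupby("library_id", sort=False):
        sets[str(lib)] = set(grp["gene_id"])
    return CorrelatedGeneSets(sets=sets)
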