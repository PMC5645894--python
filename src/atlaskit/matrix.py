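"""The gene x library FPKM matrix container and its on-disk formats.

FPKM (fragments per kilobase of transcript per million mapped reads) values
are stored genes-as-rows, libraries-as-columns in a pandas DataFrame, with
optional per-library metadata (tissue, stage, sequencing mode).  The text
layout mirrors the common supplementary-table convention: first column gene
id, header row of library names.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import DimensionError, InputError

__all__ = ["LibraryInfo", "FpkmMatrix", "read_fpkm_tsv", "read_fpkm_excel"]


@dataclass(frozen=True)
class LibraryInfo:
    """Metadata for one cDNA library.

    seq_mode is "S" for single-end or "P" for paired-end sequencing; it is a
    covariate only (e.g. for per-mode regression), never used in normalization.
    """

    library_id: str
    tissue: str = ""
    stage: str = ""
    seq_mode: str = "P"

    def __post_init__(self) -> None:
        if self.seq_mode not in ("S", "P"):
            raise InputError(
                f"library {self.library_id!r}: seq_mode must be 'S' or 'P', "
                f"got {self.seq_mode!r}"
            )


@dataclass
class FpkmMatrix:
    """Nonnegative expression values for genes (rows) across libraries (columns)."""

    values: pd.DataFrame
    library_meta: dict[str, LibraryInfo] = field(default_factory=dict)

    def __post_init__(self) -> None:
        df = self.values
        if df.index.has_duplicates:
            raise InputError("duplicated gene ids in FPKM matrix")
        if df.columns.has_duplicates:
            raise InputError("duplicated library ids in FPKM matrix")
        if df.shape[1] < 2:
            raise DimensionError(
                f"FPKM matrix needs at least 2 libraries, got {df.shape[1]}"
            )
        arr = df.to_numpy(dtype=float)
        if np.isnan(arr).any():
            raise InputError("FPKM matrix contains missing values")
        if (arr < 0).any():
            raise InputError("FPKM matrix contains negative values")
        for lib in self.library_meta:
            if lib not in df.columns:
                raise InputError(f"library_meta entry {lib!r} not a matrix column")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def library_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_libraries(self) -> int:
        return self.values.shape[1]

    def libraries_for_tissue(self, tissue: str) -> list[str]:
        """Library ids annotated with the given tissue label, in column order."""
        return [
            lib
            for lib in self.library_ids
            if lib in self.library_meta and self.library_meta[lib].tissue == tissue
        ]

    def to_tsv(self, path: str | Path, gene_column: str = "gene_id") -> None:
        out = self.values.copy()
        out.index.name = gene_column
        out.to_csv(path, sep="\t")

    def meta_frame(self) -> pd.DataFrame:
        """Library metadata as a DataFrame (tissue, stage, seq_mode), column order."""
        rows = []
        for lib in self.library_ids:
            info = self.library_meta.get(lib, LibraryInfo(lib))
            rows.append(
                {"library_id": lib, "tissue": info.tissue, "stage": info.stage,
                 "seq_mode": info.seq_mode}
            )
        return pd.DataFrame(rows).set_index("library_id")


def _from_frame(df: pd.DataFrame, meta: Mapping[str, LibraryInfo] | None) -> FpkmMatrix:
    df = df.astype(float)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return FpkmMatrix(values=df, library_meta=dict(meta or {}))


def read_fpkm_tsv(path: str | Path, meta: Mapping[str, LibraryInfo] | None = None) -> FpkmMatrix:
    """Read a tab-separated FPKM table (first column gene id, header = libraries)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return _from_frame(df, meta)


def read_fpkm_excel(
    path: str | Path,
    sheet_name: int | str = 0,
    meta: Mapping[str, LibraryInfo] | None = None,
) -> FpkmMatrix:
    """Read an .xlsx FPKM sheet laid out like the TSV format (first column gene id)."""
    df = pd.read_excel(path, sheet_name=sheet_name, index_col=0)
    return _from_frame(df, meta)
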