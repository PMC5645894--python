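"""Pairwise library similarity from correlated-gene overlap.

Two libraries X and Y with x and y correlated genes out of n total share c
genes.  Under the null hypothesis that X and Y are independent, the overlap
follows a hypergeometric law, and the tail probability of seeing at least c
shared genes is

    P = sum_{i=c}^{min(x,y)}  x! y! (n-x)! (n-y)!
                             -----------------------------------
                             n! i! (x-i)! (y-i)! (n+i-x-y)!

The probability is Bonferroni-corrected by the number of ordered pairwise
comparisons m = L x L, and reported as a "mapping score"
-log10(corrected p).  A score above 10 rejects independence; log2(score) is
the conventional plotting transform, with a score > 16 (log2 > 4) marking
closely similar libraries.

All probability work is carried out in log space via the log-gamma function:
the factorial form overflows double precision near n = 170, and for strongly
dependent pairs the corrected p-value underflows far below the smallest
subnormal double, so scores are derived from log10 p directly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

from .errors import DomainError, InputError
from .expression import CorrelatedGeneSets

__all__ = [
    "OverlapTest",
    "SimilarityMatrix",
    "overlap_pvalue",
    "overlap_log10_pvalue",
    "bonferroni_correct",
    "mapping_score",
    "n_pairwise_comparisons",
    "similarity_matrix",
    "is_dependent",
]

DEPENDENCE_THRESHOLD = 10.0
_LN10 = math.log(10.0)


@dataclass(frozen=True)
class OverlapTest:
    """One pairwise overlap test with its probabilities and mapping score."""

    n: int
    x: int
    y: int
    c: int
    p_raw: float
    p_corrected: float
    score: float


def _check_domain(n: int, x: int, y: int, c: int) -> None:
    if n < 0 or x < 0 or y < 0 or c < 0:
        raise DomainError(f"counts must be nonnegative: n={n}, x={x}, y={y}, c={c}")
    if x > n or y > n:
        raise DomainError(f"set sizes exceed gene total: n={n}, x={x}, y={y}")
    if c > min(x, y):
        raise DomainError(f"overlap c={c} exceeds min(x, y)={min(x, y)}")


def overlap_log10_pvalue(n: int, x: int, y: int, c: int) -> float:
    """log10 of the hypergeometric tail probability P(overlap >= c).

    Exact in log space; never underflows, so mapping scores remain finite and
    meaningful for arbitrarily significant overlaps.
    """
    _check_domain(n, x, y, c)
    if c == 0:
        return 0.0
    x, y = min(x, y), max(x, y)  # the formula is symmetric; canonicalize so it is exact
    i = np.arange(c, min(x, y) + 1, dtype=float)
    log_terms = (
        gammaln(x + 1.0)
        + gammaln(y + 1.0)
        + gammaln(n - x + 1.0)
        + gammaln(n - y + 1.0)
        - gammaln(n + 1.0)
        - gammaln(i + 1.0)
        - gammaln(x - i + 1.0)
        - gammaln(y - i + 1.0)
        - gammaln(n + i - x - y + 1.0)
    )
    log_p = float(logsumexp(log_terms))
    return min(log_p, 0.0) / _LN10


def overlap_pvalue(n: int, x: int, y: int, c: int) -> float:
    """Hypergeometric tail probability P(overlap >= c); see overlap_log10_pvalue."""
    return float(10.0 ** overlap_log10_pvalue(n, x, y, c))


def bonferroni_correct(p_raw: float, m: int) -> float:
    """Bonferroni-corrected p-value: min(p_raw * m, 1)."""
    if m < 1:
        raise DomainError(f"number of comparisons must be >= 1, got {m}")
    return min(p_raw * m, 1.0)


def mapping_score(p_corrected_log10: float) -> float:
    """Mapping score = -log10(corrected p), floored at 0.

    The argument is the corrected p-value in log10 space (<= 0), so extreme
    significance never underflows on the way in.
    """
    return max(0.0, -p_corrected_log10)


def n_pairwise_comparisons(n_libraries: int) -> int:
    """Number of ordered pairwise comparisons, L x L (self-pairs included)."""
    if n_libraries < 1:
        raise DomainError(f"need at least 1 library, got {n_libraries}")
    return n_libraries * n_libraries


def is_dependent(test: "OverlapTest | float", threshold: float = DEPENDENCE_THRESHOLD) -> bool:
    """Strict comparison: mapping score > threshold rejects independence."""
    score = test.score if isinstance(test, OverlapTest) else float(test)
    return score > threshold


@dataclass
class SimilarityMatrix:
    """All L x L overlap tests between libraries, on several scales.

    log2_score is NaN where the mapping score is 0 (log2 undefined); exported
    as missing rather than -inf.
    """

    library_ids: list[str]
    p_raw: pd.DataFrame
    p_corrected: pd.DataFrame
    score: pd.DataFrame
    log2_score: pd.DataFrame
    n_genes: int
    n_comparisons: int

    def pair(self, a: str, b: str, sets: CorrelatedGeneSets | None = None) -> OverlapTest:
        x = y = c = -1
        if sets is not None:
            sa, sb = sets.sets[a], sets.sets[b]
            x, y, c = len(sa), len(sb), len(sa & sb)
        return OverlapTest(
            n=self.n_genes, x=x, y=y, c=c,
            p_raw=float(self.p_raw.loc[a, b]),
            p_corrected=float(self.p_corrected.loc[a, b]),
            score=float(self.score.loc[a, b]),
        )

    def to_tsv(self, path: str | Path, layer: str = "score") -> None:
        getattr(self, layer).to_csv(path, sep="\t")


def similarity_matrix(sets: CorrelatedGeneSets, n: int) -> SimilarityMatrix:
    """Evaluate every ordered library pair, with m = L^2 Bonferroni comparisons.

    The diagonal is computed like any pair (c = x = y), so diagonal scores are
    the per-library maxima of their rows.
    """
    if n < 1:
        raise DomainError(f"total gene count must be >= 1, got {n}")
    libs = sets.library_ids
    if sets.gene_universe:
        universe = set(sets.gene_universe)
        for lib, members in sets.sets.items():
            unknown = members - universe
            if unknown:
                raise InputError(
                    f"set for library {lib!r} contains genes outside the "
                    f"universe, e.g. {sorted(unknown)[0]!r}"
                )
    for lib, members in sets.sets.items():
        if len(members) > n:
            raise InputError(f"set for library {lib!r} larger than gene total n={n}")
    L = len(libs)
    m = n_pairwise_comparisons(L)
    log10_m = math.log10(m)
    p_raw = np.ones((L, L))
    p_corr = np.ones((L, L))
    score = np.zeros((L, L))
    for a in range(L):
        sa = sets.sets[libs[a]]
        for b in range(a, L):
            sb = sets.sets[libs[b]]
            c = len(sa & sb)
            lp = overlap_log10_pvalue(n, len(sa), len(sb), c)
            lp_corr = min(lp + log10_m, 0.0)
            p_raw[a, b] = p_raw[b, a] = 10.0 ** lp
            p_corr[a, b] = p_corr[b, a] = 10.0 ** lp_corr
            score[a, b] = score[b, a] = mapping_score(lp_corr)
    with np.errstate(divide="ignore"):
        log2_score = np.where(score > 0, np.log2(np.where(score > 0, score, 1.0)), np.nan)

    def frame(arr: np.ndarray) -> pd.DataFrame:
        return pd.DataFrame(arr, index=libs, columns=libs)

    return SimilarityMatrix(
        library_ids=list(libs),
        p_raw=frame(p_raw),
        p_corrected=frame(p_corr),
        score=frame(score),
        log2_score=frame(log2_score),
        n_genes=n,
        n_comparisons=m,
    )
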