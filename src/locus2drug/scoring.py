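"""Gene scores from the evidence matrix and the biological-gene call.

A pair's score is the plain sum of its seven criterion indicators (the
nearest-gene flag never contributes); pairs scoring at least the
configured threshold (default 2) are 'biological risk genes'.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd
from scipy.stats import fisher_exact

from .evidence import CRITERIA, EvidenceVector


@dataclass(frozen=True)
class ScoreRecord:
    vector: EvidenceVector
    score: int
    biological: bool

    @property
    def pair(self):
        return self.vector.pair


def score_rows(matrix: Sequence[EvidenceVector],
               threshold: int = 2) -> list[ScoreRecord]:
    """Sum the seven indicators per row and flag biological genes."""
    return [ScoreRecord(v, sum(v.indicators()),
                        sum(v.indicators()) >= threshold)
            for v in matrix]


def select_biological(records: Sequence[ScoreRecord],
                      threshold: int) -> list[ScoreRecord]:
    """Rows scoring at least ``threshold``, original order kept."""
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    return [r for r in records if r.score >= threshold]


def distinct_genes(records: Sequence[ScoreRecord]) -> set[str]:
    """Unique gene symbols among the given score rows."""
    return {r.pair.gene for r in records}


@dataclass(frozen=True)
class NearestAssociation:
    """Nearest-gene enrichment among high- vs low-scoring pairs.

    ``table`` rows are (score >= threshold, score < threshold), columns
    (nearest, not nearest).  ``p`` is a one-sided Fisher exact p that
    high-scoring pairs are nearest more often; None when one score class
    is absent.
    """

    table: tuple[tuple[int, int], tuple[int, int]]
    prop_high: Optional[float]
    prop_low: Optional[float]
    p: Optional[float]


def nearest_gene_association(records: Sequence[ScoreRecord],
                             threshold: int = 2) -> NearestAssociation:
    hi = [r for r in records if r.score >= threshold]
    lo = [r for r in records if r.score < threshold]
    hi_near = sum(r.pair.nearest for r in hi)
    lo_near = sum(r.pair.nearest for r in lo)
    table = ((hi_near, len(hi) - hi_near), (lo_near, len(lo) - lo_near))
    prop_high = hi_near / len(hi) if hi else None
    prop_low = lo_near / len(lo) if lo else None
    p = None
    if hi and lo:
        p = float(fisher_exact(table, alternative="greater").pvalue)
    return NearestAssociation(table, prop_high, prop_low, p)


def score_report(records: Sequence[ScoreRecord]) -> pd.DataFrame:
    """Score table in the standard column order, one row per pair."""
    rows = [{"snp": r.pair.rsid, "gene": r.pair.gene,
             "nearest": int(r.pair.nearest),
             **{name: getattr(r.vector, name) for name in CRITERIA},
             "score": r.score, "biological": int(r.biological)}
            for r in records]
    return pd.DataFrame(rows, columns=["snp", "gene", "nearest", *CRITERIA,
                                       "score", "biological"])


def score_histogram(records: Sequence[ScoreRecord]) -> dict[int, int]:
    """Score value -> number of pairs (0..7)."""
    hist = {s: 0 for s in range(8)}
    for r in records:
        hist[r.score] += 1
    return hist
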