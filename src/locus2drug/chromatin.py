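"""Permutation test for risk-locus overlap with chromatin-mark peaks.

A risk locus is the lead SNP together with its qualifying LD proxies; the
locus overlaps a peak set when any member position falls inside any peak.
The observed number of overlapping loci is compared with a null obtained by
redrawing the same number of positions uniformly, without replacement, from
a user-supplied SNP universe and treating each drawn position as a
single-SNP locus.  The p estimate carries a pseudo-count,
``p = (1 + #{null >= observed}) / (1 + iterations)``, so it is never
exactly zero.  One such test is run per cell type, each with a seed derived
deterministically from the global seed and the cell-type name.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .model_io import BedInterval

Locus = tuple[str, tuple[tuple[str, int], ...]]
"""(label, ((chrom, pos), ...)) — a locus and its member SNP positions."""


@dataclass
class PeakSet:
    """Per-chromosome half-open peak intervals for one cell type.

    Point membership uses the coverage-counting identity: a position ``p``
    is covered iff #(starts <= p) > #(ends <= p), which is exact even when
    peaks overlap one another.
    """

    cell_type: str
    intervals: dict[str, list[BedInterval]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._starts: dict[str, np.ndarray] = {}
        self._ends: dict[str, np.ndarray] = {}
        for chrom, ivs in self.intervals.items():
            if any(iv.start < 0 or iv.start >= iv.end for iv in ivs):
                raise ValueError(f"{self.cell_type}/{chrom}: bad interval")
            self._starts[chrom] = np.sort(
                np.fromiter((iv.start for iv in ivs), dtype=np.int64))
            self._ends[chrom] = np.sort(
                np.fromiter((iv.end for iv in ivs), dtype=np.int64))

    def covers(self, chrom: str, positions: np.ndarray) -> np.ndarray:
        """Boolean mask: which positions on ``chrom`` fall inside a peak."""
        if chrom not in self._starts:
            return np.zeros(len(positions), dtype=bool)
        s = np.searchsorted(self._starts[chrom], positions, side="right")
        e = np.searchsorted(self._ends[chrom], positions, side="right")
        return s > e

    def covers_point(self, chrom: str, pos: int) -> bool:
        return bool(self.covers(chrom, np.array([pos]))[0])


@dataclass(frozen=True)
class PermutationResult:
    cell_type: str
    observed: int
    iterations: int
    n_ge: int
    p: float

    def __post_init__(self) -> None:
        expected = (self.n_ge + 1) / (self.iterations + 1)
        if not np.isclose(self.p, expected):
            raise ValueError("p must equal (n_ge + 1) / (iterations + 1)")


def locus_overlap_count(loci: Sequence[Locus], peaks: PeakSet) -> int:
    """Number of loci with at least one member SNP inside a peak."""
    count = 0
    for _, members in loci:
        hit = False
        for chrom, pos in members:
            if peaks.covers_point(chrom, pos):
                hit = True
                break
        if hit:
            count += 1
    return count


def _universe_coverage(universe: Sequence[tuple[str, int]],
                       peaks: PeakSet) -> np.ndarray:
    """Precomputed boolean coverage of every universe position."""
    covered = np.zeros(len(universe), dtype=bool)
    by_chrom: dict[str, list[int]] = {}
    for i, (chrom, _) in enumerate(universe):
        by_chrom.setdefault(chrom, []).append(i)
    for chrom, idx in by_chrom.items():
        pos = np.fromiter((universe[i][1] for i in idx), dtype=np.int64)
        covered[np.asarray(idx)] = peaks.covers(chrom, pos)
    return covered


def permutation_pvalue(observed: int,
                       loci: Sequence[Locus],
                       universe: Sequence[tuple[str, int]],
                       peaks: PeakSet,
                       iterations: int,
                       seed: int,
                       locus_size_matched: bool = False) -> PermutationResult:
    """Permutation p for ``observed`` overlapping loci against a SNP universe.

    Each iteration draws ``len(loci)`` positions uniformly without
    replacement and counts how many drawn single-SNP loci land inside a
    peak (with ``locus_size_matched``, each real locus is instead matched
    by a draw of its own member count, counted as one locus if any member
    lands in a peak).  Reproducible bit-for-bit given ``seed``.
    """
    n_loci = len(loci)
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    if len(universe) < n_loci:
        raise ValueError(
            f"universe ({len(universe)}) smaller than locus count ({n_loci})")
    covered = _universe_coverage(universe, peaks)
    rng = np.random.default_rng(seed)
    sizes = ([len(members) for _, members in loci]
             if locus_size_matched else [1] * n_loci)
    total = sum(sizes)
    if len(universe) < total:
        raise ValueError("universe smaller than total matched draw size")
    starts = np.cumsum([0] + sizes)[:-1]
    single = all(s == 1 for s in sizes)
    n_ge = 0
    for _ in range(iterations):
        draw = rng.choice(len(universe), size=total, replace=False)
        hits = covered[draw]
        if single:
            null_count = int(hits.sum())
        else:
            null_count = int(np.maximum.reduceat(hits, starts).sum())
        if null_count >= observed:
            n_ge += 1
    p = (n_ge + 1) / (iterations + 1)
    return PermutationResult(peaks.cell_type, observed, iterations, n_ge, p)


def celltype_seed(base_seed: int, cell_type: str) -> int:
    """Deterministic per-cell-type seed: base + stable name hash (< 2^31)."""
    digest = hashlib.blake2s(cell_type.encode()).digest()
    return (base_seed + int.from_bytes(digest[:4], "little")) % (2 ** 31)


def multi_celltype_scan(loci: Sequence[Locus],
                        universe: Sequence[tuple[str, int]],
                        peak_sets: Mapping[str, PeakSet] | Sequence[PeakSet],
                        iterations: int,
                        seed: int,
                        locus_size_matched: bool = False,
                        ) -> list[PermutationResult]:
    """One permutation test per cell type, sorted by ascending p.

    Ties in p break by cell-type name so the ordering is deterministic.
    """
    sets = (list(peak_sets.values()) if isinstance(peak_sets, Mapping)
            else list(peak_sets))
    results = []
    for ps in sets:
        obs = locus_overlap_count(loci, ps)
        results.append(permutation_pvalue(
            obs, loci, universe, ps, iterations,
            celltype_seed(seed, ps.cell_type), locus_size_matched))
    results.sort(key=lambda r: (r.p, r.cell_type))
    return results


def loci_from_bundle(bundle, cfg) -> list[Locus]:
    """Risk loci as (lead rsid, member positions) from bundle LD data.

    Members are the lead SNP plus proxies with r² strictly above the
    configured threshold; proxies without a recorded position are skipped.
    """
    loci: list[Locus] = []
    for snp in bundle.risk_snps:
        if snp.pos is None or snp.chrom is None:
            continue
        members = [(snp.chrom, snp.pos)]
        for proxy in bundle.proxies_of(snp.rsid, cfg.r2_threshold):
            if proxy.proxy_pos is not None and proxy.proxy_chrom is not None:
                members.append((proxy.proxy_chrom, proxy.proxy_pos))
        loci.append((snp.rsid, tuple(members)))
    return loci
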