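"""Candidate-gene assignment at risk loci by proximity and LD extent.

A risk locus is delimited by the span of the lead SNP and its LD proxies
(r² strictly above the configured threshold); candidate genes are those
whose bodies intersect that span, always augmented with the gene nearest
to the lead SNP, which is flagged.  Distance is measured to gene-body
edges, strand-free: zero inside the body, basepairs to the nearer edge
outside.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

from .model_io import (GeneModel, LDProxy, PipelineConfig, ResourceBundle,
                       RiskSNP, SNPGenePair)

log = logging.getLogger(__name__)


class LocusError(ValueError):
    """A locus could not be mapped (e.g. no gene on its chromosome)."""


@dataclass(frozen=True)
class LocusInterval:
    lead_rsid: str
    chrom: str
    start: int
    end: int  # half-open
    n_proxies: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("start must be <= end")


def ld_interval(lead: RiskSNP,
                proxies: Sequence[LDProxy],
                r2_threshold: float,
                flank_bp: int = 0) -> LocusInterval:
    """Half-open span of the lead plus qualifying proxies, with flanks.

    Proxies qualify at r² strictly above ``r2_threshold``; proxies on a
    different chromosome are skipped with a warning.  The span covers
    every member point position and is clipped at zero on the left.
    """
    if lead.pos is None or lead.chrom is None:
        raise LocusError(f"{lead.rsid}: lead SNP has no position")
    positions = [lead.pos]
    used = 0
    for p in proxies:
        if p.lead_rsid != lead.rsid or p.r2 <= r2_threshold:
            continue
        if p.proxy_pos is None:
            continue
        if p.proxy_chrom is not None and p.proxy_chrom != lead.chrom:
            log.warning("proxy %s of %s on %s != lead chromosome %s; skipped",
                        p.proxy_rsid, lead.rsid, p.proxy_chrom, lead.chrom)
            continue
        positions.append(p.proxy_pos)
        used += 1
    start = max(0, min(positions) - flank_bp)
    end = max(positions) + 1 + flank_bp  # +1: cover the rightmost point
    return LocusInterval(lead.rsid, lead.chrom, start, end, used)


def _distance(pos: int, gene: GeneModel) -> int:
    """Basepairs from a point to a gene body; zero inside [start, end)."""
    if gene.start <= pos < gene.end:
        return 0
    if pos < gene.start:
        return gene.start - pos
    return pos - (gene.end - 1)


def nearest_gene(snp: RiskSNP, genes: Sequence[GeneModel]) -> GeneModel:
    """Gene minimizing edge distance to the SNP on its chromosome.

    Ties break by smaller start, then lexicographic symbol.
    """
    if snp.pos is None or snp.chrom is None:
        raise LocusError(f"{snp.rsid}: SNP has no position")
    on_chrom = [g for g in genes if g.chrom == snp.chrom]
    if not on_chrom:
        raise LocusError(f"{snp.rsid}: no gene on chromosome {snp.chrom}")
    return min(on_chrom,
               key=lambda g: (_distance(snp.pos, g), g.start, g.symbol))


def map_locus_genes(lead: RiskSNP,
                    bundle: ResourceBundle,
                    cfg: PipelineConfig) -> list[SNPGenePair]:
    """Candidate SNP–gene pairs for one locus.

    Genes whose bodies intersect the LD interval, unioned with the nearest
    gene; exactly one returned pair carries ``nearest=True``.  Pairs are
    ordered by gene start, nearest-only genes appended last when outside
    the span.
    """
    interval = ld_interval(lead, bundle.ld, cfg.r2_threshold,
                           cfg.locus_flank_bp)
    near = nearest_gene(lead, bundle.genes)
    hits = [g for g in bundle.genes
            if g.chrom == interval.chrom
            and g.start < interval.end and g.end > interval.start]
    hits.sort(key=lambda g: (g.start, g.symbol))
    symbols = [g.symbol for g in hits]
    if near.symbol not in symbols:
        symbols.append(near.symbol)
    return [SNPGenePair(lead.rsid, s, nearest=(s == near.symbol))
            for s in symbols]


def map_all_loci(bundle: ResourceBundle,
                 cfg: PipelineConfig) -> tuple[list[SNPGenePair], list[str]]:
    """Candidate pairs for every risk SNP; unmappable loci are reported.

    Returns (pairs, error messages); a locus with no gene on its
    chromosome is reported, not fatal.
    """
    pairs: list[SNPGenePair] = []
    errors: list[str] = []
    seen: set[tuple[str, str]] = set()
    for snp in bundle.risk_snps:
        try:
            for pair in map_locus_genes(snp, bundle, cfg):
                key = (pair.rsid, pair.gene)
                if key not in seen:
                    seen.add(key)
                    pairs.append(pair)
        except LocusError as exc:
            errors.append(str(exc))
    return pairs, errors
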