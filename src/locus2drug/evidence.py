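"""The seven binary prioritization criteria per SNP–gene pair.

Each candidate pair is scored against seven independent lines of evidence:

1. missense — the lead SNP or an LD proxy (r² > threshold) is annotated
   as a missense variant in this gene;
2. eqtl — a qualifying cis-eQTL links the SNP (or its best present proxy)
   to this gene (FDR < 0.50, p < 0.0016, SNP–probe distance < 250 kb);
3. textmining — the gene reaches p < 0.05 in a literature-relatedness
   scan (GRAIL-style per-gene output, consumed as a table);
4. ppi_seed — the gene reaches p < 0.05 in a seed-connectivity PPI scan
   (DAPPLE-style per-gene output, consumed as a table);
5. somatic — the gene carries registered cancer somatic mutations;
6. ko_phenotype — the gene belongs to at least one knockout-mouse
   phenotype category significantly enriched among the candidates;
7. functional — likewise for pooled functional-term collections
   (GO/KEGG/OMIM-style).

All significance thresholds are strict ``<``.  Category enrichment uses
the exact hypergeometric upper tail on an explicit gene universe; an
EASE-style conservative variant (tail at overlap − 1) is available behind
a config switch.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .model_io import (PipelineConfig, ResourceBundle, SNPGenePair,
                       norm_symbol)
from .network_pharma import OverlapTest, hypergeom_upper_tail

CRITERIA = ("missense", "eqtl", "textmining", "ppi_seed",
            "somatic", "ko_phenotype", "functional")


@dataclass(frozen=True)
class EvidenceVector:
    pair: SNPGenePair
    missense: int = 0
    eqtl: int = 0
    textmining: int = 0
    ppi_seed: int = 0
    somatic: int = 0
    ko_phenotype: int = 0
    functional: int = 0

    def __post_init__(self) -> None:
        for name in CRITERIA:
            if getattr(self, name) not in (0, 1):
                raise ValueError(f"{name} must be 0 or 1")

    def indicators(self) -> tuple[int, ...]:
        return tuple(getattr(self, name) for name in CRITERIA)


@dataclass(frozen=True)
class CategoryEnrichment:
    category: str
    overlap: OverlapTest
    significant: bool


def _qualifying_rsids(pair: SNPGenePair, bundle: ResourceBundle,
                      cfg: PipelineConfig) -> set[str]:
    """Lead rsid plus proxies above the r² threshold."""
    out = {pair.rsid}
    out.update(p.proxy_rsid
               for p in bundle.proxies_of(pair.rsid, cfg.r2_threshold))
    return out


def eval_missense(pair: SNPGenePair, bundle: ResourceBundle,
                  cfg: PipelineConfig) -> int:
    """1 iff the lead or a qualifying proxy is missense in this gene."""
    rsids = _qualifying_rsids(pair, bundle, cfg)
    tab = bundle.consequences
    hit = tab[(tab["rsid"].isin(rsids))
              & (tab["gene"] == pair.gene)
              & (tab["consequence"] == "missense")]
    return int(len(hit) > 0)


def eval_eqtl(pair: SNPGenePair, bundle: ResourceBundle,
              cfg: PipelineConfig) -> int:
    """1 iff a qualifying cis-eQTL row links the pair's SNP to its gene.

    When the lead rsid is absent from the eQTL table entirely, the
    highest-r² proxy present in the table substitutes for it (ties by the
    proxy's smallest recorded SNP–probe distance, then rsid).
    """
    tab = bundle.eqtl
    present = set(tab["rsid"])
    query = pair.rsid
    if query not in present:
        candidates = []
        for p in bundle.proxies_of(pair.rsid, cfg.r2_threshold):
            if p.proxy_rsid in present:
                dmin = tab.loc[tab["rsid"] == p.proxy_rsid, "distance"].min()
                candidates.append((-p.r2, dmin, p.proxy_rsid))
        if not candidates:
            return 0
        query = min(candidates)[2]
    rows = tab[(tab["rsid"] == query) & (tab["gene"] == pair.gene)]
    ok = ((rows["fdr"] < cfg.eqtl_fdr_max)
          & (rows["p"] < cfg.eqtl_p_max)
          & (rows["distance"] < cfg.eqtl_cis_window))
    return int(ok.any())


def eval_gene_pvalue(gene: str, table: Mapping[str, float],
                     threshold: float) -> int:
    """1 iff the gene is present with p strictly below the threshold."""
    p = table.get(norm_symbol(gene))
    return int(p is not None and p < threshold)


def eval_set_membership(gene: str, gene_set: Iterable[str]) -> int:
    """Case-insensitive set membership indicator."""
    members = gene_set if isinstance(gene_set, set) else set(gene_set)
    return int(norm_symbol(gene) in members)


def enrich_categories(candidates: Iterable[str],
                      collection: Mapping[str, set[str]],
                      universe_n: int,
                      cfg: PipelineConfig) -> list[CategoryEnrichment]:
    """Hypergeometric enrichment of the candidate set in each category.

    Categories sort by ascending p (names break ties); ``significant``
    applies the strict category_p_threshold.  With ``cfg.ease_correction``
    the tail is taken at overlap − 1 (DAVID's conservative EASE variant).
    """
    cand = {norm_symbol(g) for g in candidates}
    if universe_n < len(cand):
        raise ValueError("universe smaller than candidate set")
    out = []
    for name, members in collection.items():
        if len(members) > universe_n:
            raise ValueError(f"category {name!r} larger than universe")
        test = OverlapTest(universe_n, len(members), len(cand),
                           len(cand & members))
        p = test.p_upper
        if cfg.ease_correction:
            p = hypergeom_upper_tail(universe_n, len(members), len(cand),
                                     max(test.overlap_k - 1, 0))
        out.append(CategoryEnrichment(name, test,
                                      p < cfg.category_p_threshold))
    out.sort(key=lambda e: (e.overlap.p_upper, e.category))
    return out


def eval_enriched_membership(gene: str,
                             enrichments: Sequence[CategoryEnrichment],
                             collection: Mapping[str, set[str]]) -> int:
    """1 iff the gene sits in at least one significantly enriched category."""
    g = norm_symbol(gene)
    return int(any(e.significant and g in collection[e.category]
                   for e in enrichments))


def build_evidence_matrix(pairs: Sequence[SNPGenePair],
                          bundle: ResourceBundle,
                          cfg: PipelineConfig) -> list[EvidenceVector]:
    """One evidence vector per pair; a pure function of (bundle, config).

    Category enrichment for criteria 6 and 7 is computed once over the
    distinct candidate genes and shared across rows; everything else is
    row-local, so shuffling the pair list permutes rows identically.
    """
    genes = sorted({p.gene for p in pairs})
    universe_n = bundle.universe_n()
    ko_enrich = enrich_categories(genes, bundle.ko_categories,
                                  universe_n, cfg)
    fn_enrich = enrich_categories(genes, bundle.functional_terms,
                                  universe_n, cfg)
    out = []
    for pair in pairs:
        out.append(EvidenceVector(
            pair=pair,
            missense=eval_missense(pair, bundle, cfg),
            eqtl=eval_eqtl(pair, bundle, cfg),
            textmining=eval_gene_pvalue(pair.gene, bundle.textmining_p,
                                        cfg.gene_p_threshold),
            ppi_seed=eval_gene_pvalue(pair.gene, bundle.ppi_seed_p,
                                      cfg.gene_p_threshold),
            somatic=eval_set_membership(pair.gene, bundle.somatic_genes),
            ko_phenotype=eval_enriched_membership(pair.gene, ko_enrich,
                                                  bundle.ko_categories),
            functional=eval_enriched_membership(pair.gene, fn_enrich,
                                                bundle.functional_terms)))
    return out


def matrix_to_frame(matrix: Sequence[EvidenceVector]) -> pd.DataFrame:
    """Evidence matrix as a DataFrame in the standard column order."""
    rows = [{"snp": v.pair.rsid, "gene": v.pair.gene,
             "nearest": int(v.pair.nearest),
             **{name: getattr(v, name) for name in CRITERIA}}
            for v in matrix]
    return pd.DataFrame(rows, columns=["snp", "gene", "nearest", *CRITERIA])


def criterion_correlation(matrix: Sequence[EvidenceVector]
                          ) -> tuple[pd.DataFrame, Optional[float]]:
    """Pearson correlation between the seven criterion columns.

    Returns (7×7 r table, max off-diagonal r²).  Zero-variance columns
    yield NaN entries — reported as undefined, never coerced to zero; the
    maximum r² ignores undefined pairs and is None when all are undefined.
    """
    if len(matrix) < 2:
        raise ValueError("need at least two evidence rows")
    data = pd.DataFrame([v.indicators() for v in matrix], columns=CRITERIA,
                        dtype=float)
    corr = data.corr()  # pandas leaves zero-variance columns as NaN
    np.fill_diagonal(corr.values, 1.0)
    off = corr.values[~np.eye(len(CRITERIA), dtype=bool)]
    finite = off[np.isfinite(off)]
    max_r2 = float(np.max(finite ** 2)) if finite.size else None
    return corr, max_r2
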