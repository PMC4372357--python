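"""Synthetic resource bundles with planted structure, and in-paper fixtures.

The generator emits a complete :class:`~locus2drug.model_io.ResourceBundle`
on abstract chromosomes ("chrS1"…) with known ground truth, so every
pipeline stage can be exercised and its recovery measured without any
external database.  The construction is top-down: the desired indicator
matrix is drawn first (planted genes satisfy each criterion at an elevated
rate, others at a background rate) and the criterion resources are then
built so that evidence evaluation recovers that matrix — this inverse
construction is the primary correctness harness for the evidence module.

Category-membership criteria (knockout phenotypes, functional terms) pass
through an enrichment test, so their ground-truth columns are finalized by
running the same hypergeometric rule the pipeline applies; with the
default planted effect the drawn and final columns coincide.

Also packaged here: transcriptions of the two printed tables (the 64-row
risk-SNP summary and the 35-row biological-gene evidence table) and the
drug-overlap scenario with the printed cardinalities
(N=11303, |x|=584, |y|=8, |z|=871, |x∩y|=5, |x∩z|=70).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from importlib import resources

import networkx as nx
import numpy as np
import pandas as pd

from .chromatin import PeakSet
from .evidence import CRITERIA, EvidenceVector
from .model_io import (BedInterval, GeneModel, LDProxy, PipelineConfig,
                       ResourceBundle, RiskSNP, SNPGenePair)
from .network_pharma import hypergeom_upper_tail


@dataclass
class SimulationConfig:
    """Knobs of the planted-structure generator.

    Defaults emulate the study conditions: 50 risk loci yielding a few
    candidate genes each (~140 pairs), 31 planted risk genes satisfying
    criteria at an elevated rate against a low background, 34 chromatin
    cell types with one truly enriched, and a drug table whose
    CRC-approved targets are wired to planted genes through the PPI graph.
    """

    n_genes: int = 2000
    n_loci: int = 50
    genes_per_locus_mean: float = 2.8
    criterion_rates: tuple[float, ...] = (0.05,) * 7
    planted_genes: int = 31
    elevated_rate: float = 0.8
    ppi_edge_prob: float = 0.004
    n_drug_targets: int = 150
    n_crc_targets: int = 8
    planted_link_prob: float = 0.5
    peak_coverage_bg: float = 0.05
    peak_coverage_enriched: float = 0.8
    n_cell_types: int = 34
    seed: int = 0
    # geometry / bookkeeping
    n_chroms: int = 5
    universe_snps: int = 20_000
    n_ko_categories: int = 30
    n_ko_enriched: int = 9
    n_fn_categories: int = 20
    n_fn_enriched: int = 5

    def __post_init__(self) -> None:
        probs = (*self.criterion_rates, self.elevated_rate,
                 self.ppi_edge_prob, self.planted_link_prob,
                 self.peak_coverage_bg, self.peak_coverage_enriched)
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValueError("all probabilities must lie in [0, 1]")
        if len(self.criterion_rates) != 7:
            raise ValueError("criterion_rates needs exactly 7 entries")
        if self.planted_genes > self.n_genes:
            raise ValueError("more planted genes than genes")


@dataclass
class GroundTruth:
    """What the generator planted, for recovery tests."""

    planted: set[str]
    pairs: list[SNPGenePair]
    matrix: list[EvidenceVector]            # the recoverable truth
    expected_column_sums: dict[str, float]  # from the drawn rates
    biological_genes: set[str]              # truth genes scoring >= 2
    planted_fold: float                     # CRC-drug fold implied by truth
    enriched_cell_types: set[str]

    def realized_column_sums(self) -> dict[str, int]:
        return {name: sum(getattr(v, name) for v in self.matrix)
                for name in CRITERIA}


_GENE_LEN = (5_000, 40_000)
_GENE_GAP = (10_000, 60_000)
_PEAK_WIDTH = 2_000


def _place_genes(cfg: SimulationConfig, rng: np.random.Generator
                 ) -> tuple[list[GeneModel], dict[str, int]]:
    """Non-overlapping gene bodies laid sequentially on each chromosome."""
    genes: list[GeneModel] = []
    per_chrom = cfg.n_genes // cfg.n_chroms
    chrom_len: dict[str, int] = {}
    gid = 0
    for c in range(cfg.n_chroms):
        chrom = f"chrS{c + 1}"
        pos = int(rng.integers(*_GENE_GAP))
        n_here = per_chrom + (1 if c < cfg.n_genes % cfg.n_chroms else 0)
        for _ in range(n_here):
            length = int(rng.integers(*_GENE_LEN))
            genes.append(GeneModel(f"GS{gid:05d}", chrom, pos, pos + length))
            pos += length + int(rng.integers(*_GENE_GAP))
            gid += 1
        chrom_len[chrom] = pos
    return genes, chrom_len


def _background_peaks(chrom_len: dict[str, int], coverage: float,
                      rng: np.random.Generator) -> dict[str, list[BedInterval]]:
    out: dict[str, list[BedInterval]] = {}
    for chrom, length in chrom_len.items():
        n_peaks = max(0, int(round(coverage * length / _PEAK_WIDTH)))
        starts = np.sort(rng.integers(0, max(1, length - _PEAK_WIDTH),
                                      size=n_peaks))
        out[chrom] = [BedInterval(chrom, int(s), int(s) + _PEAK_WIDTH)
                      for s in starts]
    return out


def simulate_bundle(cfg: SimulationConfig
                    ) -> tuple[ResourceBundle, GroundTruth]:
    """Generate a bundle with planted risk genes, peaks and drug links.

    Deterministic given ``cfg.seed``; raises if the requested genes cannot
    be placed.
    """
    rng = np.random.default_rng(cfg.seed)
    genes, chrom_len = _place_genes(cfg, rng)
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    chroms = sorted(by_chrom)

    # --- risk loci: runs of adjacent genes spanned by lead + proxies -----
    risk_snps: list[RiskSNP] = []
    ld: list[LDProxy] = []
    pairs: list[SNPGenePair] = []
    used: set[tuple[str, int]] = set()
    for i in range(cfg.n_loci):
        run = 1 + int(rng.poisson(max(cfg.genes_per_locus_mean - 1.0, 0.0)))
        for _attempt in range(1000):
            chrom = chroms[int(rng.integers(len(chroms)))]
            row = by_chrom[chrom]
            if len(row) < run:
                continue
            start_idx = int(rng.integers(0, len(row) - run + 1))
            span = {(chrom, j) for j in range(start_idx - 1,
                                              start_idx + run + 1)}
            if span & used:
                continue
            used |= span
            break
        else:
            raise RuntimeError("could not place locus; too few genes")
        run_genes = row[start_idx:start_idx + run]
        lead_gene = run_genes[0]
        lead_pos = int(rng.integers(lead_gene.start, lead_gene.end))
        rsid = f"rsS{i:04d}"
        risk_snps.append(RiskSNP(rsid, chrom, lead_pos, region=f"synth{i}",
                                 assoc_p=1e-8, odds_ratio=1.1))
        # two qualifying proxies pin the LD span to the gene run,
        # one sub-threshold proxy exercises the r^2 filter
        ld.append(LDProxy(rsid, f"{rsid}px1", 0.95, chrom,
                          run_genes[0].start))
        ld.append(LDProxy(rsid, f"{rsid}px2", 0.90, chrom,
                          run_genes[-1].end - 1))
        ld.append(LDProxy(rsid, f"{rsid}px0", 0.50, chrom,
                          run_genes[0].start))
        for g in run_genes:
            pairs.append(SNPGenePair(rsid, g.symbol,
                                     nearest=(g is lead_gene)))

    cand_genes = sorted({p.gene for p in pairs})
    planted = set(rng.choice(cand_genes,
                             size=min(cfg.planted_genes, len(cand_genes)),
                             replace=False).tolist())

    # --- draw the indicator matrix (pair-level 1-2, gene-level 3-7) ------
    def rate(gene: str, c: int) -> float:
        return cfg.elevated_rate if gene in planted else cfg.criterion_rates[c]

    gene_ind = {g: {CRITERIA[c]: int(rng.random() < rate(g, c))
                    for c in range(2, 7)} for g in cand_genes}
    drawn: list[dict[str, int]] = []
    for p in pairs:
        row = {"missense": int(rng.random() < rate(p.gene, 0)),
               "eqtl": int(rng.random() < rate(p.gene, 1))}
        row.update(gene_ind[p.gene])
        drawn.append(row)

    # --- criterion resources realizing the drawn matrix -----------------
    cons_rows = []
    eqtl_rows = []
    eqtl_lead_absent = {s.rsid: bool(rng.random() < 0.2) for s in risk_snps}
    for p, row in zip(pairs, drawn):
        if row["missense"]:
            # half via the lead SNP, half via a qualifying proxy
            src = p.rsid if rng.random() < 0.5 else f"{p.rsid}px1"
            cons_rows.append({"rsid": src, "gene": p.gene,
                              "consequence": "missense"})
        else:
            cons_rows.append({"rsid": p.rsid, "gene": p.gene,
                              "consequence": "intronic"})
        if row["eqtl"]:
            src = (f"{p.rsid}px1" if eqtl_lead_absent[p.rsid] else p.rsid)
            eqtl_rows.append({"rsid": src, "gene": p.gene, "p": 1e-5,
                              "fdr": 0.01, "distance": 10_000})
    consequences = pd.DataFrame(cons_rows,
                                columns=["rsid", "gene", "consequence"])
    eqtl = pd.DataFrame(eqtl_rows,
                        columns=["rsid", "gene", "p", "fdr", "distance"])

    textmining_p = {g: 0.01 for g in cand_genes
                    if gene_ind[g]["textmining"]}
    ppi_seed_p = {g: 0.01 for g in cand_genes if gene_ind[g]["ppi_seed"]}
    # sub-threshold misses appear with p above the cutoff
    for g in cand_genes:
        if not gene_ind[g]["textmining"] and rng.random() < 0.5:
            textmining_p[g] = 0.5
        if not gene_ind[g]["ppi_seed"] and rng.random() < 0.5:
            ppi_seed_p[g] = 0.5

    non_cand = [g.symbol for g in genes if g.symbol not in set(cand_genes)]
    somatic = ({g for g in cand_genes if gene_ind[g]["somatic"]}
               | set(rng.choice(non_cand, size=min(100, len(non_cand)),
                                replace=False).tolist()))

    def build_collection(col: str, n_cat: int, n_enriched: int, tag: str
                         ) -> dict[str, set[str]]:
        members = {g for g in cand_genes if gene_ind[g][col]}
        out: dict[str, set[str]] = {}
        for j in range(n_cat):
            if j < n_enriched and members:
                filler = rng.choice(non_cand, size=10, replace=False)
                out[f"{tag}{j:02d}"] = members | set(filler.tolist())
            else:
                bg = rng.choice(non_cand, size=25, replace=False)
                out[f"{tag}{j:02d}"] = set(bg.tolist())
        return out

    ko_categories = build_collection("ko_phenotype", cfg.n_ko_categories,
                                     cfg.n_ko_enriched, "ko_")
    functional_terms = build_collection("functional", cfg.n_fn_categories,
                                        cfg.n_fn_enriched, "fn_")

    # --- PPI network and drug table --------------------------------------
    net = nx.relabel_nodes(
        nx.fast_gnp_random_graph(cfg.n_genes, cfg.ppi_edge_prob,
                                 seed=int(rng.integers(2 ** 31))),
        {i: genes[i].symbol for i in range(cfg.n_genes)})
    crc_targets = rng.choice(non_cand, size=cfg.n_crc_targets,
                             replace=False).tolist()
    for pg in sorted(planted):
        for t in crc_targets:
            if rng.random() < cfg.planted_link_prob:
                net.add_edge(pg, t)
    other_pool = [g for g in non_cand if g not in set(crc_targets)]
    n_other = max(cfg.n_drug_targets - cfg.n_crc_targets, 0)
    other_targets = rng.choice(other_pool, size=n_other,
                               replace=False).tolist()
    drug_rows = [{"drug": f"crcdrug{j}", "gene": t, "status": "approved",
                  "indication": "colorectal cancer", "crc_approved": True}
                 for j, t in enumerate(crc_targets)]
    statuses = ("approved", "clinical", "experimental")
    for j, t in enumerate(other_targets):
        drug_rows.append({"drug": f"drug{j}", "gene": t,
                          "status": statuses[j % 3],
                          "indication": "other", "crc_approved": False})
    drugs = pd.DataFrame(drug_rows, columns=["drug", "gene", "status",
                                             "indication", "crc_approved"])

    # --- chromatin peaks and SNP universe --------------------------------
    universe: list[tuple[str, int]] = []
    per_chrom = cfg.universe_snps // len(chroms)
    for chrom in chroms:
        pos = np.sort(rng.integers(0, chrom_len[chrom], size=per_chrom))
        universe.extend((chrom, int(x)) for x in pos)
    peak_sets: dict[str, PeakSet] = {}
    enriched_ct = "celltype00"
    for t in range(cfg.n_cell_types):
        name = f"celltype{t:02d}"
        ivs = _background_peaks(chrom_len, cfg.peak_coverage_bg, rng)
        if name == enriched_ct:
            for s in risk_snps:
                if rng.random() < cfg.peak_coverage_enriched:
                    ivs.setdefault(s.chrom, []).append(BedInterval(
                        s.chrom, max(0, s.pos - 500), s.pos + 500))
        for chrom in ivs:
            ivs[chrom].sort(key=lambda iv: (iv.start, iv.end))
        peak_sets[name] = PeakSet(name, ivs)

    bundle = ResourceBundle(
        risk_snps=risk_snps, ld=ld, genes=genes,
        consequences=consequences, eqtl=eqtl,
        textmining_p=textmining_p, ppi_seed_p=ppi_seed_p,
        somatic_genes=somatic, ko_categories=ko_categories,
        functional_terms=functional_terms, peaks=peak_sets,
        snp_universe=universe, network=net, drugs=drugs,
        gene_universe_n=cfg.n_genes)

    # --- finalize ground truth -------------------------------------------
    truth = _finalize_truth(cfg, bundle, pairs, drawn, gene_ind, planted,
                            cand_genes, enriched_ct)
    return bundle, truth


def _finalize_truth(cfg: SimulationConfig, bundle: ResourceBundle,
                    pairs: list[SNPGenePair], drawn: list[dict[str, int]],
                    gene_ind: dict[str, dict[str, int]], planted: set[str],
                    cand_genes: list[str], enriched_ct: str) -> GroundTruth:
    # enriched-category membership is what the pipeline will see, so the
    # truth for criteria 6-7 is recomputed with the same enrichment rule
    pcfg = PipelineConfig()
    cand = set(cand_genes)

    def effective(col: str, collection: dict[str, set[str]]
                  ) -> dict[str, int]:
        flags = {}
        members_by_cat = {}
        for name, members in collection.items():
            k = len(cand & members)
            p = hypergeom_upper_tail(bundle.universe_n(), len(members),
                                     len(cand), k)
            members_by_cat[name] = (members, p < pcfg.category_p_threshold)
        for g in cand_genes:
            flags[g] = int(any(sig and g in members
                               for members, sig in members_by_cat.values()))
        return flags

    ko_eff = effective("ko_phenotype", bundle.ko_categories)
    fn_eff = effective("functional", bundle.functional_terms)
    matrix = []
    for p, row in zip(pairs, drawn):
        matrix.append(EvidenceVector(
            pair=p, missense=row["missense"], eqtl=row["eqtl"],
            textmining=row["textmining"], ppi_seed=row["ppi_seed"],
            somatic=row["somatic"], ko_phenotype=ko_eff[p.gene],
            functional=fn_eff[p.gene]))

    def rate(gene: str, c: int) -> float:
        return (cfg.elevated_rate if gene in planted
                else cfg.criterion_rates[c])

    expected = {
        "missense": sum(rate(p.gene, 0) for p in pairs),
        "eqtl": sum(rate(p.gene, 1) for p in pairs),
        **{CRITERIA[c]: sum(rate(p.gene, c) for p in pairs)
           for c in range(2, 7)}}

    bio = {p.gene for p, v in zip(pairs, matrix)
           if sum(v.indicators()) >= pcfg.score_threshold}
    planted_fold = math.nan
    if bio:
        from .network_pharma import drug_overlap_report
        rep = drug_overlap_report(
            [(p.rsid, p.gene) for p in pairs if p.gene in bio],
            bundle.network, bundle.drugs, bundle.universe_n())
        planted_fold = rep.crc_test.fold if rep.crc_test else math.nan
    enriched = ({enriched_ct}
                if cfg.peak_coverage_enriched > cfg.peak_coverage_bg
                else set())
    return GroundTruth(planted=planted, pairs=pairs, matrix=matrix,
                       expected_column_sums=expected,
                       biological_genes=bio, planted_fold=planted_fold,
                       enriched_cell_types=enriched)


def null_bundle(cfg: SimulationConfig) -> tuple[ResourceBundle, GroundTruth]:
    """A bundle with every planted effect switched off.

    All criteria run at their background rates, the chromatin coverage is
    flat across cell types, CRC drug targets are wired like any other gene
    and the planted set is empty; knockout/functional categories are drawn
    independently of candidacy (a genuine enrichment null).
    """
    ncfg = replace(cfg, elevated_rate=0.0, planted_link_prob=0.0,
                   peak_coverage_enriched=cfg.peak_coverage_bg,
                   planted_genes=0)
    # elevated_rate never applies (no planted genes); keep background rates
    bundle, truth = simulate_bundle(ncfg)
    # replace candidate-anchored categories with candidacy-independent ones
    rng = np.random.default_rng(ncfg.seed + 1)
    all_syms = [g.symbol for g in bundle.genes]
    for coll in (bundle.ko_categories, bundle.functional_terms):
        for name in coll:
            coll[name] = set(rng.choice(all_syms, size=25,
                                        replace=False).tolist())
    cand = sorted({p.gene for p in truth.pairs})
    pcfg = PipelineConfig()
    from .evidence import enrich_categories, eval_enriched_membership
    ko_e = enrich_categories(cand, bundle.ko_categories,
                             bundle.universe_n(), pcfg)
    fn_e = enrich_categories(cand, bundle.functional_terms,
                             bundle.universe_n(), pcfg)
    matrix = [replace(v,
                      ko_phenotype=eval_enriched_membership(
                          v.pair.gene, ko_e, bundle.ko_categories),
                      functional=eval_enriched_membership(
                          v.pair.gene, fn_e, bundle.functional_terms))
              for v in truth.matrix]
    truth = GroundTruth(planted=set(), pairs=truth.pairs, matrix=matrix,
                        expected_column_sums=truth.expected_column_sums,
                        biological_genes={
                            v.pair.gene for v in matrix
                            if sum(v.indicators()) >= pcfg.score_threshold},
                        planted_fold=math.nan, enriched_cell_types=set())
    return bundle, truth


# ---------------------------------------------------------------------------
# In-paper fixtures
# ---------------------------------------------------------------------------

def _data_path(name: str):
    return resources.files("locus2drug.data").joinpath(name)


def _region_chrom(region: str) -> str:
    """Cytoband → chromosome name: '8q24.2' → '8', 'Xp22.2' → 'X'."""
    for i, ch in enumerate(region):
        if ch in "pq":
            return region[:i]
    return region


def fixture_table1() -> list[RiskSNP]:
    """The 64 printed GWAS risk-allele rows (rsids repeat across studies).

    The printed summary carries no basepair positions, so ``pos`` is None
    and ``chrom`` is derived from the cytoband.  One row's printed CI has
    its bounds inverted and is stored with the CI absent.
    """
    df = pd.read_csv(_data_path("table1_risk_snps.tsv"), sep="\t",
                     dtype=str)
    out = []
    for _, r in df.iterrows():
        lo = None if pd.isna(r["ci_low"]) else float(r["ci_low"])
        hi = None if pd.isna(r["ci_high"]) else float(r["ci_high"])
        out.append(RiskSNP(rsid=r["rsid"], chrom=_region_chrom(r["region"]),
                           pos=None, region=r["region"], assoc_p=float(r["p"]),
                           odds_ratio=float(r["or"]), ci_low=lo, ci_high=hi))
    return out


@dataclass(frozen=True)
class Table2Row:
    vector: EvidenceVector
    printed_score: int
    ambiguous: bool  # the printed row's cell alignment is uncertain


def fixture_table2() -> list[Table2Row]:
    """The 35 printed biological-gene evidence rows with printed scores."""
    df = pd.read_csv(_data_path("table2_evidence.tsv"), sep="\t")
    out = []
    for _, r in df.iterrows():
        pair = SNPGenePair(r["snp"], r["gene"], nearest=bool(r["nearest"]))
        vec = EvidenceVector(pair=pair,
                             **{name: int(r[name]) for name in CRITERIA})
        out.append(Table2Row(vec, int(r["score"]), bool(r["ambiguous"])))
    return out


@dataclass
class OverlapScenario:
    """Synthetic labels realizing the printed drug-overlap cardinalities."""

    universe_n: int
    x: set[str]
    y: set[str]
    z: set[str]
    seed_pairs: list[tuple[str, str]]
    network: nx.Graph
    drugs: pd.DataFrame


def fixture_overlap_scenario() -> OverlapScenario:
    """N=11303 with |x|=584, |y|=8, |z|=871, |x∩y|=5, |x∩z|=70, y ⊆ z.

    The 31 seed genes expand to exactly 584 through a star network; gene
    labels are arbitrary, and every reported statistic depends only on the
    cardinalities.
    """
    y = [f"CRCTGT{i}" for i in range(8)]
    z_extra = [f"TGT{i:03d}" for i in range(863)]     # z \ y
    seeds = [f"SEED{i:02d}" for i in range(31)]
    # x = 31 seeds + 553 neighbors; overlaps sit among the neighbors
    neighbors = y[:5] + z_extra[:65] + [f"NBR{i:03d}" for i in range(483)]
    assert len(neighbors) == 553
    net = nx.Graph()
    net.add_nodes_from(seeds)
    for n in neighbors:
        net.add_edge(seeds[0], n)
    drug_rows = [{"drug": f"crcdrug{i}", "gene": g, "status": "approved",
                  "indication": "colorectal cancer", "crc_approved": True}
                 for i, g in enumerate(y)]
    drug_rows += [{"drug": f"drug{i}", "gene": g, "status": "approved",
                   "indication": "other", "crc_approved": False}
                  for i, g in enumerate(z_extra)]
    drugs = pd.DataFrame(drug_rows, columns=["drug", "gene", "status",
                                             "indication", "crc_approved"])
    seed_pairs = [(f"rsF{i:02d}", g) for i, g in enumerate(seeds)]
    return OverlapScenario(universe_n=11303,
                           x=set(seeds) | set(neighbors),
                           y=set(y), z=set(y) | set(z_extra),
                           seed_pairs=seed_pairs, network=net, drugs=drugs)
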