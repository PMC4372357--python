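"""Domain types and file I/O for every table the pipeline touches.

All genomic coordinates are held internally as 0-based half-open intervals
(the BED convention).  GWAS, eQTL and SNP-universe positions arrive 1-based
and are converted exactly once, at the parsing boundary, via
:func:`pos_1based_to_internal`.  Gene identity is the upper-cased symbol
string throughout; there is no identifier-mapping service.

Tables are tab-separated with a header line; intervals are BED3/BED4; gene
sets are GMT.  Every reader has a matching writer and the pair round-trips.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import networkx as nx
import pandas as pd
import yaml


class FormatError(ValueError):
    """A file violates the expected table format (e.g. a missing column)."""


class RowError(ValueError):
    """A single row is malformed; the message carries the line number."""


def pos_1based_to_internal(pos: int) -> int:
    """Map a 1-based position ``p`` to the half-open interval start ``p - 1``.

    A 1-based point position occupies the internal interval ``[p-1, p)``.
    """
    if pos < 1:
        raise ValueError(f"1-based position must be >= 1, got {pos}")
    return pos - 1


def norm_symbol(symbol: str) -> str:
    """Canonical gene symbol: stripped and upper-cased."""
    return symbol.strip().upper()


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RiskSNP:
    """One GWAS association row: a risk SNP with its summary statistics.

    ``pos`` is the internal 0-based coordinate (``None`` when the source
    table, like a printed summary table, carries no position).  Confidence
    interval bounds are optional; a malformed CI is recorded as absent.
    """

    rsid: str
    chrom: Optional[str] = None
    pos: Optional[int] = None
    region: str = ""
    assoc_p: float = math.nan
    odds_ratio: float = math.nan
    ci_low: Optional[float] = None
    ci_high: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.rsid:
            raise ValueError("rsid must be nonempty")
        if self.pos is not None and self.pos < 0:
            raise ValueError(f"{self.rsid}: internal position must be >= 0")
        if (
            self.ci_low is not None
            and self.ci_high is not None
            and self.ci_low > self.ci_high
        ):
            raise ValueError(f"{self.rsid}: ci_low > ci_high")


@dataclass(frozen=True)
class LDProxy:
    """A proxy SNP tagging a lead SNP at squared correlation ``r2``."""

    lead_rsid: str
    proxy_rsid: str
    r2: float
    proxy_chrom: Optional[str] = None
    proxy_pos: Optional[int] = None  # internal 0-based

    def __post_init__(self) -> None:
        if not 0.0 <= self.r2 <= 1.0:
            raise ValueError(f"r2 must be in [0, 1], got {self.r2}")


@dataclass(frozen=True)
class GeneModel:
    """A gene body on a chromosome, 0-based half-open, strand-agnostic."""

    symbol: str
    chrom: str
    start: int
    end: int
    strand: str = "unknown"

    def __post_init__(self) -> None:
        object.__setattr__(self, "symbol", norm_symbol(self.symbol))
        if self.start >= self.end:
            raise ValueError(f"{self.symbol}: start must be < end")
        if self.strand not in {"+", "-", "unknown"}:
            raise ValueError(f"{self.symbol}: bad strand {self.strand!r}")


@dataclass(frozen=True)
class SNPGenePair:
    """A candidate (risk SNP, gene) pair; ``nearest`` marks the closest gene."""

    rsid: str
    gene: str
    nearest: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "gene", norm_symbol(self.gene))


@dataclass
class PipelineConfig:
    """Tunable thresholds and run parameters for the whole pipeline.

    Defaults encode the analysis conditions: LD proxies qualify at
    r² strictly above 0.80; cis-eQTL rows qualify at FDR < 0.50,
    p < 0.0016 and SNP–probe distance < 250 kb; per-gene p-value criteria
    and category enrichment use strict p < 0.05; genes scoring at least 2
    of the 7 criteria are called biological risk genes; the chromatin
    permutation test runs 10^5 iterations.
    """

    r2_threshold: float = 0.80
    eqtl_fdr_max: float = 0.50
    eqtl_p_max: float = 0.0016
    eqtl_cis_window: int = 250_000
    gene_p_threshold: float = 0.05
    category_p_threshold: float = 0.05
    score_threshold: int = 2
    permutation_iters: int = 100_000
    rng_seed: int = 0
    locus_flank_bp: int = 0
    # EASE-style conservative tail (overlap - 1) for term enrichment
    ease_correction: bool = False
    # chromatin null: sample |members| positions per locus instead of one
    locus_size_matched_null: bool = False
    # Fisher comparison of CRC vs all drug targets: compare y against z \ y
    # (default) or against z as given
    fisher_exclude_y_from_z: bool = True

    def __post_init__(self) -> None:
        for name in ("r2_threshold", "eqtl_fdr_max", "eqtl_p_max",
                     "gene_p_threshold", "category_p_threshold"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.permutation_iters < 1:
            raise ValueError("permutation_iters must be >= 1")
        if self.score_threshold < 0:
            raise ValueError("score_threshold must be >= 0")
        if self.eqtl_cis_window < 0 or self.locus_flank_bp < 0:
            raise ValueError("window/flank must be >= 0")


@dataclass
class ResourceBundle:
    """Every data resource one pipeline run consumes.

    DataFrame columns:

    * ``consequences``: rsid, gene, consequence
    * ``eqtl``: rsid, gene, p, fdr, distance (bp, nonnegative)
    * ``drugs``: drug, gene, status, indication, crc_approved
    """

    risk_snps: list[RiskSNP] = field(default_factory=list)
    ld: list[LDProxy] = field(default_factory=list)
    genes: list[GeneModel] = field(default_factory=list)
    consequences: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["rsid", "gene", "consequence"]))
    eqtl: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["rsid", "gene", "p", "fdr", "distance"]))
    textmining_p: dict[str, float] = field(default_factory=dict)
    ppi_seed_p: dict[str, float] = field(default_factory=dict)
    somatic_genes: set[str] = field(default_factory=set)
    ko_categories: dict[str, set[str]] = field(default_factory=dict)
    functional_terms: dict[str, set[str]] = field(default_factory=dict)
    peaks: dict[str, "object"] = field(default_factory=dict)  # cell type -> PeakSet
    snp_universe: list[tuple[str, int]] = field(default_factory=list)
    network: nx.Graph = field(default_factory=nx.Graph)
    drugs: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["drug", "gene", "status", "indication", "crc_approved"]))
    gene_universe_n: Optional[int] = None

    def universe_n(self) -> int:
        """The hypergeometric universe size N.

        Defaults to the PPI node count when not set explicitly; the true N
        is a property of the interactome snapshot, not derivable from the
        bundle, so real analyses should set it.
        """
        if self.gene_universe_n is not None:
            return self.gene_universe_n
        return self.network.number_of_nodes()

    def proxies_of(self, rsid: str, r2_threshold: float) -> list[LDProxy]:
        """Proxies of ``rsid`` with r² strictly above the threshold."""
        return [p for p in self.ld
                if p.lead_rsid == rsid and p.r2 > r2_threshold]


# ---------------------------------------------------------------------------
# BED intervals
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BedInterval:
    chrom: str
    start: int
    end: int
    name: str = ""


def read_bed(path: str | Path) -> dict[str, list[BedInterval]]:
    """Read a BED3/BED4 file into per-chromosome, start-sorted intervals.

    Overlapping intervals are retained, never merged.
    """
    out: dict[str, list[BedInterval]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise RowError(f"line {lineno}: expected >= 3 BED columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise RowError(
                    f"line {lineno}: non-integer coordinates") from exc
            if start >= end:
                raise RowError(f"line {lineno}: start >= end ({start} >= {end})")
            name = fields[3] if len(fields) > 3 else ""
            out.setdefault(chrom, []).append(
                BedInterval(chrom, start, end, name))
    for chrom in out:
        out[chrom].sort(key=lambda iv: (iv.start, iv.end, iv.name))
    return out


def write_bed(intervals: Mapping[str, Sequence[BedInterval]],
              path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(intervals):
            for iv in sorted(intervals[chrom],
                             key=lambda iv: (iv.start, iv.end, iv.name)):
                cols = [iv.chrom, str(iv.start), str(iv.end)]
                if iv.name:
                    cols.append(iv.name)
                fh.write("\t".join(cols) + "\n")


# ---------------------------------------------------------------------------
# GWAS table
# ---------------------------------------------------------------------------

_GWAS_REQUIRED = ("rsid", "chrom", "pos", "p", "or")


def read_gwas_table(path: str | Path) -> list[RiskSNP]:
    """Read a GWAS risk-SNP table (TSV with header).

    Mandatory columns: rsid, chrom, pos (1-based), p, or.  Optional:
    region, ci_low, ci_high.  Malformed CI fields become absent, not
    errors; an unparsable p or OR is a row error with its line number.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    df.columns = [c.strip().lower() for c in df.columns]
    for col in _GWAS_REQUIRED:
        if col not in df.columns:
            raise FormatError(f"missing mandatory column {col!r}")
    out = []
    for i, row in df.iterrows():
        lineno = i + 2  # header is line 1
        try:
            p = float(row["p"])
            odds = float(row["or"])
            pos = int(row["pos"])
        except (TypeError, ValueError) as exc:
            raise RowError(f"line {lineno}: unparsable field: {exc}") from exc
        ci_low = ci_high = None
        try:
            lo = float(row.get("ci_low"))
            hi = float(row.get("ci_high"))
            if math.isfinite(lo) and math.isfinite(hi) and lo <= hi:
                ci_low, ci_high = lo, hi
        except (TypeError, ValueError):
            pass
        out.append(RiskSNP(
            rsid=str(row["rsid"]).strip(),
            chrom=str(row["chrom"]).strip(),
            pos=pos_1based_to_internal(pos),
            region=str(row["region"]).strip() if "region" in df.columns
            and pd.notna(row.get("region")) else "",
            assoc_p=p, odds_ratio=odds, ci_low=ci_low, ci_high=ci_high))
    return out


def write_gwas_table(snps: Sequence[RiskSNP], path: str | Path) -> None:
    rows = []
    for s in snps:
        rows.append({
            "rsid": s.rsid, "chrom": s.chrom,
            "pos": "" if s.pos is None else s.pos + 1,  # back to 1-based
            "region": s.region, "p": repr(s.assoc_p), "or": repr(s.odds_ratio),
            "ci_low": "" if s.ci_low is None else repr(s.ci_low),
            "ci_high": "" if s.ci_high is None else repr(s.ci_high)})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def dedup_risk_snps(snps: Sequence[RiskSNP]) -> list[RiskSNP]:
    """Collapse repeated rsids, keeping each rsid's smallest-p record.

    Order of first appearance is preserved; the operation is idempotent and
    never lengthens the list.
    """
    best: dict[str, RiskSNP] = {}
    order: list[str] = []
    for s in snps:
        if s.rsid not in best:
            best[s.rsid] = s
            order.append(s.rsid)
        elif s.assoc_p < best[s.rsid].assoc_p:
            best[s.rsid] = s
    return [best[r] for r in order]


# ---------------------------------------------------------------------------
# LD, consequences, eQTL, per-gene p tables
# ---------------------------------------------------------------------------

def read_ld_table(path: str | Path) -> list[LDProxy]:
    """TSV: lead_rsid, proxy_rsid, r2, [proxy_chrom, proxy_pos (1-based)]."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    df.columns = [c.strip().lower() for c in df.columns]
    for col in ("lead_rsid", "proxy_rsid", "r2"):
        if col not in df.columns:
            raise FormatError(f"missing mandatory column {col!r}")
    out = []
    for i, row in df.iterrows():
        try:
            r2 = float(row["r2"])
        except (TypeError, ValueError) as exc:
            raise RowError(f"line {i + 2}: unparsable r2") from exc
        pos = None
        if "proxy_pos" in df.columns and pd.notna(row["proxy_pos"]):
            pos = pos_1based_to_internal(int(row["proxy_pos"]))
        chrom = None
        if "proxy_chrom" in df.columns and pd.notna(row["proxy_chrom"]):
            chrom = str(row["proxy_chrom"]).strip()
        out.append(LDProxy(str(row["lead_rsid"]).strip(),
                           str(row["proxy_rsid"]).strip(), r2, chrom, pos))
    return out


def write_ld_table(proxies: Sequence[LDProxy], path: str | Path) -> None:
    rows = [{"lead_rsid": p.lead_rsid, "proxy_rsid": p.proxy_rsid,
             "r2": repr(p.r2),
             "proxy_chrom": p.proxy_chrom or "",
             "proxy_pos": "" if p.proxy_pos is None else p.proxy_pos + 1}
            for p in proxies]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_consequence_table(path: str | Path) -> pd.DataFrame:
    """Variant-consequence rows (ANNOVAR-style): rsid, gene, consequence."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    df.columns = [c.strip().lower() for c in df.columns]
    for col in ("rsid", "gene", "consequence"):
        if col not in df.columns:
            raise FormatError(f"missing mandatory column {col!r}")
    df["gene"] = df["gene"].map(norm_symbol)
    df["consequence"] = df["consequence"].str.strip().str.lower()
    return df[["rsid", "gene", "consequence"]]


def read_eqtl_table(path: str | Path) -> pd.DataFrame:
    """cis-eQTL associations: rsid, gene, p, fdr, distance (bp)."""
    df = pd.read_csv(path, sep="\t")
    df.columns = [c.strip().lower() for c in df.columns]
    for col in ("rsid", "gene", "p", "fdr", "distance"):
        if col not in df.columns:
            raise FormatError(f"missing mandatory column {col!r}")
    df["gene"] = df["gene"].astype(str).map(norm_symbol)
    df["rsid"] = df["rsid"].astype(str).str.strip()
    return df[["rsid", "gene", "p", "fdr", "distance"]]


def read_gene_pvalues(path: str | Path) -> dict[str, float]:
    """Per-gene p-value table (GRAIL- or DAPPLE-style output): gene, p."""
    df = pd.read_csv(path, sep="\t")
    df.columns = [c.strip().lower() for c in df.columns]
    for col in ("gene", "p"):
        if col not in df.columns:
            raise FormatError(f"missing mandatory column {col!r}")
    return {norm_symbol(str(g)): float(p)
            for g, p in zip(df["gene"], df["p"])}


def write_gene_pvalues(table: Mapping[str, float], path: str | Path) -> None:
    pd.DataFrame({"gene": list(table), "p": [repr(table[g]) for g in table]}
                 ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Gene sets (GMT)
# ---------------------------------------------------------------------------

def read_gene_sets(path: str | Path) -> dict[str, set[str]]:
    """Read a GMT file: name, description, then member symbols.

    Symbols are upper-cased and duplicates collapsed; a repeated set name
    or a line with fewer than three fields is an error.
    """
    out: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise RowError(
                    f"line {lineno}: GMT line needs name, description and "
                    f"at least one member")
            name = fields[0].strip()
            if name in out:
                raise FormatError(f"duplicate gene-set name {name!r}")
            members = {norm_symbol(s) for s in fields[2:] if s.strip()}
            if not members:
                raise RowError(f"line {lineno}: empty member list")
            out[name] = members
    return out


def write_gene_sets(collection: Mapping[str, Iterable[str]],
                    path: str | Path) -> None:
    with open(path, "w") as fh:
        for name in collection:
            members = sorted({norm_symbol(s) for s in collection[name]})
            fh.write("\t".join([name, "na"] + members) + "\n")


# ---------------------------------------------------------------------------
# PPI edge list
# ---------------------------------------------------------------------------

def read_edge_list(path: str | Path) -> nx.Graph:
    """Two-column TSV of interacting gene symbols -> undirected graph.

    Self-loops are dropped and duplicate edges (either orientation)
    collapse; extra columns are ignored.
    """
    g = nx.Graph()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2 or not fields[0].strip() or not fields[1].strip():
                raise RowError(f"line {lineno}: need two nonblank symbols")
            a, b = norm_symbol(fields[0]), norm_symbol(fields[1])
            if a == b:
                g.add_node(a)  # self-loop dropped, node kept
                continue
            g.add_edge(a, b)
    return g


def write_edge_list(g: nx.Graph, path: str | Path) -> None:
    with open(path, "w") as fh:
        for a, b in sorted(tuple(sorted(e)) for e in g.edges()):
            fh.write(f"{a}\t{b}\n")
        # isolated nodes survive a round trip as degenerate comment records
        for n in sorted(g.nodes()):
            if g.degree(n) == 0:
                fh.write(f"{n}\t{n}\n")


# ---------------------------------------------------------------------------
# Drug-target table
# ---------------------------------------------------------------------------

_DRUG_STATUSES = {"approved", "clinical", "experimental"}


def read_drug_table(path: str | Path) -> pd.DataFrame:
    """Drug–target rows: drug, gene, status, indication, crc_approved.

    ``status`` must be approved/clinical/experimental; ``crc_approved`` is
    0/1 and marks targets of drugs approved for colorectal cancer.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    df.columns = [c.strip().lower() for c in df.columns]
    for col in ("drug", "gene", "status"):
        if col not in df.columns:
            raise FormatError(f"missing mandatory column {col!r}")
    df["gene"] = df["gene"].map(norm_symbol)
    df["status"] = df["status"].str.strip().str.lower()
    bad = ~df["status"].isin(_DRUG_STATUSES)
    if bad.any():
        lineno = int(bad.idxmax()) + 2
        raise RowError(
            f"line {lineno}: unknown status {df.loc[bad.idxmax(), 'status']!r}")
    if "indication" not in df.columns:
        df["indication"] = ""
    df["indication"] = df["indication"].fillna("")
    if "crc_approved" in df.columns:
        df["crc_approved"] = df["crc_approved"].fillna("0").astype(int).astype(bool)
    else:
        df["crc_approved"] = False
    return df[["drug", "gene", "status", "indication", "crc_approved"]]


def drug_target_genes(drugs: pd.DataFrame,
                      status: Optional[str] = None,
                      crc_approved: Optional[bool] = None) -> set[str]:
    """Distinct target-gene symbols, optionally filtered."""
    df = drugs
    if status is not None:
        df = df[df["status"] == status]
    if crc_approved is not None:
        df = df[df["crc_approved"] == crc_approved]
    return set(df["gene"])


# ---------------------------------------------------------------------------
# SNP universe and configuration
# ---------------------------------------------------------------------------

def read_snp_universe(path: str | Path) -> list[tuple[str, int]]:
    """Two-column TSV (chrom, pos 1-based) -> internal (chrom, pos) list."""
    out = []
    with open(path) as fh:
        header = fh.readline()
        if not header.lower().startswith("chrom"):
            raise FormatError("SNP universe needs a 'chrom<TAB>pos' header")
        for lineno, line in enumerate(fh, 2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise RowError(f"line {lineno}: need chrom and pos")
            out.append((fields[0], pos_1based_to_internal(int(fields[1]))))
    return out


def write_snp_universe(universe: Sequence[tuple[str, int]],
                       path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tpos\n")
        for chrom, pos in universe:
            fh.write(f"{chrom}\t{pos + 1}\n")


def read_config(path: str | Path) -> PipelineConfig:
    """Load a YAML config whose keys mirror PipelineConfig field names."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(data) - known
    if unknown:
        raise FormatError(f"unknown config keys: {sorted(unknown)}")
    return PipelineConfig(**data)


def write_config(cfg: PipelineConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(dataclasses.asdict(cfg), fh, sort_keys=False)
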