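"""Drug-target overlap enrichment over the one-hop PPI neighborhood.

Let x be the biological risk genes together with all their direct PPI
neighbors, y the targets of approved colorectal-cancer drugs and z the
targets of all approved/clinical/experimental drugs.  Overlaps of x with y
and with z are scored against a hypergeometric null on an N-gene universe:
expected count K·n/N, fold enrichment k / expected, and the exact upper
tail P(X ≥ k).  The relative fold (k_y/K_y)/(k_z/K_z) compares how much
more concentrated the CRC-drug targets are inside x than drug targets at
large, with a one-sided Fisher exact test on the corresponding 2×2 table.

The hypergeometric tail here is the shared exact engine for every overlap
test in the package.  It is evaluated in log space from log-factorials
(``gammaln``), never via a normal or binomial approximation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import networkx as nx
import pandas as pd
from scipy.special import gammaln
from scipy.stats import fisher_exact

from .model_io import norm_symbol


def _log_comb(n: int, k: int) -> float:
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def hypergeom_upper_tail(N: int, K: int, n: int, k: int) -> float:
    """Exact P(X >= k) for X ~ Hypergeometric(N, K, n).

    Summed in log space from log-factorials over the achievable tail
    k..min(K, n); k <= 0 returns 1.0 exactly.
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"need 0 <= K, n <= N; got N={N}, K={K}, n={n}")
    if k > min(K, n):
        raise ValueError(f"k={k} exceeds min(K, n)={min(K, n)}")
    if k <= 0:
        return 1.0
    log_denom = _log_comb(N, n)
    total = 0.0
    for j in range(k, min(K, n) + 1):
        if n - j > N - K:
            continue  # unachievable: not enough non-category genes
        total += math.exp(_log_comb(K, j) + _log_comb(N - K, n - j)
                          - log_denom)
    return min(total, 1.0)


@dataclass(frozen=True)
class OverlapTest:
    """One hypergeometric set-overlap test and its summary statistics."""

    universe_n: int
    category_k: int
    draw_n: int
    overlap_k: int
    expected: float = field(init=False)
    fold: float = field(init=False)
    p_upper: float = field(init=False)

    def __post_init__(self) -> None:
        N, K, n, k = (self.universe_n, self.category_k,
                      self.draw_n, self.overlap_k)
        if not (0 <= k <= min(K, n)):
            raise ValueError(f"need 0 <= k <= min(K, n); got k={k}")
        if K > N or n > N:
            raise ValueError("category and draw must fit in the universe")
        expected = K * n / N
        object.__setattr__(self, "expected", expected)
        object.__setattr__(self, "fold",
                           k / expected if expected > 0 else math.nan)
        object.__setattr__(self, "p_upper", hypergeom_upper_tail(N, K, n, k))


def overlap_test(universe_n: int,
                 category: Iterable[str],
                 draw: Iterable[str]) -> OverlapTest:
    """Overlap of two symbol sets within an N-gene universe."""
    cat = {norm_symbol(s) for s in category}
    drw = {norm_symbol(s) for s in draw}
    if len(cat) > universe_n or len(drw) > universe_n:
        raise ValueError("universe smaller than a set")
    return OverlapTest(universe_n, len(cat), len(drw), len(cat & drw))


def one_hop_expand(seeds: Iterable[str], network: nx.Graph) -> set[str]:
    """Seeds plus every direct PPI neighbor of any seed (one hop only)."""
    seed_set = {norm_symbol(s) for s in seeds}
    out = set(seed_set)
    for s in seed_set:
        if s in network:
            out.update(network.neighbors(s))
    return out


def relative_fold(test_y: OverlapTest, test_z: OverlapTest) -> float:
    """(k_y/K_y) / (k_z/K_z): CRC-drug target concentration vs all drugs."""
    if test_z.overlap_k == 0 or test_y.category_k == 0:
        return math.nan
    return ((test_y.overlap_k / test_y.category_k)
            / (test_z.overlap_k / test_z.category_k))


def compare_target_sets(test_y: OverlapTest,
                        test_z: OverlapTest,
                        exclude_y_from_z: bool = True) -> float:
    """One-sided Fisher exact p that y's in-network fraction exceeds z's.

    Table [[k_y, K_y - k_y], [k_z', K_z' - k_z']]; with
    ``exclude_y_from_z`` the second row uses z \\ y counts so the two rows
    are disjoint (y is a subset of z in the drug tables).
    """
    ky, Ky = test_y.overlap_k, test_y.category_k
    kz, Kz = test_z.overlap_k, test_z.category_k
    if exclude_y_from_z:
        kz, Kz = kz - ky, Kz - Ky
    table = [[ky, Ky - ky], [kz, Kz - kz]]
    if any(c < 0 for row in table for c in row):
        raise ValueError(f"negative cell in {table}")
    return float(fisher_exact(table, alternative="greater").pvalue)


@dataclass
class DrugOverlapReport:
    x_set: set[str]
    crc_test: Optional[OverlapTest]
    all_test: Optional[OverlapTest]
    relative_fold: float
    comparison_p: float
    connections: pd.DataFrame  # snp, risk_gene, ppi_gene, drug, indication


def connection_paths(seed_pairs: Sequence[tuple[str, str]],
                     network: nx.Graph,
                     drugs: pd.DataFrame,
                     x_set: set[str]) -> pd.DataFrame:
    """Flat (snp, risk gene, PPI gene, drug) paths behind the overlaps.

    For every drug whose target lies in x, emit the path risk SNP → risk
    gene → targeted gene → drug; the targeted gene is either the risk gene
    itself or one of its direct neighbors.  Paths deduplicate on
    (risk gene, PPI gene, drug) and sort lexicographically.
    """
    rows = []
    seen = set()
    gene_to_snps: dict[str, list[str]] = {}
    for rsid, gene in seed_pairs:
        gene_to_snps.setdefault(norm_symbol(gene), []).append(rsid)
    targets = drugs[drugs["gene"].isin(x_set)]
    for _, drow in targets.iterrows():
        target, drug = drow["gene"], drow["drug"]
        for risk_gene, rsids in gene_to_snps.items():
            linked = (target == risk_gene
                      or (risk_gene in network
                          and network.has_edge(risk_gene, target)))
            if not linked:
                continue
            key = (risk_gene, target, drug)
            if key in seen:
                continue
            seen.add(key)
            rows.append({"snp": sorted(rsids)[0], "risk_gene": risk_gene,
                         "ppi_gene": target, "drug": drug,
                         "indication": drow.get("indication", "")})
    df = pd.DataFrame(rows, columns=["snp", "risk_gene", "ppi_gene",
                                     "drug", "indication"])
    return df.sort_values(["risk_gene", "ppi_gene", "drug"],
                          ignore_index=True)


def drug_overlap_report(seed_pairs: Sequence[tuple[str, str]],
                        network: nx.Graph,
                        drugs: pd.DataFrame,
                        universe_n: int,
                        exclude_y_from_z: bool = True) -> DrugOverlapReport:
    """The full drug-target enrichment report.

    ``seed_pairs`` are (rsid, gene) rows for the biological risk genes;
    distinct genes seed the one-hop expansion.  An empty seed set yields a
    flagged report with no tests.
    """
    seeds = {norm_symbol(g) for _, g in seed_pairs}
    if not seeds:
        return DrugOverlapReport(set(), None, None, math.nan, math.nan,
                                 connection_paths([], network, drugs, set()))
    x = one_hop_expand(seeds, network)
    y = set(drugs.loc[drugs["crc_approved"], "gene"])
    z = set(drugs["gene"])
    crc = overlap_test(universe_n, y, x)
    al = overlap_test(universe_n, z, x)
    rel = relative_fold(crc, al)
    comp = (compare_target_sets(crc, al, exclude_y_from_z)
            if al.overlap_k > 0 else math.nan)
    return DrugOverlapReport(
        x, crc, al, rel, comp,
        connection_paths(list(seed_pairs), network, drugs, x))


def export_dot(connections: pd.DataFrame) -> str:
    """GraphViz DOT text for the bipartite risk-gene → drug connection map."""
    lines = ["graph drug_connections {"]
    for _, r in connections.iterrows():
        lines.append(f'  "{r.risk_gene}" -- "{r.ppi_gene}";')
        lines.append(f'  "{r.ppi_gene}" -- "drug:{r.drug}";')
    lines.append("}")
    return "\n".join(dict.fromkeys(lines))  # dedup, order-preserving
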