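import math
from fractions import Fraction

import pytest

from locus2drug.model_io import PipelineConfig
from locus2drug.synthetic import SimulationConfig, simulate_bundle


def enum_hypergeom_tail(N: int, K: int, n: int, k: int) -> float:
    """Brute-force exact upper tail by direct pmf enumeration (Fraction)."""
    total = Fraction(0)
    denom = math.comb(N, n)
    for j in range(max(k, 0), min(K, n) + 1):
        if n - j > N - K:
            continue
        total += Fraction(math.comb(K, j) * math.comb(N - K, n - j), denom)
    return float(min(total, Fraction(1)))


def enum_fisher_greater(a: int, b: int, c: int, d: int) -> float:
    """One-sided Fisher exact p by enumerating tables with fixed margins."""
    row1, col1, total = a + b, a + c, a + b + c + d
    p = Fraction(0)
    denom = math.comb(total, col1)
    for a2 in range(a, min(row1, col1) + 1):
        c2 = col1 - a2
        if c2 < 0 or c2 > c + d:
            continue
        p += Fraction(math.comb(row1, a2) * math.comb(c + d, c2), denom)
    return float(min(p, Fraction(1)))


@pytest.fixture(scope="session")
def pipeline_cfg() -> PipelineConfig:
    return PipelineConfig()


@pytest.fixture(scope="session")
def small_sim():
    """One small planted bundle shared across read-only tests."""
    cfg = SimulationConfig(seed=42, n_genes=600, n_loci=20,
                           planted_genes=12, n_cell_types=3,
                           universe_snps=4000, n_drug_targets=60,
                           n_crc_targets=6)
    bundle, truth = simulate_bundle(cfg)
    return cfg, bundle, truth
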