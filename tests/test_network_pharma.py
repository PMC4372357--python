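import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import hypergeom

from conftest import enum_fisher_greater, enum_hypergeom_tail
from locus2drug.network_pharma import (OverlapTest, compare_target_sets,
                                       drug_overlap_report, export_dot,
                                       hypergeom_upper_tail, one_hop_expand,
                                       overlap_test, relative_fold)
from locus2drug.synthetic import fixture_overlap_scenario


class TestOneHopExpand:
    def test_one_hop_only(self):
        g = nx.Graph([("A", "B"), ("B", "C")])
        assert one_hop_expand({"A"}, g) == {"A", "B"}

    def test_seeds_without_edges_survive(self):
        g = nx.Graph([("X", "Y")])
        assert one_hop_expand({"A", "B"}, g) == {"A", "B"}

    def test_orientation_and_order_invariance(self):
        edges = [("A", "B"), ("B", "C"), ("C", "D"), ("A", "D")]
        g1 = nx.Graph(edges)
        g2 = nx.Graph([(b, a) for a, b in reversed(edges)])
        assert one_hop_expand({"A"}, g1) == one_hop_expand({"A"}, g2)

    def test_scenario_expands_31_seeds_to_584(self):
        sc = fixture_overlap_scenario()
        x = one_hop_expand({g for _, g in sc.seed_pairs}, sc.network)
        assert len(x) == 584 and x == sc.x


class TestHypergeomUpperTail:
    def test_printed_overlap_tail(self):
        p = hypergeom_upper_tail(11303, 8, 584, 5)
        assert p == pytest.approx(1.78e-5, rel=5e-3)

    def test_all_drug_overlap_tail_matches_print(self):
        # the 70-of-871 overlap's printed p is the plain upper tail;
        # printed mantissas are truncated, not rounded (1.2094 -> 1.20)
        p = hypergeom_upper_tail(11303, 871, 584, 70)
        assert 1.20e-4 <= p < 1.21e-4

    def test_k_zero_is_exactly_one(self):
        assert hypergeom_upper_tail(100, 10, 20, 0) == 1.0

    def test_bound_violations_error(self):
        with pytest.raises(ValueError):
            hypergeom_upper_tail(10, 11, 5, 0)
        with pytest.raises(ValueError):
            hypergeom_upper_tail(10, 4, 4, 5)

    def test_full_enumeration_small_universes(self):
        for N in range(1, 26):
            for K in range(0, N + 1, 3):
                for n in range(0, N + 1, 3):
                    for k in range(0, min(K, n) + 1):
                        assert abs(hypergeom_upper_tail(N, K, n, k)
                                   - enum_hypergeom_tail(N, K, n, k)) < 1e-12

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.data())
    def test_matches_enumeration_and_scipy_up_to_60(self, data):
        N = data.draw(st.integers(1, 60))
        K = data.draw(st.integers(0, N))
        n = data.draw(st.integers(0, N))
        k = data.draw(st.integers(0, min(K, n)))
        mine = hypergeom_upper_tail(N, K, n, k)
        assert abs(mine - enum_hypergeom_tail(N, K, n, k)) < 1e-12
        assert mine == pytest.approx(hypergeom.sf(k - 1, N, K, n), abs=1e-10)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.data())
    def test_pmf_normalizes_and_tail_monotone(self, data):
        N = data.draw(st.integers(1, 60))
        K = data.draw(st.integers(0, N))
        n = data.draw(st.integers(0, N))
        # P(X >= max(0, n-(N-K))) covers the whole support
        assert abs(hypergeom_upper_tail(N, K, n, max(0, n - (N - K)))
                   - 1.0) < 1e-12
        tails = [hypergeom_upper_tail(N, K, n, k)
                 for k in range(0, min(K, n) + 1)]
        assert all(a >= b - 1e-15 for a, b in zip(tails, tails[1:]))


class TestOverlapTest:
    def test_crc_drug_fold_two_decimals(self):
        t = overlap_test(11303, [f"y{i}" for i in range(8)],
                         [f"y{i}" for i in range(5)]
                         + [f"x{i}" for i in range(579)])
        assert t.overlap_k == 5
        assert math.floor(t.fold * 100) / 100 == 12.09

    def test_all_drug_fold_two_decimals(self):
        t = OverlapTest(11303, 871, 584, 70)
        assert math.floor(t.fold * 100) / 100 == 1.55

    def test_saturation_identity(self):
        genes = [f"G{i}" for i in range(30)]
        t = overlap_test(30, genes[:12], genes)
        assert t.overlap_k == t.category_k and t.fold == pytest.approx(1.0)

    def test_fold_scales_with_universe(self):
        t1 = OverlapTest(1000, 50, 100, 20)
        t2 = OverlapTest(2000, 50, 100, 20)
        assert t2.fold == pytest.approx(2 * t1.fold)

    def test_fold_times_expected_equals_overlap(self):
        t = OverlapTest(500, 40, 60, 11)
        assert t.fold * t.expected == pytest.approx(11)

    def test_universe_smaller_than_sets_errors(self):
        with pytest.raises(ValueError):
            overlap_test(3, [f"G{i}" for i in range(5)], ["G0"])


class TestRelativeFold:
    def test_printed_relative_fold(self):
        ty = OverlapTest(11303, 8, 584, 5)
        tz = OverlapTest(11303, 871, 584, 70)
        assert math.floor(relative_fold(ty, tz) * 100) / 100 == 7.77
        assert relative_fold(ty, tz) == pytest.approx(7.78, abs=5e-3)

    def test_identical_proportions_give_one(self):
        ty = OverlapTest(1000, 10, 100, 4)
        tz = OverlapTest(1000, 50, 100, 20)
        assert relative_fold(ty, tz) == pytest.approx(1.0)

    def test_zero_denominator_flagged_nan(self):
        ty = OverlapTest(1000, 10, 100, 4)
        tz = OverlapTest(1000, 50, 100, 0)
        assert math.isnan(relative_fold(ty, tz))

    def test_matches_direct_division_on_random_instances(self):
        rng = np.random.default_rng(0)
        for _ in range(1000):
            N = int(rng.integers(50, 500))
            Ky = int(rng.integers(1, 20))
            Kz = int(rng.integers(20, N // 2))
            n = int(rng.integers(1, N))
            ky = int(rng.integers(1, min(Ky, n) + 1))
            kz = int(rng.integers(1, min(Kz, n) + 1))
            ty = OverlapTest(N, Ky, n, ky)
            tz = OverlapTest(N, Kz, n, kz)
            assert relative_fold(ty, tz) == pytest.approx(
                (ky / Ky) / (kz / Kz))


class TestCompareTargetSets:
    ty = OverlapTest(11303, 8, 584, 5)
    tz = OverlapTest(11303, 871, 584, 70)

    def test_crc_vs_all_comparison_in_expected_band(self):
        p = compare_target_sets(self.ty, self.tz, exclude_y_from_z=False)
        assert 1e-5 < p < 1e-3
        assert p == pytest.approx(enum_fisher_greater(5, 3, 70, 801),
                                  rel=1e-9)

    def test_excluding_y_from_z_matches_enumeration(self):
        p = compare_target_sets(self.ty, self.tz, exclude_y_from_z=True)
        assert p == pytest.approx(enum_fisher_greater(5, 3, 65, 798),
                                  rel=1e-9)

    def test_identical_rows_are_nonsignificant(self):
        t = OverlapTest(1000, 20, 100, 5)
        assert compare_target_sets(t, t, exclude_y_from_z=False) >= 0.5

    def test_matches_enumeration_for_small_margins(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            a, b, c, d = (int(x) for x in rng.integers(0, 15, 4))
            ty = OverlapTest(1000, a + b, 100, a)
            tz = OverlapTest(1000, c + d, 100, c)
            p = compare_target_sets(ty, tz, exclude_y_from_z=False)
            assert p == pytest.approx(enum_fisher_greater(a, b, c, d),
                                      rel=1e-9, abs=1e-12)


class TestDrugOverlapReport:
    def test_scenario_reproduces_all_printed_statistics(self):
        sc = fixture_overlap_scenario()
        rep = drug_overlap_report(sc.seed_pairs, sc.network, sc.drugs,
                                  sc.universe_n)
        assert len(rep.x_set) == 584
        assert math.floor(rep.crc_test.fold * 100) / 100 == 12.09
        assert math.floor(rep.all_test.fold * 100) / 100 == 1.55
        assert rep.relative_fold == pytest.approx(7.78, abs=5e-3)
        assert rep.crc_test.p_upper == pytest.approx(1.78e-5, rel=5e-3)

    def test_label_permutation_leaves_statistics_unchanged(self):
        sc = fixture_overlap_scenario()
        mapping = {n: f"Z_{n}" for n in
                   set(sc.network.nodes) | set(sc.drugs["gene"])}
        net2 = nx.relabel_nodes(sc.network, mapping)
        drugs2 = sc.drugs.assign(gene=sc.drugs["gene"].map(mapping))
        pairs2 = [(r, mapping[g]) for r, g in sc.seed_pairs]
        # relabeling must go through symbol normalization unscathed
        rep1 = drug_overlap_report(sc.seed_pairs, sc.network, sc.drugs,
                                   sc.universe_n)
        rep2 = drug_overlap_report(pairs2, net2, drugs2, sc.universe_n)
        assert rep1.crc_test == rep2.crc_test
        assert rep1.all_test == rep2.all_test
        assert rep1.relative_fold == rep2.relative_fold

    def test_empty_drug_table_gives_k_zero_p_one(self):
        sc = fixture_overlap_scenario()
        empty = sc.drugs.iloc[0:0]
        rep = drug_overlap_report(sc.seed_pairs, sc.network, empty,
                                  sc.universe_n)
        assert rep.crc_test.overlap_k == 0
        assert rep.crc_test.p_upper == 1.0 and rep.all_test.p_upper == 1.0

    def test_empty_seeds_flagged(self):
        sc = fixture_overlap_scenario()
        rep = drug_overlap_report([], sc.network, sc.drugs, sc.universe_n)
        assert rep.crc_test is None and math.isnan(rep.relative_fold)

    def test_connection_paths_deduplicate_and_sort(self):
        g = nx.Graph([("RG", "T1"), ("RG", "T2")])
        drugs = pd.DataFrame(
            [{"drug": "d1", "gene": "T1", "status": "approved",
              "indication": "x", "crc_approved": True},
             {"drug": "d1", "gene": "T1", "status": "approved",
              "indication": "x", "crc_approved": True},
             {"drug": "d2", "gene": "T2", "status": "approved",
              "indication": "y", "crc_approved": False}])
        rep = drug_overlap_report([("rs1", "RG"), ("rs2", "RG")],
                                  g, drugs, 100)
        assert list(rep.connections["drug"]) == ["d1", "d2"]
        assert list(rep.connections["ppi_gene"]) == ["T1", "T2"]
        dot = export_dot(rep.connections)
        assert '"RG" -- "T1";' in dot and '"drug:d2"' in dot


def test_planted_bundle_fold_recovered_within_ten_percent(small_sim):
    from locus2drug.evidence import build_evidence_matrix
    from locus2drug.model_io import PipelineConfig
    from locus2drug.scoring import score_rows, select_biological
    _, bundle, truth = small_sim
    cfg = PipelineConfig()
    matrix = build_evidence_matrix(truth.pairs, bundle, cfg)
    sel = select_biological(score_rows(matrix), cfg.score_threshold)
    rep = drug_overlap_report([(r.pair.rsid, r.pair.gene) for r in sel],
                              bundle.network, bundle.drugs,
                              bundle.universe_n())
    assert rep.crc_test.fold == pytest.approx(truth.planted_fold, rel=0.10)
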