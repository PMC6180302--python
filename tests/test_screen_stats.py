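"""Hit rates, summary-statistic tests, ΔΔCt, network summaries, MeSH buckets."""

import math

import numpy as np
import pytest

from ccmscreen.screen_stats import (GroupSummary, MeshBucketCounts,
                                    anova_tukey_summary, ddct_fold_change,
                                    hit_rate, mean_sem, mesh_bucket,
                                    network_summary, pooled_t_test_summary)


class TestHitRate:
    @pytest.mark.parametrize("active,screened,expected", [
        (134, 1600, 8.4),
        (350, 4748, 7.4),
        (0, 100, 0.0),
    ])
    def test_published_screen_rates(self, active, screened, expected):
        assert hit_rate(active, screened) == expected

    def test_zero_denominator_rejected(self):
        with pytest.raises(ValueError):
            hit_rate(1, 0)


class TestMeanSem:
    def test_knockdown_ratio_triplicate(self):
        # the three shRNA knock-down expression ratios reported for the
        # HUVEC screen validation
        mean, sem = mean_sem([0.34184, 0.38087, 0.20438])
        assert mean == pytest.approx(0.309, abs=5e-4)
        assert sem == pytest.approx(0.05352, abs=5e-6)

    def test_constant_values(self):
        assert mean_sem([2.5, 2.5, 2.5]) == (2.5, 0.0)

    def test_hand_computed_small_sample(self):
        mean, sem = mean_sem([1, 2, 3])
        assert mean == 2
        assert sem == pytest.approx(1 / math.sqrt(3))

    def test_single_value_warns(self):
        with pytest.warns(UserWarning):
            assert mean_sem([7.0]) == (7.0, 0.0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            mean_sem([])


class TestPooledTTest:
    def test_small_lesion_counts_8v8(self):
        # vehicle vs treated lesion counts (<5000 um^2), n=8 per arm
        r = pooled_t_test_summary(GroupSummary("veh", 155.4, 69.18, 8),
                                  GroupSummary("drug", 95.75, 18.77, 8))
        assert r.df == 14
        assert r.p == pytest.approx(0.0338, abs=2e-4)

    def test_small_lesion_counts_5v6(self):
        r = pooled_t_test_summary(GroupSummary("veh", 197.7, 26.34, 5),
                                  GroupSummary("drug", 123.6, 35.37, 6))
        assert r.df == 9
        assert r.p == pytest.approx(0.0038, abs=2e-4)

    def test_equal_means_give_p_one(self):
        r = pooled_t_test_summary(GroupSummary("a", 5.0, 1.0, 4),
                                  GroupSummary("b", 5.0, 2.0, 4))
        assert r.t == 0.0 and r.p == pytest.approx(1.0)

    def test_degenerate_zero_variance_equal_means(self):
        r = pooled_t_test_summary(GroupSummary("a", 1.0, 0.0, 3),
                                  GroupSummary("b", 1.0, 0.0, 3))
        assert r.degenerate and r.p == 1.0

    def test_round_trip_from_raw_values(self):
        from scipy import stats

        rng = np.random.default_rng(12)
        for _ in range(10):
            a = rng.normal(0.0, 1.0, size=int(rng.integers(3, 12)))
            b = rng.normal(0.5, 1.5, size=int(rng.integers(3, 12)))
            expect_t, expect_p = stats.ttest_ind(a, b, equal_var=True)
            r = pooled_t_test_summary(GroupSummary.from_values("a", a),
                                      GroupSummary.from_values("b", b))
            assert r.t == pytest.approx(float(expect_t))
            assert r.p == pytest.approx(float(expect_p))


ZF_QPCR_GROUPS = [
    GroupSummary("wt+DMSO", 1.0, 0.0, 6),
    GroupSummary("ccm2+DMSO", 1.466, 0.22, 6),
    GroupSummary("wt+drug", 0.5778, 0.2458, 6),
    GroupSummary("ccm2+drug", 0.6992, 0.3278, 6),
]


class TestAnovaTukey:
    def test_relative_expression_four_groups(self):
        # relative klf2a expression in four treatment arms, n=6 each; the
        # published adjusted p for arm 1 vs arm 2 is 0.013 (summaries are
        # rounded re-statements of the raw data, hence the tolerance)
        r = anova_tukey_summary(ZF_QPCR_GROUPS)
        pair = next(p for p in r.pairs
                    if {p.label_a, p.label_b} == {"wt+DMSO", "ccm2+DMSO"})
        assert pair.p_adjusted == pytest.approx(0.013, abs=3e-3)
        assert r.df_error == 20

    def test_equal_means_all_pairs_null(self):
        groups = [GroupSummary(f"g{i}", 3.0, 1.0, 5) for i in range(3)]
        r = anova_tukey_summary(groups)
        assert all(p.q == 0.0 and p.p_adjusted == pytest.approx(1.0)
                   for p in r.pairs)

    def test_two_groups_reduces_to_pooled_t(self):
        # at k=2 the studentized range relates to t via q = |t|*sqrt(2)
        a = GroupSummary("a", 10.0, 2.0, 6)
        b = GroupSummary("b", 12.5, 3.0, 6)
        tukey = anova_tukey_summary([a, b])
        t = pooled_t_test_summary(a, b)
        assert tukey.pairs[0].p_adjusted == pytest.approx(t.p, abs=1e-6)
        assert tukey.pairs[0].q == pytest.approx(abs(t.t) * math.sqrt(2))

    def test_relabeling_invariance(self):
        r1 = anova_tukey_summary(ZF_QPCR_GROUPS)
        r2 = anova_tukey_summary(list(reversed(ZF_QPCR_GROUPS)))
        p1 = {frozenset((p.label_a, p.label_b)): p.p_adjusted for p in r1.pairs}
        p2 = {frozenset((p.label_a, p.label_b)): p.p_adjusted for p in r2.pairs}
        assert p1 == pytest.approx(p2)
        assert r1.f == pytest.approx(r2.f)

    def test_zero_mse_unequal_means_rejected(self):
        with pytest.raises(ValueError):
            anova_tukey_summary([GroupSummary("a", 1.0, 0.0, 3),
                                 GroupSummary("b", 2.0, 0.0, 3)])

    def test_null_simulations_consistent_with_f(self):
        # when the overall F is clearly null, no Tukey pair should reject
        rng = np.random.default_rng(30)
        for _ in range(20):
            groups = [
                GroupSummary.from_values(f"g{i}", rng.normal(0, 1, size=6))
                for i in range(4)
            ]
            r = anova_tukey_summary(groups)
            if r.p_f > 0.5:
                assert all(p.p_adjusted > 0.05 for p in r.pairs)


class TestDdct:
    def test_identity_condition_is_one(self):
        assert ddct_fold_change(20.0, [18.0, 19.0], 20.0, [18.0, 19.0]) == 1.0

    def test_one_cycle_halves_expression(self):
        assert ddct_fold_change(25.0, [20.0, 22.0], 24.0, [20.0, 22.0]) == 0.5

    def test_reference_shift_cancels(self):
        base = ddct_fold_change(25.0, [20.0], 24.0, [20.0])
        shifted = ddct_fold_change(26.0, [21.0], 25.0, [21.0])
        assert base == shifted == 0.5

    def test_empty_references_rejected(self):
        with pytest.raises(ValueError):
            ddct_fold_change(20.0, [], 19.0, [18.0])


class TestNetworkSummary:
    def test_printed_network_dimensions(self):
        # any simple graph with the printed node/edge counts reproduces the
        # printed average degree 2E/N
        import networkx as nx

        g = nx.gnm_random_graph(47, 75, seed=1)
        s = network_summary(g.edges, nodes=g.nodes)
        assert round(s.avg_degree, 2) == 3.19

    def test_triangle(self):
        s = network_summary([(1, 2), (2, 3), (1, 3)])
        assert s.avg_degree == 2.0
        assert s.avg_local_clustering == 1.0

    def test_star_has_zero_clustering(self):
        s = network_summary([(0, 1), (0, 2), (0, 3)])
        assert s.avg_degree == pytest.approx(1.5)
        assert s.avg_local_clustering == 0.0

    def test_avg_degree_equals_mean_node_degree(self):
        import networkx as nx

        g = nx.gnm_random_graph(30, 44, seed=7)
        s = network_summary(g.edges, nodes=g.nodes)
        assert s.avg_degree == pytest.approx(np.mean([d for _n, d in g.degree]))

    def test_empty_graph_rejected(self):
        with pytest.raises(ValueError):
            network_summary([])


class TestMeshBucket:
    def test_three_compound_fixture(self):
        counts = mesh_bucket({
            "c1": {"D27.505.954.248"},
            "c2": {"D27.505.519.389.745", "D27.505.954.122"},
            "c3": {"D27.505.696.100", "garbage..number"},
        })
        assert counts.branch_counts() == {
            "D27.505.519": 1, "D27.505.696": 1, "D27.505.954": 2,
        }
        assert counts.subcategory_counts()["D27.505.954.248"] == 1
        assert counts.unclassified == {"c3": {"garbage..number"}}

    def test_compound_in_two_branches_counted_once_each(self):
        counts = mesh_bucket({"c": {"D27.505.519.1", "D27.505.696.2"}})
        assert counts.branch_counts()["D27.505.519"] == 1
        assert counts.branch_counts()["D27.505.696"] == 1

    def test_non_d27_numbers_unclassified(self):
        counts = mesh_bucket({"c": {"D02.455.426"}})
        assert counts.branch_counts() == {
            "D27.505.519": 0, "D27.505.696": 0, "D27.505.954": 0,
        }
        assert counts.unclassified == {"c": {"D02.455.426"}}
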