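import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cooccur3 import (DataError, PhyleticProfile, ProfileMatrix, SpeciesPanel,
                      background_thresholds, classify_pair, classify_pairs,
                      dollo_gain_loss, global_trend, hamming,
                      partial_correlation, subset_score, taxonomic_subset)
from cooccur3.pairwise import (PairThresholds, gain_loss_matrix, is_eligible,
                               nearest_rank_percentile)
from cooccur3.simulate import plant_pair_cohort, simulate_tree

from .oracles import all_trees, min_dollo_losses


class TestHamming:
    def test_identical_is_zero(self, panel4, profile_factory):
        p = profile_factory("A", [1, 0, 1, 0], panel4)
        q = profile_factory("B", [1, 0, 1, 0], panel4)
        assert hamming(p, q) == 0

    def test_complementary_is_n(self, table2):
        pm, _ = table2
        panel = pm.panel
        rng = np.random.default_rng(1)
        counts = (rng.random(51) < 0.5).astype(np.int64)
        p = PhyleticProfile("P", counts, panel)
        q = PhyleticProfile("Q", 1 - counts, panel)
        assert hamming(p, q) == 51

    def test_mtor_vs_rictor_from_table(self, table2):
        # independent tally of differing rows in the printed columns
        pm, _ = table2
        expected = sum(
            int(pm["MTOR"].counts[i] > 0) != int(pm["RICTOR"].counts[i] > 0)
            for i in range(51))
        assert hamming(pm["MTOR"], pm["RICTOR"]) == expected == 15

    def test_panel_mismatch_is_error(self, panel4, profile_factory):
        other = SpeciesPanel.from_iterable(["x1", "x2", "x3", "x4"])
        p = profile_factory("A", [1, 0, 1, 0], panel4)
        q = profile_factory("B", [1, 0, 1, 0], other)
        with pytest.raises(DataError):
            hamming(p, q)


class TestDollo:
    def test_all_present_gain_at_root(self, tree4, panel4, profile_factory):
        vec = dollo_gain_loss(profile_factory("A", [1, 1, 1, 1], panel4), tree4)
        assert vec[tree4.root] == 1
        assert (vec == 1).sum() == 1
        assert (vec == -1).sum() == 0

    def test_single_leaf_gain_on_terminal(self, tree4, panel4, profile_factory):
        vec = dollo_gain_loss(profile_factory("A", [1, 0, 0, 0], panel4), tree4)
        gain_node = int(np.flatnonzero(vec == 1)[0])
        assert tree4.is_leaf(gain_node)
        assert tree4.leaf_name[gain_node] == "s1"
        assert (vec == -1).sum() == 0

    def test_checkerboard_two_terminal_losses(self, tree4, panel4,
                                              profile_factory):
        vec = dollo_gain_loss(profile_factory("A", [1, 0, 1, 0], panel4), tree4)
        assert vec[tree4.root] == 1
        lost = [tree4.leaf_name[int(i)] for i in np.flatnonzero(vec == -1)]
        assert sorted(lost) == ["s2", "s4"]

    def test_all_absent_is_error(self, tree4, panel4, profile_factory):
        with pytest.raises(DataError):
            dollo_gain_loss(profile_factory("A", [0, 0, 0, 0], panel4), tree4)

    def test_single_gain_invariant(self, tree4, panel4, profile_factory):
        for bits in itertools.product([0, 1], repeat=4):
            if not any(bits):
                continue
            vec = dollo_gain_loss(profile_factory("A", list(bits), panel4), tree4)
            assert (vec == 1).sum() == 1

    @pytest.mark.parametrize("n_leaves", [2, 3, 4, 5])
    def test_loss_count_minimal_exhaustive(self, n_leaves):
        """Loss count equals the DP minimum on every topology/profile."""
        for tree in all_trees(n_leaves):
            panel = SpeciesPanel.from_iterable(tree.leaves) \
                if n_leaves >= 4 else None
            for bits in itertools.product([0, 1], repeat=n_leaves):
                if not any(bits):
                    continue
                presence = np.array(bits, dtype=bool)
                vec = dollo_gain_loss(presence, tree)
                assert int((vec == -1).sum()) == min_dollo_losses(tree, bits)

    def test_losses_descend_from_gain(self, table2):
        pm, _ = table2
        tree = simulate_tree(51, seed=9)
        rng = np.random.default_rng(0)
        presence = rng.random(51) < 0.6
        presence[0] = True
        vec = dollo_gain_loss(presence, tree)
        gain = int(np.flatnonzero(vec == 1)[0])
        for node in np.flatnonzero(vec == -1):
            assert tree.is_ancestor(gain, int(node))


class TestGlobalTrend:
    def test_two_ubiquitous_ogs(self, tree4, panel4, profile_factory):
        pm = ProfileMatrix(panel4)
        pm.add(profile_factory("A", [1, 1, 1, 1], panel4))
        pm.add(profile_factory("B", [1, 1, 1, 1], panel4))
        trend = global_trend(pm, tree4)
        assert trend[tree4.root] == 2.0
        assert (trend != 0).sum() == 1

    def test_single_og_equals_its_vector(self, tree4, panel4, profile_factory):
        pm = ProfileMatrix(panel4)
        pm.add(profile_factory("A", [1, 0, 1, 1], panel4))
        trend = global_trend(pm, tree4)
        np.testing.assert_array_equal(
            trend, dollo_gain_loss(pm["A"], tree4).astype(float))

    def test_matrix_sum_oracle(self):
        tree = simulate_tree(12, seed=4)
        panel = SpeciesPanel.from_iterable(tree.leaves)
        rng = np.random.default_rng(21)
        pm = ProfileMatrix(panel)
        for i in range(20):
            presence = rng.random(12) < 0.7
            if not presence.any():
                presence[0] = True
            pm.add(PhyleticProfile(f"OG{i}", presence.astype(np.int64), panel))
        stacked = gain_loss_matrix(pm, tree)
        np.testing.assert_array_equal(global_trend(pm, tree),
                                      stacked.sum(axis=0).astype(float))


class TestPartialCorrelation:
    def test_identical_vectors_give_one(self):
        g = np.array([1, 0, -1, 0, 1, -1], float)
        trend = np.array([2, 1, -1, 0, 1, 0], float)
        r, degenerate = partial_correlation(g, g, trend)
        assert r == pytest.approx(1.0)

    def test_orthogonal_vectors_give_zero(self):
        g_a = np.array([1, -1, 1, -1], float)
        g_b = np.array([1, 1, -1, -1], float)
        trend = np.array([1, -1, -1, 1], float)
        r, degenerate = partial_correlation(g_a, g_b, trend)
        assert r == pytest.approx(0.0)
        assert not degenerate

    def test_textbook_formula_oracle(self):
        rng = np.random.default_rng(33)
        g_a = rng.integers(-1, 2, size=10).astype(float)
        g_b = rng.integers(-1, 2, size=10).astype(float)
        trend = rng.normal(size=10)
        r, _ = partial_correlation(g_a, g_b, trend)

        def pearson(x, y):
            x = x - x.mean()
            y = y - y.mean()
            return float((x * y).sum() / np.sqrt((x * x).sum() * (y * y).sum()))

        r_ab, r_ag, r_bg = pearson(g_a, g_b), pearson(g_a, trend), pearson(g_b, trend)
        expected = (r_ab - r_ag * r_bg) / np.sqrt((1 - r_ag**2) * (1 - r_bg**2))
        assert r == pytest.approx(expected)

    def test_symmetry(self):
        rng = np.random.default_rng(8)
        g_a = rng.integers(-1, 2, size=15).astype(float)
        g_b = rng.integers(-1, 2, size=15).astype(float)
        trend = rng.normal(size=15)
        assert partial_correlation(g_a, g_b, trend)[0] == pytest.approx(
            partial_correlation(g_b, g_a, trend)[0])

    def test_branch_relabeling_invariance(self):
        rng = np.random.default_rng(9)
        g_a = rng.integers(-1, 2, size=12).astype(float)
        g_b = rng.integers(-1, 2, size=12).astype(float)
        trend = rng.normal(size=12)
        perm = rng.permutation(12)
        assert partial_correlation(g_a, g_b, trend)[0] == pytest.approx(
            partial_correlation(g_a[perm], g_b[perm], trend[perm])[0])

    def test_degenerate_flag(self):
        g = np.array([1, -1, 1, -1], float)
        r, degenerate = partial_correlation(g, g, g.astype(float))
        assert degenerate
        assert r == pytest.approx(1.0)

    def test_zero_variance_is_error(self):
        with pytest.raises(DataError):
            partial_correlation(np.zeros(5), np.ones(5), np.arange(5.0))


class TestSubsetScore:
    def test_strict_subset_is_difference(self, panel4, profile_factory):
        p = profile_factory("A", [1, 1, 1, 1], panel4)
        q = profile_factory("B", [1, 1, 0, 0], panel4)
        assert subset_score(p, q) == 2

    def test_identical_is_zero(self, panel4, profile_factory):
        p = profile_factory("A", [1, 1, 0, 1], panel4)
        q = profile_factory("B", [1, 1, 0, 1], panel4)
        assert subset_score(p, q) == 0

    def test_hnrnpk_vs_pdcd4(self, table2):
        pm, _ = table2
        # 16 species have HNRNPK without PDCD4 and none the converse
        assert subset_score(pm["HNRNPK"], pm["PDCD4"]) == 16

    def test_symmetric_in_argument_order(self, table2):
        pm, _ = table2
        assert subset_score(pm["PDCD4"], pm["HNRNPK"]) == \
            subset_score(pm["HNRNPK"], pm["PDCD4"])

    def test_subset_cardinality_property(self, table2):
        pm, _ = table2
        rng = np.random.default_rng(12)
        panel = pm.panel
        for trial in range(20):
            pa = rng.random(51) < 0.7
            pb = pa & (rng.random(51) < 0.6)
            if not pb.any() or pb.sum() == pa.sum():
                continue
            p = PhyleticProfile("P", pa.astype(np.int64), panel)
            q = PhyleticProfile("Q", pb.astype(np.int64), panel)
            assert subset_score(p, q) == int(pa.sum()) - int(pb.sum())


class TestTaxonomicSubset:
    def test_nested_clade_true(self, tree4, panel4, profile_factory):
        a = profile_factory("A", [1, 1, 1, 1], panel4)
        b = profile_factory("B", [1, 1, 0, 0], panel4)
        assert taxonomic_subset(a, b, tree4)

    def test_both_span_root_false(self, tree4, panel4, profile_factory):
        a = profile_factory("A", [1, 0, 0, 1], panel4)
        b = profile_factory("B", [0, 1, 1, 0], panel4)
        assert not taxonomic_subset(a, b, tree4)

    def test_no_overlap_false(self, tree4, panel4, profile_factory):
        a = profile_factory("A", [1, 1, 0, 0], panel4)
        b = profile_factory("B", [0, 0, 1, 1], panel4)
        assert not taxonomic_subset(a, b, tree4)

    def test_lca_strict_descendance_oracle(self):
        tree = simulate_tree(8, seed=6)
        panel = SpeciesPanel.from_iterable(tree.leaves)
        a = PhyleticProfile("A", np.array([1, 1, 1, 0, 0, 0, 0, 0]), panel)
        b = PhyleticProfile("B", np.array([1, 1, 0, 0, 0, 0, 0, 0]), panel)
        lca_a = tree.lca(a.presence)
        lca_b = tree.lca(b.presence)
        expect = (lca_a != lca_b) and (
            tree.is_ancestor(lca_a, lca_b) or tree.is_ancestor(lca_b, lca_a))
        assert taxonomic_subset(a, b, tree) == expect


class TestThresholds:
    def test_nearest_rank_1_to_100(self):
        th = background_thresholds(list(range(1, 101)), list(range(1, 101)), 90)
        assert th.matching_cutoff == 90
        # strictly-exceeds semantics
        assert 91 > th.matching_cutoff
        assert not (90 > th.matching_cutoff)

    def test_all_equal_background(self):
        th = background_thresholds([0.5] * 50, [3] * 50, 90)
        assert th.matching_cutoff == 0.5
        assert not (0.5 > th.matching_cutoff)

    def test_sort_index_oracle(self):
        rng = np.random.default_rng(77)
        vals = rng.normal(size=1000).tolist()
        for pct in (85, 90, 95):
            cutoff = nearest_rank_percentile(vals, pct)
            arr = sorted(vals)
            assert cutoff == arr[int(np.ceil(pct / 100 * 1000)) - 1]

    def test_too_few_values_is_error(self):
        with pytest.raises(DataError):
            background_thresholds([1.0] * 5, [1] * 5, 90)


class TestClassifyPair:
    def test_identical_ubiquitous_is_matching(self, tree4, panel4,
                                              profile_factory):
        p = profile_factory("A", [1, 1, 1, 1], panel4)
        q = profile_factory("B", [1, 1, 1, 1], panel4)
        th = PairThresholds(matching_cutoff=0.5, subset_cutoff=1.0)
        assert classify_pair(p, q, pcorr=1.0, sscore=0,
                             thresholds=th, tree=tree4) == "matching"

    def test_taxonomic_precedes_subset(self, tree4, panel4, profile_factory):
        p = profile_factory("A", [1, 1, 1, 1], panel4)
        q = profile_factory("B", [1, 1, 0, 0], panel4)
        th = PairThresholds(matching_cutoff=0.9, subset_cutoff=1.0)
        # passes the subset cutoff (score 2 > 1) but is clade-nested
        assert classify_pair(p, q, pcorr=0.0, sscore=2,
                             thresholds=th, tree=tree4) == "taxonomic"

    def test_ineligible_is_error(self, tree4, panel4, profile_factory):
        p = profile_factory("A", [1, 0, 0, 0], panel4)
        q = profile_factory("B", [0, 1, 0, 0], panel4)
        th = PairThresholds(matching_cutoff=0.5, subset_cutoff=1.0)
        with pytest.raises(DataError):
            classify_pair(p, q, 0.0, 0, th, tree4)

    def test_half_of_species_filter(self, panel4, profile_factory):
        # ceil(4/2) = 2 of 4
        p = profile_factory("A", [1, 1, 0, 0], panel4)
        q = profile_factory("B", [0, 0, 0, 1], panel4)
        assert is_eligible(p, q)
        r = profile_factory("C", [1, 0, 0, 0], panel4)
        assert not is_eligible(r, q)

    def test_planted_cohort_recovery(self):
        """>=95% of planted pairs recover their true category."""
        ok = tot = 0
        for seed in (0, 1, 2):
            tree = simulate_tree(51, seed)
            pm, pairs, truth = plant_pair_cohort(tree, n_per_category=25,
                                                 seed=seed + 100)
            records, _ = classify_pairs(pm, tree, pairs,
                                        background_nodes=pm.og_ids,
                                        percentile=90.0,
                                        max_background=5000, seed=seed)
            for rec in records:
                tot += 1
                ok += (rec.category == truth[(rec.og_a, rec.og_b)])
        assert ok / tot >= 0.95

    def test_categories_partition_eligible(self):
        tree = simulate_tree(51, 5)
        pm, pairs, _ = plant_pair_cohort(tree, n_per_category=10, seed=55)
        records, _ = classify_pairs(pm, tree, pairs,
                                    background_nodes=pm.og_ids,
                                    max_background=3000, seed=5)
        n_eligible = sum(r.eligible for r in records)
        n_categorized = sum(r.category is not None for r in records)
        assert n_eligible == n_categorized
        counts = {}
        for r in records:
            if r.category:
                counts[r.category] = counts.get(r.category, 0) + 1
        assert sum(counts.values()) == n_eligible
        assert set(counts) <= {"matching", "taxonomic", "subset", "other"}


@given(bits_a=st.lists(st.booleans(), min_size=4, max_size=4),
       bits_b=st.lists(st.booleans(), min_size=4, max_size=4))
@settings(max_examples=60, deadline=None)
def test_subset_score_antisymmetric_component(bits_a, bits_b):
    """|A wo B| - |B wo A| is computed with A the wider profile, so the
    score never depends on argument order."""
    panel = SpeciesPanel.from_iterable(["s1", "s2", "s3", "s4"])
    p = PhyleticProfile("A", np.array(bits_a, dtype=np.int64), panel)
    q = PhyleticProfile("B", np.array(bits_b, dtype=np.int64), panel)
    assert subset_score(p, q) == subset_score(q, p)
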