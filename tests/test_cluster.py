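"""Within-groups linkage, BIC model selection, d' and refinement."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from retclust.cluster import (
    cluster_grid,
    cluster_stats,
    cut_tree_labels,
    dprime,
    gaussian_bic,
    hierarchical_merge_tree,
    refine_by_dprime,
    select_initial_k_bic,
)
from retclust.oracles import (
    gaussian_bic_direct,
    within_groups_merge_sequence,
)
from retclust.types import ClusterStats


class TestMergeTree:
    def test_nearest_pair_merges_first(self):
        merges = hierarchical_merge_tree(np.array([0.0, 1.0, 10.0]))
        assert merges[0][:2] == (0, 1)

    def test_duplicates_merge_first_at_zero_cost(self):
        merges = hierarchical_merge_tree(np.array([5.0, 0.0, 5.0, 9.0]))
        assert merges[0] == (0, 2, 0.0)

    @pytest.mark.parametrize("trial", range(5))
    def test_matches_brute_force_oracle(self, trial):
        rng = np.random.default_rng(100 + trial)
        pts = rng.normal(size=40)
        fast = hierarchical_merge_tree(pts)
        slow = within_groups_merge_sequence(pts)
        assert [(a, b) for a, b, _ in fast] == [(a, b) for a, b, _ in slow]
        np.testing.assert_allclose([c for _, _, c in fast],
                                   [c for _, _, c in slow], rtol=1e-8)

    def test_vector_features_match_oracle(self):
        rng = np.random.default_rng(3)
        pts = rng.normal(size=(30, 4))
        fast = hierarchical_merge_tree(pts)
        slow = within_groups_merge_sequence(pts)
        assert [(a, b) for a, b, _ in fast] == [(a, b) for a, b, _ in slow]

    def test_single_point_rejected(self):
        with pytest.raises(ValueError):
            hierarchical_merge_tree(np.array([1.0]))


class TestBIC:
    def test_identical_values_select_one_cluster(self):
        x = np.full(50, 3.0)
        merges = hierarchical_merge_tree(x + np.arange(50) * 0)
        assert select_initial_k_bic(x, merges, k_max=8) == 1

    def test_two_well_separated_gaussians_select_two(self, rng):
        x = np.concatenate([rng.normal(-10, 1, 200), rng.normal(10, 1, 200)])
        merges = hierarchical_merge_tree(x)
        k0 = select_initial_k_bic(x, merges, k_max=3)
        assert k0 == 2
        # independent direct evaluation confirms the decision: the BIC
        # improves massively from 1 to 2 clusters, and the final merge
        # (joining the two modes) towers over every earlier merge distance
        bics = {k: gaussian_bic_direct(x, cut_tree_labels(merges, len(x), k))
                for k in (1, 2, 3)}
        assert bics[2] < bics[1]
        n = len(x)
        join_modes = merges[n - 2][2]
        within_mode = merges[n - 3][2]
        assert join_modes > 10 * within_mode

    def test_k_max_one_forces_single_cluster(self, rng):
        x = rng.normal(size=30)
        merges = hierarchical_merge_tree(x)
        assert select_initial_k_bic(x, merges, k_max=1) == 1

    def test_bic_agrees_with_direct_evaluation(self, rng):
        x = rng.normal(size=80)
        merges = hierarchical_merge_tree(x)
        for k in (1, 2, 4, 7):
            labels = cut_tree_labels(merges, 80, k)
            assert gaussian_bic(x, labels) == pytest.approx(
                gaussian_bic_direct(x, labels), rel=1e-9
            )


class TestDprime:
    def test_direct_value(self):
        a = ClusterStats(mean=-10.0, sd=3.0, n=5)
        b = ClusterStats(mean=-4.0, sd=5.0, n=5)
        assert dprime(a, b) == pytest.approx(6.0 / np.sqrt(17.0), rel=1e-12)

    def test_symmetry_and_zero(self, rng):
        for _ in range(20):
            a = ClusterStats(rng.normal(), rng.uniform(0.1, 3), 4)
            b = ClusterStats(rng.normal(), rng.uniform(0.1, 3), 4)
            assert dprime(a, b) == dprime(b, a)
        same = ClusterStats(1.0, 2.0, 3)
        assert dprime(same, same) == 0.0

    def test_degenerate_zero_variance(self):
        a = ClusterStats(1.0, 0.0, 2)
        assert dprime(a, ClusterStats(1.0, 0.0, 2)) == 0.0
        assert dprime(a, ClusterStats(2.0, 0.0, 2)) == np.inf

    @settings(derandomize=True, max_examples=50)
    @given(
        x1=st.floats(-50, 50), s1=st.floats(0.1, 20),
        x2=st.floats(-50, 50), s2=st.floats(0.1, 20),
        shift=st.floats(-100, 100), scale=st.floats(0.01, 50),
    )
    def test_affine_invariance_property(self, x1, s1, x2, s2, shift, scale):
        """d' is invariant to shifting all values and scaling by c > 0
        (both means and SDs transform together)."""
        base = dprime(ClusterStats(x1, s1, 3), ClusterStats(x2, s2, 3))
        moved = dprime(ClusterStats(scale * x1 + shift, scale * s1, 3),
                       ClusterStats(scale * x2 + shift, scale * s2, 3))
        assert moved == pytest.approx(base, rel=1e-9, abs=1e-12)

    def test_shift_and_scale_invariance(self, rng):
        x = rng.normal(size=40)
        y = rng.normal(3, 2, size=40)
        base = dprime(cluster_stats(x), cluster_stats(y))
        for c, s in ((5.0, 1.0), (0.0, 3.0), (-2.0, 0.5)):
            shifted = dprime(cluster_stats(s * x + c), cluster_stats(s * y + c))
            assert shifted == pytest.approx(base, rel=1e-12)


class TestRefinement:
    def test_pair_below_criterion_merges(self, rng):
        # two heavily overlapping groups: d' ~ 0.5
        v = np.concatenate([rng.normal(0, 2, 50), rng.normal(1.8, 2, 50)])
        labels = np.repeat([0, 1], 50)
        new_labels, stats, _ = refine_by_dprime(v, labels)
        assert len(stats) == 1 and np.all(new_labels == 0)

    def test_pair_above_criterion_survives(self, rng):
        v = np.concatenate([rng.normal(0, 1, 50), rng.normal(4, 1, 50)])
        labels = np.repeat([0, 1], 50)
        _, stats, M = refine_by_dprime(v, labels)
        assert len(stats) == 2
        assert M[0, 1] >= 1.0

    def test_smallest_dprime_merges_first(self):
        # three groups at means 0, 0.4 and 10 (sd ~0.5 each): pairwise d'
        # ~ {0.8, 20, 21} -> only the 0/0.4 pair falls below 1 and merges
        v = np.concatenate([
            np.array([-0.6, 0.0, 0.6]), np.array([-0.2, 0.4, 1.0]),
            np.array([9.5, 10.0, 10.5]),
        ])
        labels = np.repeat([0, 1, 2], 3)
        new_labels, stats, M = refine_by_dprime(v, labels)
        assert len(stats) == 2
        assert stats[0].mean == pytest.approx(10.0)  # label order: descending mean
        assert stats[1].mean == pytest.approx(0.2)
        assert stats[0].n == 3 and stats[1].n == 6

    def test_final_solution_meets_criterion(self, rng):
        v = rng.normal(size=200) + np.repeat(np.arange(8.0), 25)
        labels = np.repeat(np.arange(8), 25)
        _, stats, M = refine_by_dprime(v, labels)
        if len(stats) > 1:
            assert M[np.triu_indices(len(stats), k=1)].min() >= 1.0


class TestClusterGrid:
    def test_k_never_exceeds_k0(self, rng):
        values = rng.normal(size=(64, 64))
        valid = np.ones((64, 64), bool)
        sol = cluster_grid(values, valid, k_max=6)
        assert 1 <= sol.k <= sol.k0 <= 6
        assert set(np.unique(sol.labels)) <= set(range(sol.k + 1))

    def test_invalid_cells_labelled_zero(self, rng):
        values = rng.normal(size=(64, 64))
        valid = rng.random((64, 64)) > 0.3
        sol = cluster_grid(values, valid, k_max=4)
        assert np.all(sol.labels[~valid] == 0)
        assert np.all(sol.labels[valid] >= 1)

    def test_ordinal_labelling_descending_mean(self, rng):
        values = rng.normal(size=(64, 64))
        values[:32] += 8.0
        sol = cluster_grid(values, np.ones((64, 64), bool), k_max=4)
        means = [c.mean for c in sol.clusters]
        assert means == sorted(means, reverse=True)
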