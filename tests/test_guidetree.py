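import numpy as np
import pytest

from oracles import scipy_linkage_partitions
from pnpalign.errors import InputError
from pnpalign.guidetree import (
    UPGMA,
    WPGMA,
    build_tree,
    distance_matrix,
    expected_accuracy,
    merge_distance_upgma,
    merge_distance_wpgma,
    select_tree_method,
)


def tree_partitions(tree):
    """(height, frozenset of leaves) per internal node, for comparison."""
    return sorted(
        (node.height, frozenset(node.leaf_indices()))
        for node in tree.internal_nodes()
    )


def random_distance_matrix(rng, n):
    d = rng.random((n, n))
    d = (d + d.T) / 2
    np.fill_diagonal(d, 0.0)
    return d


class TestMergeDistances:
    def test_upgma_weighted_mean(self):
        assert merge_distance_upgma(0.4, 0.8, 3, 1) == pytest.approx(0.5)

    def test_upgma_reduces_to_wpgma_for_singletons(self):
        assert merge_distance_upgma(0.4, 0.8, 1, 1) == merge_distance_wpgma(0.4, 0.8)

    def test_wpgma_plain_mean(self):
        assert merge_distance_wpgma(0.4, 0.8) == pytest.approx(0.6)

    @pytest.mark.parametrize("si,sj", [(1, 1), (2, 5), (7, 3)])
    def test_equal_inputs_are_a_fixed_point(self, si, sj):
        assert merge_distance_upgma(0.3, 0.3, si, sj) == pytest.approx(0.3)
        assert merge_distance_wpgma(0.3, 0.3) == pytest.approx(0.3)


class TestSelectTreeMethod:
    def test_low_discrepancy_selects_wpgma(self):
        assert select_tree_method(0.08, 0.115) == WPGMA

    def test_high_discrepancy_selects_upgma(self):
        assert select_tree_method(0.20, 0.115) == UPGMA

    def test_boundary_is_strict(self):
        assert select_tree_method(0.115, 0.115) == UPGMA


class TestBuildTree:
    def test_two_taxa(self):
        tree = build_tree(np.array([[0.0, 0.4], [0.4, 0.0]]), UPGMA, ids=("a", "b"))
        assert tree.root.height == pytest.approx(0.2)
        assert sorted(tree.root.leaf_indices()) == [0, 1]

    def test_three_taxa_methods_agree(self):
        d = np.array([[0.0, 0.2, 0.6], [0.2, 0.0, 0.4], [0.6, 0.4, 0.0]])
        tu = build_tree(d, UPGMA)
        tw = build_tree(d, WPGMA)
        assert tree_partitions(tu) == tree_partitions(tw)
        # (A,B) join first at 0.1; then cluster-to-C distance is 0.5
        assert tree_partitions(tu)[0] == (pytest.approx(0.1), frozenset({0, 1}))
        assert tree_partitions(tu)[1][0] == pytest.approx(0.25)

    def test_methods_differ_when_cluster_sizes_do(self):
        """A size-2 cluster merging against a singleton separates Eq-style
        weighted and unweighted updates."""
        d = np.array(
            [
                [0.0, 0.1, 0.5, 0.9],
                [0.1, 0.0, 0.5, 0.8],
                [0.5, 0.5, 0.0, 0.55],
                [0.9, 0.8, 0.55, 0.0],
            ]
        )
        tu = build_tree(d, UPGMA)
        tw = build_tree(d, WPGMA)
        hu = [h for h, _ in tree_partitions(tu)]
        hw = [h for h, _ in tree_partitions(tw)]
        assert hu != hw

    @pytest.mark.parametrize("method,scipy_method", [(UPGMA, "average"), (WPGMA, "weighted")])
    def test_matches_scipy_linkage_on_random_matrices(self, method, scipy_method):
        rng = np.random.default_rng(7)
        for n in (4, 5, 6):
            for _ in range(5):
                d = random_distance_matrix(rng, n)
                tree = build_tree(d, method)
                ours = tree_partitions(tree)
                oracle = sorted(
                    (h / 2.0, members)
                    for h, members in scipy_linkage_partitions(d, scipy_method)
                )
                for (h1, m1), (h2, m2) in zip(ours, oracle):
                    assert m1 == m2
                    assert h1 == pytest.approx(h2)

    def test_equal_size_merges_make_methods_identical(self):
        """Balanced designs where every merge joins equal-size clusters:
        the weighted and unweighted updates coincide throughout."""
        d = np.array(
            [
                [0.0, 0.10, 0.60, 0.70],
                [0.10, 0.0, 0.65, 0.60],
                [0.60, 0.65, 0.0, 0.12],
                [0.70, 0.60, 0.12, 0.0],
            ]
        )
        tu, tw = build_tree(d, UPGMA), build_tree(d, WPGMA)
        assert tree_partitions(tu) == tree_partitions(tw)

    def test_deterministic_tie_breaking(self):
        d = np.full((4, 4), 0.5)
        np.fill_diagonal(d, 0.0)
        t1 = build_tree(d, UPGMA)
        t2 = build_tree(d, UPGMA)
        assert tree_partitions(t1) == tree_partitions(t2)
        # ties resolve toward the smallest leaf indices
        assert tree_partitions(t1)[0][1] == frozenset({0, 1})

    def test_newick_export_contains_all_ids(self):
        d = np.array([[0.0, 0.2, 0.6], [0.2, 0.0, 0.4], [0.6, 0.4, 0.0]])
        nwk = build_tree(d, UPGMA, ids=("a", "b", "c")).to_newick()
        assert nwk.endswith(";")
        for name in ("a", "b", "c"):
            assert name in nwk

    def test_invalid_matrices_rejected(self):
        with pytest.raises(InputError):
            build_tree(np.array([[0.0, 1.0], [2.0, 0.0]]), UPGMA)
        with pytest.raises(InputError):
            build_tree(np.zeros((2, 2)), "nj")


class TestDistanceMatrix:
    def test_identical_pair_distance_near_zero(self, global_hmm):
        from pnpalign.posterior import compute_posteriors
        from pnpalign.seqio import Family, Sequence

        fam = Family(
            (
                Sequence("a", "MKTAYIAKQR"),
                Sequence("b", "MKTAYIAKQR"),
                Sequence("c", "WWPGHHGWPW"),
            )
        )
        ps = compute_posteriors(fam, [global_hmm], cutoff=0.0)
        d = distance_matrix(ps, fam)
        assert d[0, 1] < 0.05
        assert d[0, 2] > d[0, 1]
        assert np.allclose(d, d.T) and np.all(np.diag(d) == 0)

    def test_all_zero_posteriors_give_distance_one(self, toy_family):
        from itertools import combinations

        from pnpalign.posterior import PosteriorSet

        mats = {
            (i, j): np.zeros((len(toy_family[i]), len(toy_family[j])))
            for i, j in combinations(range(3), 2)
        }
        d = distance_matrix(PosteriorSet(3, mats), toy_family)
        assert np.all(d[np.triu_indices(3, 1)] == 1.0)

    def test_expected_accuracy_matches_path_enumeration(self):
        """Tiny matrix: best monotone path found by brute force."""
        post = np.array([[0.6, 0.3], [0.1, 0.8]])

        def best_path(mat):
            lx, ly = mat.shape
            best = 0.0
            from itertools import combinations as comb

            # enumerate strictly increasing partial matchings
            cells = [(i, j) for i in range(lx) for j in range(ly)]
            for r in range(1, min(lx, ly) + 1):
                for subset in comb(cells, r):
                    rows = [c[0] for c in subset]
                    cols = [c[1] for c in subset]
                    if sorted(rows) == rows and sorted(cols) == cols and len(
                        set(rows)
                    ) == r and len(set(cols)) == r:
                        best = max(best, sum(mat[c] for c in subset))
            return best

        assert expected_accuracy(post) == pytest.approx(best_path(post) / 2)
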