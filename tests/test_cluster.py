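import itertools

import numpy as np
import pytest
from scipy.cluster.hierarchy import linkage
from sklearn.metrics import adjusted_rand_score

from sunhet.cluster import (
    adjusted_rand,
    cluster_purity,
    cut_tree,
    dendrogram_to_newick,
    hybrid_hkmeans,
    lloyd_kmeans,
    pairwise_euclidean,
    ward_d2_linkage,
    within_cluster_ss,
)
from sunhet.panel import ValidationError


def ward_oracle(X):
    """Exhaustive Ward.D2 agglomeration recomputed from raw coordinates.

    The merge cost of clusters A, B is sqrt(2|A||B|/(|A|+|B|)) * ||c_A - c_B||,
    evaluated afresh from the points at every step (no recurrence).
    """
    clusters = [[i] for i in range(len(X))]
    steps = []
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(range(len(clusters)), 2):
            A, B = X[clusters[a]], X[clusters[b]]
            na, nb = len(A), len(B)
            d = np.sqrt(2.0 * na * nb / (na + nb)) * np.linalg.norm(
                A.mean(axis=0) - B.mean(axis=0)
            )
            if best is None or d < best[0]:
                best = (d, a, b)
        d, a, b = best
        steps.append((frozenset(clusters[a]), frozenset(clusters[b]), d))
        clusters = [c for i, c in enumerate(clusters) if i not in (a, b)] + [
            clusters[a] + clusters[b]
        ]
    return steps


def merge_members(dend):
    """Member sets of each merge of a Dendrogram, in merge order."""
    n = dend.n_leaves
    members = {i: frozenset([i]) for i in range(n)}
    out = []
    for i, (a, b, h, _) in enumerate(dend.merges):
        ma, mb = members[int(a)], members[int(b)]
        out.append((ma, mb, h))
        members[n + i] = ma | mb
    return out


class TestDistances:
    def test_identical_rows_distance_zero(self):
        D = pairwise_euclidean(np.ones((3, 4)))
        np.testing.assert_array_equal(D, np.zeros((3, 3)))

    def test_unit_vectors(self):
        D = pairwise_euclidean(np.eye(2))
        assert D[0, 1] == pytest.approx(np.sqrt(2))

    def test_matches_double_loop_oracle(self):
        X = np.random.default_rng(0).normal(size=(10, 4))
        D = pairwise_euclidean(X)
        for i in range(10):
            for j in range(10):
                assert D[i, j] == pytest.approx(np.linalg.norm(X[i] - X[j]))


class TestWardD2:
    def test_two_points_merge_at_their_distance(self):
        X = np.array([[0.0, 0.0], [3.0, 4.0]])
        dend = ward_d2_linkage(pairwise_euclidean(X))
        assert dend.merges[0, 2] == pytest.approx(5.0)

    def test_identical_points_merge_at_zero(self):
        dend = ward_d2_linkage(np.zeros((4, 4)))
        np.testing.assert_allclose(dend.merges[:, 2], 0.0)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_exhaustive_ward_criterion_oracle(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(rng.integers(4, 9), rng.integers(2, 5)))
        dend = ward_d2_linkage(pairwise_euclidean(X))
        got = merge_members(dend)
        want = ward_oracle(X)
        for (ga, gb, gh), (wa, wb, wh) in zip(got, want):
            assert {ga, gb} == {wa, wb}
            assert gh == pytest.approx(wh)

    def test_matches_scipy_ward_heights(self):
        X = np.random.default_rng(5).normal(size=(30, 4))
        Z = linkage(X, method="ward")
        dend = ward_d2_linkage(pairwise_euclidean(X))
        np.testing.assert_allclose(dend.merges[:, 2], Z[:, 2])
        np.testing.assert_array_equal(dend.merges[:, 3], Z[:, 3])

    def test_asymmetric_matrix_rejected(self):
        D = np.array([[0.0, 1.0], [2.0, 0.0]])
        with pytest.raises(ValidationError):
            ward_d2_linkage(D)

    def test_feature_permutation_leaves_partition_unchanged(self):
        rng = np.random.default_rng(11)
        X = rng.normal(size=(20, 6))
        perm = rng.permutation(6)
        lab_a = cut_tree(ward_d2_linkage(pairwise_euclidean(X)), k=4)
        lab_b = cut_tree(ward_d2_linkage(pairwise_euclidean(X[:, perm])), k=4)
        assert adjusted_rand(lab_a, lab_b) == pytest.approx(1.0)


class TestCutTree:
    @pytest.fixture
    def dend(self):
        X = np.random.default_rng(2).normal(size=(15, 3))
        return ward_d2_linkage(pairwise_euclidean(X))

    def test_cut_above_root_gives_one_cluster(self, dend):
        labels = cut_tree(dend, height=dend.merges[:, 2].max() + 1)
        assert set(labels) == {1}

    def test_cut_below_all_merges_gives_singletons(self, dend):
        positive = dend.merges[dend.merges[:, 2] > 0, 2]
        labels = cut_tree(dend, height=positive.min() / 2)
        assert len(set(labels)) == dend.n_leaves

    @pytest.mark.parametrize("k", [2, 5, 9])
    def test_k_mode_and_height_mode_agree(self, dend, k):
        heights = np.sort(dend.merges[:, 2])
        # to get k clusters the threshold sits between the (k-1)-th and k-th
        # largest merge heights
        thresh = (heights[-(k - 1)] + heights[-k]) / 2 if k > 1 else heights[-1] + 1
        np.testing.assert_array_equal(
            cut_tree(dend, k=k), cut_tree(dend, height=thresh)
        )

    def test_labels_numbered_by_first_leaf(self, dend):
        labels = cut_tree(dend, k=4)
        assert labels[0] == 1
        seen = []
        for lab in labels:
            if lab not in seen:
                seen.append(lab)
        assert seen == sorted(seen)

    def test_k_out_of_range_rejected(self, dend):
        with pytest.raises(ValidationError):
            cut_tree(dend, k=0)
        with pytest.raises(ValidationError):
            cut_tree(dend, k=16)


class TestNewick:
    def test_round_trip_through_dendropy(self):
        dendropy = pytest.importorskip("dendropy")
        X = np.random.default_rng(3).normal(size=(8, 3))
        ids = [f"G{i}" for i in range(8)]
        dend = ward_d2_linkage(pairwise_euclidean(X), leaf_ids=ids)
        tree = dendropy.Tree.get(data=dendrogram_to_newick(dend), schema="newick")
        taxa = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
        assert taxa == set(ids)
        root_h = dend.merges[-1, 2]
        for leaf in tree.leaf_node_iter():
            assert leaf.distance_from_root() == pytest.approx(root_h)


class TestKMeans:
    def test_k_equals_n_gives_zero_wss(self):
        X = np.random.default_rng(4).normal(size=(6, 2))
        res = lloyd_kmeans(X, k=6, seed=0, n_init=3)
        assert res.wss == pytest.approx(0.0, abs=1e-12)
        assert len(set(res.labels)) == 6

    def test_k_one_gives_total_ss(self):
        X = np.random.default_rng(5).normal(size=(20, 3))
        res = lloyd_kmeans(X, k=1, seed=0)
        np.testing.assert_allclose(res.centers[0], X.mean(axis=0))
        assert res.wss == pytest.approx(((X - X.mean(axis=0)) ** 2).sum())

    def test_wss_consistent_with_labels(self):
        X = np.random.default_rng(6).normal(size=(30, 4))
        res = lloyd_kmeans(X, k=3, seed=1)
        recomputed = ((X - res.centers[res.labels - 1]) ** 2).sum()
        assert res.wss == pytest.approx(recomputed)

    def test_separated_blobs_recovered_in_200_seeded_runs(self):
        rng = np.random.default_rng(100)
        truth = np.repeat([0, 1], 20)
        X = rng.normal(size=(40, 3))
        X[truth == 1] += 10.0  # 10 sigma separation
        for seed in range(200):
            res = lloyd_kmeans(X, k=2, seed=seed, n_init=1)
            assert adjusted_rand(res.labels, truth) == pytest.approx(1.0)

    def test_deterministic_in_seed(self):
        X = np.random.default_rng(7).normal(size=(25, 3))
        a = lloyd_kmeans(X, k=4, seed=9)
        b = lloyd_kmeans(X, k=4, seed=9)
        np.testing.assert_array_equal(a.labels, b.labels)
        assert a.wss == b.wss


class TestHybrid:
    def test_wss_never_above_hierarchical_cut(self):
        for seed in range(5):
            X = np.random.default_rng(seed).normal(size=(30, 4))
            dend = ward_d2_linkage(pairwise_euclidean(X))
            hier_wss = within_cluster_ss(X, cut_tree(dend, k=5))
            assert hybrid_hkmeans(X, k=5).wss <= hier_wss + 1e-9

    def test_agrees_with_both_parents_on_separated_blobs(self):
        rng = np.random.default_rng(8)
        truth = np.repeat([0, 1], 15)
        X = rng.normal(size=(30, 2))
        X[truth == 1] += 10.0
        hk = hybrid_hkmeans(X, k=2)
        km = lloyd_kmeans(X, k=2, seed=0)
        hier = cut_tree(ward_d2_linkage(pairwise_euclidean(X)), k=2)
        assert adjusted_rand(hk.labels, truth) == pytest.approx(1.0)
        assert adjusted_rand(km.labels, truth) == pytest.approx(1.0)
        assert adjusted_rand(hier, truth) == pytest.approx(1.0)

    def test_deterministic(self):
        X = np.random.default_rng(9).normal(size=(20, 3))
        a = hybrid_hkmeans(X, k=4)
        b = hybrid_hkmeans(X, k=4)
        np.testing.assert_array_equal(a.labels, b.labels)
        assert a.wss == b.wss


class TestPartitionQuality:
    def test_purity_one_for_perfect_labels(self):
        classes = ["R"] * 5 + ["CMS"] * 5
        purity, table = cluster_purity([1] * 5 + [2] * 5, classes)
        assert purity == 1.0
        assert set(table["majority_class"]) == {"R", "CMS"}

    def test_single_cluster_purity_is_largest_class_frequency(self):
        classes = ["R"] * 7 + ["CMS"] * 3
        purity, _ = cluster_purity([1] * 10, classes)
        assert purity == pytest.approx(0.7)

    def test_purity_matches_counting_oracle(self):
        rng = np.random.default_rng(10)
        labels = rng.integers(0, 4, size=60)
        classes = rng.choice(["CMS", "B", "R", "SFP"], size=60)
        purity, _ = cluster_purity(labels, classes)
        total = 0
        for lab in np.unique(labels):
            cls, counts = np.unique(classes[labels == lab], return_counts=True)
            total += counts.max()
        assert purity == pytest.approx(total / 60)

    def test_ari_identical_partitions(self):
        labels = [1, 1, 2, 2, 3]
        assert adjusted_rand(labels, labels) == pytest.approx(1.0)

    def test_ari_matches_pair_counting_oracle(self):
        rng = np.random.default_rng(11)
        a = rng.integers(0, 3, size=12)
        b = rng.integers(0, 3, size=12)
        n11 = n00 = n10 = n01 = 0
        for i, j in itertools.combinations(range(12), 2):
            same_a, same_b = a[i] == a[j], b[i] == b[j]
            n11 += same_a and same_b
            n00 += (not same_a) and (not same_b)
            n10 += same_a and not same_b
            n01 += same_b and not same_a
        expected = 2.0 * (n11 * n00 - n10 * n01) / (
            (n11 + n10) * (n10 + n00) + (n11 + n01) * (n01 + n00)
        )
        assert adjusted_rand(a, b) == pytest.approx(expected)

    def test_ari_matches_sklearn(self):
        rng = np.random.default_rng(12)
        for _ in range(5):
            a = rng.integers(0, 5, size=40)
            b = rng.integers(0, 5, size=40)
            assert adjusted_rand(a, b) == pytest.approx(adjusted_rand_score(a, b))

    def test_ari_near_zero_under_random_permutations(self):
        rng = np.random.default_rng(13)
        labels = np.repeat(np.arange(4), 10)
        vals = [adjusted_rand(labels, rng.permutation(labels)) for _ in range(1000)]
        assert abs(np.mean(vals)) < 0.01

    def test_empty_input_rejected(self):
        with pytest.raises(ValidationError):
            adjusted_rand([], [])
        with pytest.raises(ValidationError):
            cluster_purity([], [])
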