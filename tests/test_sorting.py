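"""K-means clustering, silhouette selection and Pearson classification."""

import itertools

import numpy as np
import pytest

from synergykit import (
    DataError,
    kmeans_cluster,
    make_ground_truth,
    match_to_reference,
    select_cluster_number,
    silhouette_mean,
    similarity_rate,
    synthesize_subject,
)
from synergykit.sorting import ReferenceSynergySet, _lloyd


def _archetype_pool(rng, k=4, per=20, noise=0.05, m=10):
    """Noisy copies of k unit-norm archetype vectors, as columns."""
    gt = make_ground_truth(seed=9, m=m, k_true=k)
    cols, labels = [], []
    for j in range(k):
        for _ in range(per):
            v = gt.W_true[:, j] + rng.normal(0, noise, m)
            v = np.clip(v, 0.0, None)
            cols.append(v / np.linalg.norm(v))
            labels.append(j)
    return np.column_stack(cols), np.array(labels), gt


def _same_partition(a, b):
    return len({(x, y) for x, y in zip(a, b)}) == len(set(a)) == len(set(b))


class TestKMeans:
    def test_one_cluster_per_point_zero_distortion(self, rng):
        D = rng.random((5, 6))
        _, _, J = kmeans_cluster(D, 6, seed=0, n_init=5)
        assert J == pytest.approx(0.0, abs=1e-20)

    def test_separated_clouds_recovered(self, rng):
        a = rng.normal(0, 0.05, (4, 10))
        b = rng.normal(5, 0.05, (4, 10))
        D = np.concatenate([a, b], axis=1)
        labels, centroids, _ = kmeans_cluster(D, 2, seed=1, n_init=10)
        truth = np.array([0] * 10 + [1] * 10)
        assert _same_partition(labels, truth)
        assert centroids.shape == (4, 2)

    def test_matches_brute_force_optimum_on_small_instance(self, rng):
        """On <= 8 points the globally optimal 2-partition is enumerable;
        multi-start Lloyd must attain its distortion."""
        X = rng.random((8, 3)) + np.repeat([[0], [4]], 4, axis=0)
        best = np.inf
        for mask in itertools.product([0, 1], repeat=8):
            mask = np.array(mask)
            if mask.min() == mask.max():
                continue
            J = sum(
                np.sum((X[mask == c] - X[mask == c].mean(axis=0)) ** 2)
                for c in (0, 1)
            )
            best = min(best, J)
        _, _, J = kmeans_cluster(X.T, 2, seed=0, n_init=20)
        assert J == pytest.approx(best, abs=1e-9)

    def test_distortion_trace_non_increasing(self, rng):
        X = rng.random((30, 4))
        init = X[rng.choice(30, 3, replace=False)]
        _, _, _, trace = _lloyd(X, init, max_iter=100, tol=0.0)
        assert all(b <= a + 1e-12 for a, b in zip(trace, trace[1:]))

    def test_agrees_with_sklearn_inertia(self, rng):
        cluster = pytest.importorskip("sklearn.cluster")
        D = rng.random((6, 40))
        _, _, J = kmeans_cluster(D, 4, seed=0, n_init=30)
        km = cluster.KMeans(n_clusters=4, n_init=30, random_state=0).fit(D.T)
        assert J <= km.inertia_ * 1.01

    def test_bad_cluster_count_rejected(self, rng):
        with pytest.raises(DataError):
            kmeans_cluster(rng.random((3, 5)), 6)


class TestSilhouette:
    def test_hand_computed_two_pair_value(self):
        """1-D points {0, 0.1} vs {10, 10.1}: per-point scores follow
        directly from the (b-a)/max(a,b) definition."""
        D = np.array([[0.0, 0.1, 10.0, 10.1]])
        labels = np.array([0, 0, 1, 1])
        s0 = (10.05 - 0.1) / 10.05  # point 0: a=0.1, b=(10+10.1)/2
        s1 = (9.95 - 0.1) / 9.95  # point 0.1: b=(9.9+10)/2
        expected = (2 * s0 + 2 * s1) / 4
        assert silhouette_mean(D, labels) == pytest.approx(expected, abs=1e-12)

    def test_identical_points_score_zero(self):
        D = np.ones((3, 6))
        assert silhouette_mean(D, np.array([0, 0, 0, 1, 1, 1])) == 0.0

    def test_bounded_and_relabel_and_scale_invariant(self, rng):
        D = rng.random((5, 24))
        labels = rng.integers(0, 3, 24)
        if len(np.unique(labels)) < 2:
            labels[0], labels[1] = 0, 1
        s = silhouette_mean(D, labels)
        assert -1.0 <= s <= 1.0
        assert silhouette_mean(D, 2 - labels) == pytest.approx(s, abs=1e-12)
        assert silhouette_mean(10.0 * D, labels) == pytest.approx(s, abs=1e-12)

    def test_matches_sklearn(self, rng):
        metrics = pytest.importorskip("sklearn.metrics")
        D = rng.random((6, 30))
        labels = rng.integers(0, 3, 30)
        labels[:3] = [0, 1, 2]
        ours = silhouette_mean(D, labels)
        theirs = metrics.silhouette_score(D.T, labels)
        assert ours == pytest.approx(theirs, abs=1e-9)

    def test_single_cluster_rejected(self, rng):
        with pytest.raises(DataError):
            silhouette_mean(rng.random((3, 5)), np.zeros(5, dtype=int))


class TestClusterNumberSelection:
    def test_four_archetypes_select_four(self, rng):
        D, _, _ = _archetype_pool(rng, k=4)
        refs = select_cluster_number(D, seed=0, n_init=20)
        assert refs.i == 4
        assert refs.n_refs == 4

    def test_two_archetypes_select_two(self, rng):
        D, _, _ = _archetype_pool(rng, k=2)
        refs = select_cluster_number(D, seed=0, n_init=20)
        assert refs.i == 2

    def test_centroids_match_archetypes(self, rng):
        D, _, gt = _archetype_pool(rng, k=4, noise=0.03)
        refs = select_cluster_number(D, seed=0, n_init=20)
        cos = refs.centroids.T @ gt.W_true  # unit-norm columns both sides
        cos = cos / np.linalg.norm(refs.centroids, axis=0)[:, None]
        assert sorted(cos.max(axis=1)) == pytest.approx([1.0] * 4, abs=0.05)
        assert min(cos.max(axis=1)) > 0.95

    def test_deterministic_under_fixed_seed(self, rng):
        D, _, _ = _archetype_pool(rng, k=3)
        r1 = select_cluster_number(D, seed=5, n_init=10)
        r2 = select_cluster_number(D, seed=5, n_init=10)
        assert r1.i == r2.i
        assert np.array_equal(r1.centroids, r2.centroids)


def _refs_from(centroids):
    k = centroids.shape[1]
    return ReferenceSynergySet(
        centroids=centroids,
        assignment=np.arange(k),
        distortion=0.0,
        silhouette=1.0,
        i=k,
    )


class TestMatching:
    def test_centroid_matches_itself_perfectly(self, rng):
        cents = rng.random((10, 3)) + 0.1
        cents /= np.linalg.norm(cents, axis=0)
        refs = _refs_from(cents)
        ms = match_to_reference(cents[:, [1]], refs)
        assert ms[0].classified
        assert ms[0].best_ref == 1
        assert ms[0].r == pytest.approx(1.0, abs=1e-12)

    def test_uncorrelated_vector_unclassified(self):
        cents = np.zeros((10, 1))
        cents[:5, 0] = 1.0
        cents /= np.linalg.norm(cents, axis=0)
        w = np.zeros((10, 1))
        w[::2, 0] = 1.0  # r ~ 0 against the block centroid
        ms = match_to_reference(w, _refs_from(cents))
        assert not ms[0].classified

    def test_small_noise_always_recovers_assignment(self, rng):
        """A centroid perturbed by sigma=0.05 noise stays above the 0.6
        correlation gate for its own centroid, across 100 draws."""
        gt = make_ground_truth(seed=9)
        refs = _refs_from(gt.W_true)
        hits = 0
        for _ in range(100):
            j = rng.integers(0, 4)
            w = gt.W_true[:, j] + rng.normal(0, 0.05, 10)
            ms = match_to_reference(w[:, None], refs)
            hits += ms[0].classified and ms[0].best_ref == j
        assert hits == 100

    def test_permutation_equivariant_in_centroid_order(self, rng):
        cents = rng.random((8, 4)) + 0.1
        w = rng.random((8, 2))
        perm = np.array([2, 0, 3, 1])
        m1 = match_to_reference(w, _refs_from(cents))
        m2 = match_to_reference(w, _refs_from(cents[:, perm]))
        for a, b in zip(m1, m2):
            assert np.allclose(a.r_values[perm], b.r_values)
            assert perm[b.best_ref] == a.best_ref

    def test_zero_variance_vector_warns_unclassified(self):
        cents = np.eye(4)[:, :2]
        with pytest.warns(UserWarning, match="zero variance"):
            ms = match_to_reference(np.ones((4, 1)), _refs_from(cents))
        assert not ms[0].classified


class TestSimilarityRate:
    def test_all_and_none_classified(self, rng):
        cents = rng.random((6, 2)) + 0.1
        refs = _refs_from(cents)
        ms = match_to_reference(cents, refs)
        assert similarity_rate(ms) == 100.0
        for m in ms:
            m.classified = False
        assert similarity_rate(ms) == 0.0

    def test_patient_like_group_matches_less(self, ground_truth):
        """Greater modular heterogeneity in the patient-like group lowers
        its similarity rate against healthy-derived references."""
        refs = _refs_from(ground_truth.W_true)
        mh, mc = [], []
        for s in range(12):
            sub_h = synthesize_subject(ground_truth, "healthy", subject_seed=s)
            sub_c = synthesize_subject(ground_truth, "CAI", subject_seed=100 + s)
            mh += match_to_reference(sub_h.W_subject, refs)
            mc += match_to_reference(sub_c.W_subject, refs)
        assert similarity_rate(mh) > similarity_rate(mc)
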