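"""Normalisation, PCA, clustering, selection, LOIO similarity, MDS."""

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from scenersa.stimulus_selection import (cluster_kmeans, fit_pca,
                                         loio_similarity_matrix, mds_embed,
                                         normalize_corpus, select_stimuli)

RNG = np.random.default_rng(1)


def loio_bruteforce(vectors, labels):
    """Independent enumeration of every leave-one-out iteration."""
    clusters = np.unique(labels)
    members = [sorted(np.flatnonzero(labels == c)) for c in clusters]
    k, n = len(clusters), len(members[0])
    acc = np.zeros((k, k))
    for j in range(n):
        for a in range(k):
            rest = [m for idx, m in enumerate(members[a]) if idx != j]
            mean_a = np.mean([vectors[m] for m in rest], axis=0)
            for b in range(k):
                left = vectors[members[b][j]]
                acc[a, b] += np.corrcoef(mean_a, left)[0, 1]
    m = acc / n
    return 0.5 * (m + m.T)


class TestNormalize:
    def test_hand_worked_two_image_example(self):
        raw = np.array([[1.0, 0.0, 2.0], [1.0, 2.0, 2.0]])
        out = normalize_corpus(raw).matrix
        np.testing.assert_allclose(out[0], [0.7071, 0.0, 0.7071], atol=1e-4)
        np.testing.assert_allclose(out[1], [0.4082, 0.8165, 0.4082], atol=1e-4)

    def test_identical_images_give_identical_unit_rows(self):
        raw = np.tile(RNG.random(8), (5, 1))
        out = normalize_corpus(raw).matrix
        np.testing.assert_allclose(out, np.tile(out[0], (5, 1)))
        np.testing.assert_allclose(np.linalg.norm(out, axis=1), 1.0, atol=1e-9)

    def test_rows_unit_magnitude(self):
        out = normalize_corpus(RNG.random((20, 30))).matrix
        np.testing.assert_allclose(np.linalg.norm(out, axis=1), 1.0, atol=1e-9)

    def test_negative_entries_rejected(self):
        with pytest.raises(ValueError):
            normalize_corpus(np.array([[1.0, -0.5]]))

    def test_zero_column_and_row_left_zero(self):
        raw = np.array([[0.0, 1.0], [0.0, 2.0], [0.0, 0.0]])
        out = normalize_corpus(raw)
        assert np.all(out.matrix[:, 0] == 0)
        assert 2 in out.zero_rows


class TestPca:
    def test_exact_2d_subspace_captures_all_variance(self):
        basis = RNG.standard_normal((2, 10))
        data = RNG.standard_normal((50, 2)) @ basis + RNG.standard_normal(10)
        space, _ = fit_pca(data, n_components=2)
        assert space.variance_fractions.sum() == pytest.approx(1.0, abs=1e-9)

    def test_variance_fractions_match_covariance_eigenvalues(self):
        data = RNG.standard_normal((40, 6))
        space, _ = fit_pca(data, n_components=5)
        eigvals = np.sort(np.linalg.eigvalsh(np.cov(data.T)))[::-1]
        expected = eigvals[:5] / eigvals.sum()
        np.testing.assert_allclose(space.variance_fractions, expected, atol=1e-8)

    def test_axes_orthonormal(self):
        space, _ = fit_pca(RNG.standard_normal((30, 12)), n_components=6)
        gram = space.component_axes @ space.component_axes.T
        assert np.max(np.abs(gram - np.eye(6))) < 1e-8

    def test_low_rank_round_trip(self):
        basis = RNG.standard_normal((3, 8))
        data = RNG.standard_normal((25, 3)) @ basis
        space, scores = fit_pca(data, n_components=3)
        np.testing.assert_allclose(space.reconstruct(scores), data, atol=1e-8)

    def test_too_many_components_rejected(self):
        with pytest.raises(ValueError):
            fit_pca(RNG.standard_normal((5, 10)), n_components=5)


class TestKmeans:
    @pytest.fixture(scope="class")
    def blobs(self):
        centers = np.array([[0, 0], [10, 0], [0, 10], [10, 10]], dtype=float)
        labels = np.repeat(np.arange(4), 25)
        rng = np.random.default_rng(2)
        return centers[labels] + 0.3 * rng.standard_normal((100, 2)), labels

    def test_separated_blobs_recovered(self, blobs):
        x, labels = blobs
        model = cluster_kmeans(x, k=4, seed=0)
        assert adjusted_rand_score(labels, model.assignments) == 1.0

    def test_restarts_never_hurt(self, blobs):
        x, _ = blobs
        one = cluster_kmeans(x, k=4, n_restarts=1, seed=5)
        ten = cluster_kmeans(x, k=4, n_restarts=10, seed=5)
        assert ten.inertia <= one.inertia + 1e-9

    def test_deterministic(self, blobs):
        x, _ = blobs
        a = cluster_kmeans(x, k=4, seed=3)
        b = cluster_kmeans(x, k=4, seed=3)
        assert np.array_equal(a.assignments, b.assignments)

    def test_assignments_are_nearest_centroid(self, blobs):
        x, _ = blobs
        model = cluster_kmeans(x, k=4, seed=0)
        d = np.linalg.norm(x[:, None] - model.centroids[None], axis=2)
        np.testing.assert_array_equal(model.assignments, np.argmin(d, axis=1))


class TestSelect:
    def test_240_images_selected_under_study_parameters(self):
        rng = np.random.default_rng(3)
        centers = rng.standard_normal((10, 5)) * 20
        labels = np.repeat(np.arange(10), 40)
        x = centers[labels] + rng.standard_normal((400, 5))
        model = cluster_kmeans(x, k=10, seed=0)
        selected = select_stimuli(x, model, n_per_cluster=24)
        assert selected.n_images == 240
        assert all(len(v) == 24 for v in selected.cluster_images.values())

    def test_selected_distances_dominate_unselected(self):
        rng = np.random.default_rng(4)
        x = rng.standard_normal((60, 3))
        model = cluster_kmeans(x, k=3, seed=0)
        selected = select_stimuli(x, model, n_per_cluster=5)
        for c, sel_ids in selected.cluster_images.items():
            members = np.flatnonzero(model.assignments == c)
            d = np.linalg.norm(x[members] - model.centroids[c], axis=1)
            unsel = np.setdiff1d(members, sel_ids)
            if unsel.size:
                d_unsel = np.linalg.norm(x[unsel] - model.centroids[c], axis=1)
                assert selected.distances[c].max() <= d_unsel.min() + 1e-12

    def test_tied_distances_break_by_image_id(self):
        x = np.zeros((6, 2))      # all points coincide: every distance ties
        model = cluster_kmeans(x, k=1, seed=0)
        selected = select_stimuli(x, model, n_per_cluster=3)
        np.testing.assert_array_equal(selected.cluster_images[0], [0, 1, 2])

    def test_underfull_cluster_rejected_with_index(self):
        x = np.vstack([np.zeros((3, 2)), np.ones((30, 2)) * 9])
        model = cluster_kmeans(x, k=2, seed=0)
        with pytest.raises(ValueError, match="cluster"):
            select_stimuli(x, model, n_per_cluster=10)


class TestLoioSimilarity:
    def test_orthogonal_constructed_clusters(self):
        # cluster c's images all equal a cluster-specific vector; vectors
        # mutually uncorrelated after mean-centring
        base = np.array([[1.0, -1.0, 1.0, -1.0],
                         [1.0, 1.0, -1.0, -1.0],
                         [1.0, -1.0, -1.0, 1.0]])
        vectors = np.repeat(base, 3, axis=0)
        labels = np.repeat(np.arange(3), 3)
        m = loio_similarity_matrix(vectors, labels).entries
        np.testing.assert_allclose(np.diag(m), 1.0, atol=1e-9)
        np.testing.assert_allclose(m - np.diag(np.diag(m)), 0.0, atol=1e-9)

    def test_matches_bruteforce_enumeration(self):
        vectors = RNG.standard_normal((6, 4))
        labels = np.array([0, 0, 0, 1, 1, 1])
        ours = loio_similarity_matrix(vectors, labels).entries
        np.testing.assert_allclose(ours, loio_bruteforce(vectors, labels), atol=1e-12)

    def test_matches_bruteforce_on_larger_set(self):
        vectors = RNG.standard_normal((20, 7))
        labels = np.repeat(np.arange(4), 5)
        ours = loio_similarity_matrix(vectors, labels).entries
        np.testing.assert_allclose(ours, loio_bruteforce(vectors, labels), atol=1e-12)

    def test_symmetric_unit_bounded(self):
        vectors = RNG.standard_normal((12, 5))
        labels = np.repeat(np.arange(3), 4)
        m = loio_similarity_matrix(vectors, labels).entries
        assert np.allclose(m, m.T)
        assert np.all(np.abs(m) <= 1.0 + 1e-12)

    def test_unequal_cluster_sizes_rejected(self):
        with pytest.raises(ValueError):
            loio_similarity_matrix(RNG.standard_normal((5, 3)), [0, 0, 0, 1, 1])

    def test_permutation_behaviour(self):
        """Relabelling whole clusters permutes the matrix consistently, and
        the diagonal is invariant to any image reordering.

        The off-diagonals are averages over cross-cluster pairings of
        left-out images, so they legitimately depend on within-cluster
        order; only the diagonal pairs each image against its own cluster's
        mean regardless of order.
        """
        vectors = RNG.standard_normal((12, 5))
        labels = np.repeat(np.arange(3), 4)
        base = loio_similarity_matrix(vectors, labels).entries
        # cluster relabelling 0->2, 1->0, 2->1
        relabel = np.array([2, 0, 1])
        swapped = loio_similarity_matrix(vectors, relabel[labels]).entries
        np.testing.assert_allclose(swapped[np.ix_(relabel, relabel)], base, atol=1e-12)
        # within-cluster shuffling preserves the diagonal
        perm = np.concatenate([RNG.permutation(np.flatnonzero(labels == c))
                               for c in range(3)])
        shuffled = loio_similarity_matrix(vectors[perm], labels[perm]).entries
        np.testing.assert_allclose(np.diag(shuffled), np.diag(base), atol=1e-12)


class TestMds:
    def test_three_equidistant_clusters(self):
        s = np.full((3, 3), 0.2)
        np.fill_diagonal(s, 1.0)
        coords = mds_embed(s, dims=2)
        d01 = np.linalg.norm(coords[0] - coords[1])
        d02 = np.linalg.norm(coords[0] - coords[2])
        d12 = np.linalg.norm(coords[1] - coords[2])
        assert d01 == pytest.approx(d02, abs=1e-6)
        assert d01 == pytest.approx(d12, abs=1e-6)

    def test_exact_1d_structure_gives_flat_second_axis(self):
        x = np.array([0.0, 1.0, 2.0, 3.0])
        d = np.abs(x[:, None] - x[None]) / 10.0
        coords = mds_embed(1.0 - d, dims=2)
        assert np.max(np.abs(coords[:, 1])) < 1e-8
        # embedded distances reproduce the line configuration
        got = np.abs(coords[:, 0][:, None] - coords[:, 0][None])
        np.testing.assert_allclose(got, d, atol=1e-8)

    def test_identical_clusters_coincide(self):
        coords = mds_embed(np.ones((4, 4)), dims=2)
        assert np.max(np.abs(coords)) < 1e-8

    def test_asymmetric_input_rejected(self):
        s = np.eye(3)
        s[0, 1] = 0.5
        with pytest.raises(ValueError):
            mds_embed(s)
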