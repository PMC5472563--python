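"""Data-driven stimulus selection from a GIST-described image corpus.

The pipeline: normalise the corpus descriptor matrix, reduce to 20 principal
components, k-means cluster (k = 10), pick the 24 images nearest each
centroid, and summarise the geometry of the selected set with a
leave-one-image-out cross-validated correlation similarity matrix and a
classical MDS embedding.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .core import KIND_CORRELATION, SimilarityMatrix


@dataclass
class GistCorpusMatrix:
    """Normalised per-image descriptor matrix (rows unit-magnitude)."""

    matrix: np.ndarray
    image_ids: np.ndarray
    normalised: bool = True
    zero_rows: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))


@dataclass
class PcaSpace:
    component_axes: np.ndarray       # (n_components, n_features), orthonormal rows
    mean_vector: np.ndarray
    variance_fractions: np.ndarray   # nonincreasing, each in [0, 1]

    def project(self, x: np.ndarray) -> np.ndarray:
        return (np.asarray(x, dtype=float) - self.mean_vector) @ self.component_axes.T

    def reconstruct(self, scores: np.ndarray) -> np.ndarray:
        return np.asarray(scores, dtype=float) @ self.component_axes + self.mean_vector


@dataclass
class ClusterModel:
    centroids: np.ndarray
    assignments: np.ndarray
    inertia: float


@dataclass
class StimulusSet:
    """Per-cluster ordered image-id lists with distances to own centroid."""

    cluster_images: dict[int, np.ndarray]   # cluster -> selected image ids
    distances: dict[int, np.ndarray]        # cluster -> matching distances

    @property
    def n_clusters(self) -> int:
        return len(self.cluster_images)

    @property
    def n_images(self) -> int:
        return sum(len(v) for v in self.cluster_images.values())

    def all_image_ids(self) -> np.ndarray:
        return np.concatenate([self.cluster_images[c] for c in sorted(self.cluster_images)])

    def cluster_labels(self) -> np.ndarray:
        return np.concatenate([
            np.full(len(self.cluster_images[c]), c, dtype=int)
            for c in sorted(self.cluster_images)
        ])


def normalize_corpus(raw: np.ndarray, image_ids: np.ndarray | None = None) -> GistCorpusMatrix:
    """Two-step corpus normalisation.

    Step 1 scales each descriptor component to sum to 1 across images
    (column sums become 1; all-zero columns are left zero). Step 2 scales
    each image's vector to unit magnitude (all-zero rows left zero and
    flagged).
    """
    raw = np.asarray(raw, dtype=float)
    if raw.ndim != 2 or raw.shape[0] < 1:
        raise ValueError("expected a nonempty (n_images, n_features) matrix")
    if np.any(raw < 0):
        raise ValueError("descriptor energies must be nonnegative")
    if image_ids is None:
        image_ids = np.arange(raw.shape[0])
    col_sums = raw.sum(axis=0)
    scaled = np.divide(raw, col_sums, out=np.zeros_like(raw), where=col_sums > 0)
    norms = np.linalg.norm(scaled, axis=1)
    zero_rows = np.flatnonzero(norms == 0)
    if zero_rows.size:
        warnings.warn(f"{zero_rows.size} all-zero descriptor rows left unnormalised")
    unit = np.divide(scaled, norms[:, None], out=np.zeros_like(scaled),
                     where=norms[:, None] > 0)
    return GistCorpusMatrix(unit, np.asarray(image_ids), normalised=True, zero_rows=zero_rows)


def _fix_signs(axes: np.ndarray, scores: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    # deterministic convention: largest-magnitude loading of each axis positive
    for i in range(axes.shape[0]):
        j = int(np.argmax(np.abs(axes[i])))
        if axes[i, j] < 0:
            axes[i] *= -1.0
            scores[:, i] *= -1.0
    return axes, scores


def fit_pca(corpus: GistCorpusMatrix | np.ndarray, n_components: int = 20
            ) -> tuple[PcaSpace, np.ndarray]:
    """Mean-centred PCA (no whitening) with a deterministic sign convention."""
    x = corpus.matrix if isinstance(corpus, GistCorpusMatrix) else np.asarray(corpus, dtype=float)
    n_images, n_features = x.shape
    if n_components > min(n_images - 1, n_features):
        raise ValueError(
            f"n_components={n_components} exceeds min(n_images-1, n_features)="
            f"{min(n_images - 1, n_features)}")
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(x)
    axes, scores = _fix_signs(pca.components_.copy(), scores)
    space = PcaSpace(axes, pca.mean_.copy(), pca.explained_variance_ratio_.copy())
    return space, scores


def cluster_kmeans(scores: np.ndarray, k: int = 10, n_restarts: int = 10,
                   seed: int = 0) -> ClusterModel:
    """Best-of-restarts k-means with Euclidean distance (k-means++ init).

    Final assignments are recomputed so that every point sits at its nearest
    centroid (ties broken toward the lowest cluster index). An empty cluster
    is re-seeded at the point farthest from its current centroid.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.shape[0] < k:
        raise ValueError(f"need at least k={k} points, got {scores.shape[0]}")
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed, algorithm="lloyd")
    km.fit(scores)
    centroids = km.cluster_centers_.copy()
    for _ in range(k):
        d = cdist(scores, centroids)
        assignments = np.argmin(d, axis=1)
        empty = np.setdiff1d(np.arange(k), np.unique(assignments))
        if empty.size == 0:
            break
        farthest = int(np.argmax(d[np.arange(len(scores)), assignments]))
        centroids[empty[0]] = scores[farthest]
    inertia = float(np.sum((scores - centroids[assignments]) ** 2))
    return ClusterModel(centroids, assignments, inertia)


def select_stimuli(scores: np.ndarray, model: ClusterModel,
                   n_per_cluster: int = 24,
                   image_ids: np.ndarray | None = None) -> StimulusSet:
    """Select the ``n_per_cluster`` members nearest each centroid.

    Ties in distance are broken by image-id order, so selection is
    deterministic.
    """
    scores = np.asarray(scores, dtype=float)
    if image_ids is None:
        image_ids = np.arange(scores.shape[0])
    image_ids = np.asarray(image_ids)
    k = model.centroids.shape[0]
    cluster_images: dict[int, np.ndarray] = {}
    distances: dict[int, np.ndarray] = {}
    for c in range(k):
        members = np.flatnonzero(model.assignments == c)
        if members.size < n_per_cluster:
            raise ValueError(
                f"cluster {c} has only {members.size} members, "
                f"needs {n_per_cluster}")
        d = np.linalg.norm(scores[members] - model.centroids[c], axis=1)
        order = np.lexsort((image_ids[members], d))[:n_per_cluster]
        cluster_images[c] = image_ids[members][order]
        distances[c] = d[order]
    return StimulusSet(cluster_images, distances)


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    # ptp check catches constant vectors exactly, before mean-subtraction
    # round-off can leave a spuriously tiny but nonzero residual
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        warnings.warn("zero-variance vector in correlation; reporting 0")
        return 0.0
    a = a - a.mean()
    b = b - b.mean()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        warnings.warn("zero-variance vector in correlation; reporting 0")
        return 0.0
    return float(np.clip(a @ b / (na * nb), -1.0, 1.0))


def loio_similarity_matrix(vectors: np.ndarray, cluster_labels: np.ndarray,
                           n_per_cluster: int | None = None) -> SimilarityMatrix:
    """Leave-one-image-out cross-validated cluster similarity.

    On iteration j, the j-th member of every cluster (members ordered by
    index) is left out; cluster means are computed over the remaining n-1
    members; each left-out vector is Pearson-correlated against every
    cluster mean, filling M[group_cluster, leftout_cluster]. Iteration
    matrices are averaged and the result symmetrised by (M + M.T)/2.
    """
    vectors = np.asarray(vectors, dtype=float)
    cluster_labels = np.asarray(cluster_labels)
    clusters = np.unique(cluster_labels)
    k = clusters.size
    members = [np.flatnonzero(cluster_labels == c) for c in clusters]
    sizes = {m.size for m in members}
    if len(sizes) != 1:
        raise ValueError("leave-one-image-out similarity requires equal cluster sizes")
    size = sizes.pop()
    if size < 2:
        raise ValueError("need at least 2 images per cluster")
    if n_per_cluster is None:
        n_per_cluster = size
    if n_per_cluster != size:
        raise ValueError(f"n_per_cluster={n_per_cluster} != cluster size {size}")
    folds = np.empty((n_per_cluster, k, k))
    for j in range(n_per_cluster):
        left_out = np.array([m[j] for m in members])
        means = np.stack([
            vectors[np.delete(m, j)].mean(axis=0) for m in members
        ])
        for a in range(k):          # group-mean cluster
            for b in range(k):      # left-out cluster
                folds[j, a, b] = _pearson(means[a], vectors[left_out[b]])
    mean_matrix = folds.mean(axis=0)
    sym = 0.5 * (mean_matrix + mean_matrix.T)
    return SimilarityMatrix(sym, kind=KIND_CORRELATION, fold_stack=folds)


def mds_embed(similarity: SimilarityMatrix | np.ndarray, dims: int = 2) -> np.ndarray:
    """Classical (Torgerson) MDS of dissimilarity 1 - r.

    Coordinates are centred at the origin; if fewer than ``dims`` positive
    eigenvalues exist, remaining coordinates are zero-padded with a warning.
    Column signs follow the largest-magnitude-coordinate-positive convention.
    """
    s = similarity.entries if isinstance(similarity, SimilarityMatrix) else np.asarray(similarity, dtype=float)
    if not np.allclose(s, s.T, atol=1e-8):
        raise ValueError("mds_embed requires a symmetric similarity matrix")
    d = 1.0 - s
    np.fill_diagonal(d, 0.0)
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d ** 2) @ j
    eigvals, eigvecs = np.linalg.eigh(b)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    positive = eigvals > 1e-12
    n_pos = int(np.sum(positive[:dims]))
    coords = np.zeros((n, dims))
    if n_pos < dims:
        warnings.warn(f"only {n_pos} positive eigenvalues; padding {dims - n_pos} dims with zeros")
    coords[:, :n_pos] = eigvecs[:, :n_pos] * np.sqrt(eigvals[:n_pos])
    for i in range(n_pos):
        jmax = int(np.argmax(np.abs(coords[:, i])))
        if coords[jmax, i] < 0:
            coords[:, i] *= -1.0
    return coords
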