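"""Synthetic inputs with known ground truth for every pipeline stage.

Generators produce: (a) texture corpora whose latent group structure aligns
with exactly what the GIST descriptor measures (orientation, spatial period,
spatial location); (b) multi-subject condition x voxel datasets whose
population condition-correlation structure converges to a chosen model
matrix; (c) fMRI time series from a design and betas; (d) card sorts driven
by a noisy prototype-affinity process; (e) labelled pixel masks over the
semantic vocabulary. Every generator is a pure function of its arguments
including the seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import check_unit_diagonal_symmetric
from .neural_patterns import BetaMaps, DesignMatrix
from .semantic_model import UNLABELLED, LabelMask, default_vocabulary

_ORIENTATIONS_DEG = (0.0, 45.0, 90.0, 135.0)
_PERIODS_PX = (4, 8, 16, 32)


@dataclass
class SyntheticCorpus:
    images: np.ndarray                 # (n_images, size, size), values in [0, 1]
    group_labels: np.ndarray
    params: dict


@dataclass
class SyntheticVoxelDataset:
    subjects: list[np.ndarray]         # each (n_conditions, n_voxels)
    model_matrix: np.ndarray
    signal_sd: float
    noise_sd: float
    seed: int
    shrinkage: float = 0.0


@dataclass
class SyntheticCardSortSet:
    sorts: list[np.ndarray]            # per subject: card -> stack index
    card_clusters: np.ndarray          # card -> cluster index (shared layout)
    true_similarity: np.ndarray
    cards_per_cluster: int
    n_stacks: int
    noise: float
    seed: int


def _group_signature(group: int, size: int) -> np.ndarray:
    """Deterministic latent texture for one group.

    A group owns one grating orientation, one spatial period, and one active
    quadrant — the three attributes the GIST descriptor pools over.
    """
    ori = _ORIENTATIONS_DEG[group % 4]
    period = _PERIODS_PX[(group // 4) % 4]
    quadrant = (group // 16) % 4
    yy, xx = np.mgrid[0:size, 0:size].astype(float)
    theta = np.deg2rad(ori)
    phase = 2.0 * np.pi * (xx * np.cos(theta) + yy * np.sin(theta)) / period
    grating = 0.5 + 0.35 * np.sin(phase)
    half = size // 2
    mask = np.zeros((size, size))
    r0, c0 = divmod(quadrant, 2)
    mask[r0 * half:(r0 + 1) * half, c0 * half:(c0 + 1) * half] = 1.0
    return 0.5 + (grating - 0.5) * mask


def generate_texture_corpus(n_images: int, n_groups: int, image_size: int = 64,
                            noise_sd: float = 0.05, seed: int = 0) -> SyntheticCorpus:
    """Corpus of grating textures in ``n_groups`` latent groups.

    Each image is its group's signature texture plus iid pixel noise of SD
    ``noise_sd``, clipped to [0, 1]. Group sizes are as equal as possible.
    """
    if n_images < 1:
        raise ValueError("n_images must be >= 1")
    if not 1 <= n_groups <= n_images:
        raise ValueError("need n_images >= n_groups >= 1")
    if image_size < 32 or (image_size & (image_size - 1)) != 0:
        raise ValueError("image_size must be a power of two >= 32")
    if n_groups > 64:
        raise ValueError("at most 64 distinct group signatures available")
    rng = np.random.default_rng(seed)
    labels = np.arange(n_images) % n_groups
    signatures = np.stack([_group_signature(g, image_size) for g in range(n_groups)])
    images = signatures[labels]
    if noise_sd > 0:
        images = images + rng.normal(0.0, noise_sd, size=images.shape)
    images = np.clip(images, 0.0, 1.0)
    params = dict(n_images=n_images, n_groups=n_groups, image_size=image_size,
                  noise_sd=noise_sd, seed=seed)
    return SyntheticCorpus(images, labels, params)


def shrink_to_psd(model_matrix: np.ndarray, extra: float = 1e-6) -> tuple[np.ndarray, float]:
    """Shrink a unit-diagonal similarity matrix toward the identity until PSD.

    Returns ``(1 - lam) * M + lam * I`` with the smallest ``lam`` restoring
    positive semi-definiteness, plus ``extra``. A PSD input gets only the
    ``extra`` nudge (which also regularises the Cholesky factorisation).
    """
    check_unit_diagonal_symmetric(model_matrix)
    m = np.asarray(model_matrix, dtype=float)
    eigmin = float(np.linalg.eigvalsh(m).min())
    lam = 0.0 if eigmin >= 0 else -eigmin / (1.0 - eigmin)
    lam = min(lam + extra, 1.0)
    k = m.shape[0]
    return (1.0 - lam) * m + lam * np.eye(k), lam


def generate_voxel_dataset(n_subjects: int, n_conditions: int, n_voxels: int,
                           model_matrix: np.ndarray, signal_sd: float = 1.0,
                           noise_sd: float = 0.5, seed: int = 0,
                           shrinkage: float | None = None) -> SyntheticVoxelDataset:
    """Multi-subject condition x voxel patterns with a planted similarity.

    One shared signal matrix is drawn as ``L @ Z`` (L the Cholesky factor of
    the shrunk model matrix, Z iid normal across voxels), so across voxels
    the condition-by-condition correlation converges to the model matrix as
    n_voxels grows. Each subject observes signal plus iid noise of SD
    ``noise_sd``. The mean across conditions per voxel is left free;
    normalisation happens downstream in the MVPA.
    """
    if n_subjects < 1 or n_conditions < 2 or n_voxels < 1:
        raise ValueError("need n_subjects >= 1, n_conditions >= 2, n_voxels >= 1")
    if shrinkage is None:
        target, lam = shrink_to_psd(model_matrix)
    else:
        check_unit_diagonal_symmetric(model_matrix)
        lam = shrinkage
        k = np.asarray(model_matrix).shape[0]
        target = (1.0 - lam) * np.asarray(model_matrix, dtype=float) + lam * np.eye(k)
        eigmin = float(np.linalg.eigvalsh(target).min())
        if eigmin < 0:
            raise ValueError(
                f"model matrix not PSD after shrinkage {lam}: "
                f"most negative eigenvalue {eigmin:.6g}")
    rng = np.random.default_rng(seed)
    chol = np.linalg.cholesky(target)
    z = rng.standard_normal((n_conditions, n_voxels))
    signal = signal_sd * (chol @ z)
    subjects = []
    for _ in range(n_subjects):
        noise = rng.normal(0.0, noise_sd, size=signal.shape) if noise_sd > 0 else 0.0
        subjects.append(signal + noise)
    return SyntheticVoxelDataset(subjects, np.asarray(model_matrix, dtype=float),
                                 signal_sd, noise_sd, seed, shrinkage=lam)


def generate_timeseries(design: DesignMatrix, betas: BetaMaps,
                        noise_sd: float = 0.0, seed: int = 0) -> np.ndarray:
    """4D time series = design x betas + Gaussian noise."""
    k = betas.n_conditions
    if design.n_task != k:
        raise ValueError(
            f"design has {design.n_task} task columns, betas have {k} conditions")
    rng = np.random.default_rng(seed)
    flat = betas.data.reshape(k, -1)
    series = design.task_matrix @ flat          # (t, voxels)
    if noise_sd > 0:
        series = series + rng.normal(0.0, noise_sd, size=series.shape)
    t = series.shape[0]
    return np.moveaxis(series.reshape(t, *betas.vol_shape), 0, -1)


def _merge_groups(similarity: np.ndarray, threshold: float) -> list[list[int]]:
    """Connected components of clusters with similarity above the threshold."""
    k = similarity.shape[0]
    parent = list(range(k))

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for i in range(k):
        for j in range(i + 1, k):
            if similarity[i, j] > threshold:
                parent[find(i)] = find(j)
    groups: dict[int, list[int]] = {}
    for i in range(k):
        groups.setdefault(find(i), []).append(i)
    return [sorted(g) for g in sorted(groups.values())]


def generate_cardsorts(true_similarity: np.ndarray, n_subjects: int,
                       cards_per_cluster: int = 6, n_stacks: int = 10,
                       noise: float = 0.0, seed: int = 0,
                       merge_threshold: float = 0.5) -> SyntheticCardSortSet:
    """Card sorts from a noisy prototype-affinity process.

    Clusters whose similarity exceeds ``merge_threshold`` share a stack
    prototype; a card from cluster c is assigned the stack maximising the
    prototype affinity (mean similarity of c to the prototype's clusters)
    plus Gaussian noise of SD ``noise``. Stacks without prototypes have
    baseline affinity 0, so they fill only through noise.
    """
    check_unit_diagonal_symmetric(true_similarity)
    if n_stacks < 1 or cards_per_cluster < 1:
        raise ValueError("n_stacks and cards_per_cluster must be >= 1")
    sim = np.asarray(true_similarity, dtype=float)
    k = sim.shape[0]
    groups = _merge_groups(sim, merge_threshold)
    if len(groups) > n_stacks:
        raise ValueError(f"{len(groups)} prototype groups exceed n_stacks={n_stacks}")
    affinity = np.zeros((k, n_stacks))
    for s, group in enumerate(groups):
        affinity[:, s] = sim[:, group].mean(axis=1)
    card_clusters = np.repeat(np.arange(k), cards_per_cluster)
    rng = np.random.default_rng(seed)
    sorts = []
    for _ in range(n_subjects):
        scores = affinity[card_clusters]
        if noise > 0:
            scores = scores + rng.normal(0.0, noise, size=scores.shape)
        sorts.append(np.argmax(scores, axis=1))
    return SyntheticCardSortSet(sorts, card_clusters, sim, cards_per_cluster,
                                n_stacks, noise, seed)


def generate_label_masks(n_images: int, vocabulary: list[str] | None = None,
                         proportions: list[dict[str, float]] | None = None,
                         image_size: int = 64, seed: int = 0) -> list[LabelMask]:
    """Label masks whose per-label pixel counts match requested fractions.

    ``proportions`` gives one dict per image mapping label -> pixel
    fraction; fractions must be nonnegative and sum to at most 1 (remainder
    unlabelled). Labels are painted as contiguous raster bands, so counts
    match the request to within one pixel row.
    """
    if vocabulary is None:
        vocabulary = default_vocabulary()
    if proportions is None:
        rng = np.random.default_rng(seed)
        proportions = []
        for _ in range(n_images):
            chosen = rng.choice(len(vocabulary), size=3, replace=False)
            fracs = rng.dirichlet(np.ones(3)) * 0.9
            proportions.append({vocabulary[i]: float(f) for i, f in zip(chosen, fracs)})
    if len(proportions) != n_images:
        raise ValueError("need one proportions dict per image")
    index = {label: i for i, label in enumerate(vocabulary)}
    masks = []
    total = image_size * image_size
    for prop in proportions:
        if any(f < 0 for f in prop.values()):
            raise ValueError("fractions must be nonnegative")
        if sum(prop.values()) > 1.0 + 1e-9:
            raise ValueError("fractions sum to more than 1")
        flat = np.full(total, UNLABELLED, dtype=int)
        start = 0
        for label, frac in prop.items():
            if label not in index:
                raise KeyError(f"label {label!r} not in vocabulary")
            count = int(round(frac * total))
            flat[start:start + count] = index[label]
            start += count
        masks.append(LabelMask(flat.reshape(image_size, image_size),
                               vocabulary=tuple(vocabulary)))
    return masks
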