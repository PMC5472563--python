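"""Local semantic concept model.

Each image's segmentation mask is summarised as a 22-value vector of pixel
proportions over a fixed object-label vocabulary, normalised to unit
magnitude; cluster-level semantic similarity is the leave-one-image-out
cross-validated correlation of these vectors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .core import SimilarityMatrix
from .stimulus_selection import loio_similarity_matrix

#: Sentinel index for unlabelled pixels in a LabelMask grid.
UNLABELLED = -1

# 16 core scene labels plus the 6 additions needed to cover indoor/manmade
# content, in canonical order.
_VOCABULARY = (
    "sky", "water", "foliage", "mountain", "snow", "rock", "sand", "animal",
    "hill", "fog", "cloud", "grass", "dirt", "manmade object", "canyon", "road",
    "manmade structure", "people", "footpath/paved area", "room interior",
    "foodstuff", "vehicle",
)


@dataclass
class LabelMask:
    """Per-pixel object labels: vocabulary indices, UNLABELLED elsewhere."""

    labels: np.ndarray
    vocabulary: tuple[str, ...] = _VOCABULARY

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2 or self.labels.size == 0:
            raise ValueError("label mask must be a nonempty 2D grid")
        bad = (self.labels != UNLABELLED) & (
            (self.labels < 0) | (self.labels >= len(self.vocabulary)))
        if np.any(bad):
            raise ValueError("label indices outside vocabulary range")


@dataclass
class SemanticVector:
    values: np.ndarray
    all_zero: bool = False


def default_vocabulary() -> list[str]:
    """The 22-term object-label vocabulary, in canonical order."""
    return list(_VOCABULARY)


def semantic_vector(mask: LabelMask) -> SemanticVector:
    """Pixel-proportion vector over the vocabulary, scaled to unit magnitude.

    Proportions are taken over all pixels, so unlabelled pixels dilute every
    label but contribute to none. A fully unlabelled mask yields an all-zero
    vector with a flag.
    """
    n_labels = len(mask.vocabulary)
    total = mask.labels.size
    counts = np.bincount(
        mask.labels[mask.labels != UNLABELLED].ravel(), minlength=n_labels
    ).astype(float)
    proportions = counts / total
    norm = np.linalg.norm(proportions)
    if norm == 0:
        warnings.warn("fully unlabelled mask; semantic vector is all-zero")
        return SemanticVector(proportions, all_zero=True)
    return SemanticVector(proportions / norm)


def semantic_matrix(masks: list[LabelMask]) -> np.ndarray:
    """Stack semantic vectors of many masks into (n_images, 22)."""
    return np.vstack([semantic_vector(m).values for m in masks])


def semantic_similarity_matrix(vectors: np.ndarray,
                               cluster_labels: np.ndarray) -> SimilarityMatrix:
    """Cluster-level LOIO correlation similarity of semantic vectors."""
    return loio_similarity_matrix(vectors, cluster_labels)
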