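"""Perceptual similarity from a card-sorting task.

Participants each sort a counterbalanced 60-card subset of the stimulus set
(6 cards per scene cluster) into 10 free-form stacks. For each participant
a clusters x stacks count table is built; the perceptual similarity between
two clusters is the dot product of their count vectors (co-occurrence
frequency across stacks), averaged across participants.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .core import KIND_DOT, SimilarityMatrix
from .stimulus_selection import StimulusSet


@dataclass
class CardSortCounts:
    """clusters x stacks count table for one participant's sort."""

    counts: np.ndarray
    subject_id: int | str = 0

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2D clusters x stacks table")
        if np.any(self.counts < 0) or not np.issubdtype(self.counts.dtype, np.integer):
            raise ValueError("counts must be nonnegative integers")


def make_card_subsets(stimulus_set: StimulusSet, n_subjects: int,
                      per_cluster: int = 6, seed: int = 0) -> list[dict[int, np.ndarray]]:
    """Counterbalanced per-subject card subsets.

    Each subject receives ``per_cluster`` cards from every cluster. Within a
    cluster the (seed-shuffled) member list is consumed in a rotating window,
    so across subjects every image's usage count differs by at most one.
    """
    rng = np.random.default_rng(seed)
    orders = {}
    for c, ids in stimulus_set.cluster_images.items():
        if per_cluster > len(ids):
            raise ValueError(f"per_cluster={per_cluster} exceeds cluster {c} size {len(ids)}")
        orders[c] = rng.permutation(ids)
    subsets = []
    for s in range(n_subjects):
        subset = {}
        for c, order in orders.items():
            idx = (s * per_cluster + np.arange(per_cluster)) % len(order)
            subset[c] = order[idx]
        subsets.append(subset)
    return subsets


def counts_matrix(sort: Mapping, cluster_of: Mapping, n_stacks: int,
                  n_clusters: int | None = None,
                  subject_id: int | str = 0) -> CardSortCounts:
    """Count cards of each cluster in each stack.

    ``sort`` maps card id -> stack index; ``cluster_of`` maps card id ->
    cluster index. Unknown card ids are rejected.
    """
    if n_clusters is None:
        n_clusters = int(max(cluster_of.values())) + 1
    counts = np.zeros((n_clusters, n_stacks), dtype=int)
    for card, stack in sort.items():
        if card not in cluster_of:
            raise KeyError(f"card {card!r} has no cluster assignment")
        if not 0 <= stack < n_stacks:
            raise ValueError(f"stack index {stack} out of range")
        counts[cluster_of[card], stack] += 1
    return CardSortCounts(counts, subject_id=subject_id)


def dot_similarity(counts: CardSortCounts) -> SimilarityMatrix:
    """Pairwise dot products of cluster count vectors (counts^2 scale)."""
    c = counts.counts.astype(float)
    return SimilarityMatrix(c @ c.T, kind=KIND_DOT)


def group_average_dot(sorts: list[SimilarityMatrix]) -> SimilarityMatrix:
    """Element-wise mean of per-subject dot-product similarity matrices."""
    if not sorts:
        raise ValueError("need at least one subject")
    shapes = {s.entries.shape for s in sorts}
    if len(shapes) != 1:
        raise ValueError(f"shape mismatch across subjects: {shapes}")
    stack = np.stack([s.entries for s in sorts])
    return SimilarityMatrix(stack.mean(axis=0), kind=KIND_DOT, fold_stack=stack)
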