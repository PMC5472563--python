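"""Shared containers used across the pipeline.

The 10x10 cluster-level similarity matrix is the universal currency of the
analysis: GIST feature similarity, MVPA pattern similarity, semantic-vector
similarity and card-sort co-occurrence all arrive in this shape before being
compared by representational similarity analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Tag for Pearson-correlation similarity matrices (Fisher-z transformable).
KIND_CORRELATION = "correlation"
#: Tag for card-sort dot-product co-occurrence matrices (counts^2 scale).
KIND_DOT = "dot"


@dataclass
class SimilarityMatrix:
    """A k x k cluster-level similarity matrix.

    Parameters
    ----------
    entries:
        Square array of similarities. Correlation-kind entries lie in
        [-1, 1]; dot-kind entries are nonnegative co-occurrence counts.
    kind:
        Either ``"correlation"`` or ``"dot"``. Downstream statistics apply a
        Fisher z-transform to correlation matrices only.
    fold_stack:
        Optional (n_folds, k, k) stack of per-iteration matrices from which
        ``entries`` was averaged (cross-validation iterations or subjects).
    """

    entries: np.ndarray
    kind: str = KIND_CORRELATION
    fold_stack: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.entries = np.asarray(self.entries, dtype=float)
        if self.entries.ndim != 2 or self.entries.shape[0] != self.entries.shape[1]:
            raise ValueError(f"similarity matrix must be square, got {self.entries.shape}")
        if self.kind not in (KIND_CORRELATION, KIND_DOT):
            raise ValueError(f"unknown similarity kind {self.kind!r}")

    @property
    def n_clusters(self) -> int:
        return self.entries.shape[0]

    def symmetrized(self) -> "SimilarityMatrix":
        """Return a copy with entries replaced by (M + M.T) / 2."""
        sym = 0.5 * (self.entries + self.entries.T)
        return SimilarityMatrix(sym, kind=self.kind, fold_stack=self.fold_stack)

    def is_symmetric(self, tol: float = 1e-8) -> bool:
        return bool(np.max(np.abs(self.entries - self.entries.T)) <= tol)


@dataclass
class RSAResult:
    """Outcome of one representational similarity analysis.

    ``df`` follows the parametric convention n - 2 - n_covariates, so a
    simple RSA between two 10x10 matrices (45 off-diagonal elements) has
    df = 43 and a single-covariate partial correlation df = 42.
    """

    r: float
    df: int
    p: float
    kind: str = "simple"
    covariates: list[str] = field(default_factory=list)
    undefined: bool = False

    def __post_init__(self) -> None:
        if not self.undefined:
            if not -1.0 - 1e-12 <= self.r <= 1.0 + 1e-12:
                raise ValueError(f"correlation out of range: {self.r}")
            if not 0.0 <= self.p <= 1.0:
                raise ValueError(f"p-value out of range: {self.p}")


def check_unit_diagonal_symmetric(m: np.ndarray, tol: float = 1e-8) -> None:
    """Validate a model similarity matrix: square, symmetric, unit diagonal."""
    m = np.asarray(m, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError(f"expected a square matrix, got shape {m.shape}")
    if np.max(np.abs(m - m.T)) > tol:
        raise ValueError("model matrix must be symmetric")
    if np.max(np.abs(np.diag(m) - 1.0)) > tol:
        raise ValueError("model matrix must have a unit diagonal")
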