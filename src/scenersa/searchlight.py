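"""Whole-volume searchlight mapping.

A spherical neighbourhood (10 mm radius by default) is iterated over every
in-mask voxel; within each sphere the LOPO correlation MVPA is repeated and
either the within/between-cluster discrimination t-test or an RSA against a
model vector is run, with the test's p-value assigned to the sphere's
central voxel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .neural_patterns import BetaMaps, lopo_rdms, within_between_discrimination
from .rsa_stats import RdmVector, fisher_z, offdiag_vector, rsa_correlation

#: p-value written at centers that were not evaluated.
SENTINEL = 1.0


@dataclass
class SphereSpec:
    radius_mm: float = 10.0
    min_voxels: int = 10
    mask: np.ndarray | None = None     # analysis-volume membership grid
    step: int = 1                      # stride between evaluated centers

    def __post_init__(self) -> None:
        if self.radius_mm <= 0:
            raise ValueError("radius must be positive")
        if self.min_voxels < 2:
            raise ValueError("min_voxels must be >= 2")


@dataclass
class PMap:
    volume: np.ndarray
    affine: np.ndarray
    test_kind: str
    evaluated: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=bool))


def sphere_offsets(affine: np.ndarray, radius_mm: float) -> np.ndarray:
    """Integer voxel offsets whose center-to-center mm distance <= radius.

    Distances go through the affine's linear part, so anisotropic grids are
    handled correctly.
    """
    linear = np.asarray(affine, dtype=float)[:3, :3]
    # bounding box in voxel steps along each axis
    step_mm = np.linalg.norm(linear, axis=0)
    bounds = np.ceil(radius_mm / step_mm).astype(int)
    ranges = [np.arange(-b, b + 1) for b in bounds]
    grid = np.stack(np.meshgrid(*ranges, indexing="ij"), axis=-1).reshape(-1, 3)
    mm = grid @ linear.T
    keep = np.einsum("ij,ij->i", mm, mm) <= radius_mm ** 2 + 1e-9
    return grid[keep]


def sphere_indices(vol_shape: tuple[int, int, int], affine: np.ndarray,
                   center_voxel: tuple[int, int, int], radius_mm: float,
                   mask: np.ndarray | None = None
                   ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """In-grid (and in-mask) voxel indices within ``radius_mm`` of a center."""
    center = np.asarray(center_voxel, dtype=int)
    if np.any(center < 0) or np.any(center >= np.asarray(vol_shape)):
        raise ValueError(f"center {center_voxel} outside grid {vol_shape}")
    pts = center + sphere_offsets(affine, radius_mm)
    inside = np.all((pts >= 0) & (pts < np.asarray(vol_shape)), axis=1)
    pts = pts[inside]
    if mask is not None:
        pts = pts[mask[pts[:, 0], pts[:, 1], pts[:, 2]]]
    return pts[:, 0], pts[:, 1], pts[:, 2]


def run_searchlight(betas: list[BetaMaps], spec: SphereSpec,
                    test: str = "discrimination",
                    model: RdmVector | np.ndarray | None = None) -> PMap:
    """Map a per-sphere test p-value over the analysis volume.

    ``test`` is ``"discrimination"`` (within/between paired t across LOPO
    folds) or ``"rsa"`` (Pearson correlation of the fold-averaged,
    symmetrised, Fisher-z off-diagonals against ``model``). Centers with
    fewer than ``spec.min_voxels`` sphere members keep the sentinel value.
    """
    shapes = {b.data.shape for b in betas}
    if len(shapes) != 1:
        raise ValueError(f"subjects disagree on beta-map shape: {shapes}")
    vol_shape = betas[0].vol_shape
    affine = betas[0].affine
    if test == "rsa":
        if model is None:
            raise ValueError("rsa searchlight requires a model vector")
        model_values = model.values if isinstance(model, RdmVector) else np.asarray(model)
        k = betas[0].n_conditions
        if model_values.size != k * (k - 1) // 2:
            raise ValueError(
                f"model vector length {model_values.size} != k(k-1)/2 = {k * (k - 1) // 2}")
    elif test != "discrimination":
        raise ValueError(f"unknown test {test!r}")
    mask = spec.mask if spec.mask is not None else np.ones(vol_shape, dtype=bool)
    offsets = sphere_offsets(affine, spec.radius_mm)
    data = np.stack([b.data for b in betas])   # (subjects, k, x, y, z)
    volume = np.full(vol_shape, SENTINEL)
    evaluated = np.zeros(vol_shape, dtype=bool)
    centers = np.argwhere(mask)
    if spec.step > 1:
        keep = np.all(centers % spec.step == 0, axis=1)
        centers = centers[keep]
    shape_arr = np.asarray(vol_shape)
    for center in centers:
        pts = center + offsets
        inside = np.all((pts >= 0) & (pts < shape_arr), axis=1)
        pts = pts[inside]
        pts = pts[mask[pts[:, 0], pts[:, 1], pts[:, 2]]]
        if pts.shape[0] < spec.min_voxels:
            continue
        patterns = list(data[:, :, pts[:, 0], pts[:, 1], pts[:, 2]])
        folds = lopo_rdms(betas, patterns=patterns)
        if test == "discrimination":
            p = within_between_discrimination(folds).p
        else:
            vec = fisher_z(offdiag_vector(folds.mean_symmetric()).values)
            p = rsa_correlation(vec, model_values).p
        cx, cy, cz = center
        volume[cx, cy, cz] = p if np.isfinite(p) else SENTINEL
        evaluated[cx, cy, cz] = True
    kind = "discrimination" if test == "discrimination" else "rsa"
    return PMap(volume, affine, test_kind=kind, evaluated=evaluated)
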