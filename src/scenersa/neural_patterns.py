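"""From beta maps to fold-wise MVPA similarity matrices.

Implements the blocked fMRI design and GLM utilities, flood-fill ROI
definition on a statistic map, leave-one-participant-out (LOPO) correlation
MVPA with voxel-wise mean normalisation, within/between-cluster
discrimination tests, univariate amplitudes, and noise ceilings.

The group pattern per fold is the arithmetic mean of the remaining subjects'
beta patterns — the fixed-effects limit of a group model — which preserves
the LOPO logic without a mixed-effects machinery.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats

from .rsa_stats import PairedTResult, offdiag_vector, paired_ttest

#: Single-gamma HRF parameterisation: mode 6 s, SD 3 s.
_HRF_SHAPE = 3.0 + 2.0 * np.sqrt(2.0)
_HRF_SCALE = 6.0 / (_HRF_SHAPE - 1.0)


@dataclass
class DesignMatrix:
    """HRF-convolved task regressors sampled at the TR."""

    matrix: np.ndarray                 # (n_timepoints, n_task + n_confound)
    n_task: int
    tr: float
    condition_order: np.ndarray        # condition index of each block, in time order
    frame_times: np.ndarray
    block_onsets: np.ndarray           # seconds

    @property
    def task_matrix(self) -> np.ndarray:
        return self.matrix[:, :self.n_task]

    @property
    def n_timepoints(self) -> int:
        return self.matrix.shape[0]


@dataclass
class BetaMaps:
    """Per-subject condition x volume parameter estimates."""

    data: np.ndarray                   # (n_conditions, nx, ny, nz)
    affine: np.ndarray
    condition_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ValueError("BetaMaps data must be (n_conditions, nx, ny, nz)")
        if not self.condition_names:
            self.condition_names = [f"cluster{i}" for i in range(self.data.shape[0])]

    @property
    def n_conditions(self) -> int:
        return self.data.shape[0]

    @property
    def vol_shape(self) -> tuple[int, int, int]:
        return self.data.shape[1:]

    def extract(self, roi: "RoiMask") -> np.ndarray:
        """ROI patterns as (n_conditions, n_voxels)."""
        i, j, k = roi.indices
        return self.data[:, i, j, k]


@dataclass
class RoiMask:
    """Contiguous voxel set grown around a seed on a statistic map."""

    indices: tuple[np.ndarray, np.ndarray, np.ndarray]
    vol_shape: tuple[int, int, int]
    affine: np.ndarray
    achieved_size: int
    threshold_used: float

    def as_volume(self) -> np.ndarray:
        vol = np.zeros(self.vol_shape, dtype=bool)
        vol[self.indices] = True
        return vol


@dataclass
class FoldRdms:
    """Per-fold group x left-out condition correlation matrices."""

    stack: np.ndarray                  # (n_folds, k, k)

    def __post_init__(self) -> None:
        self.stack = np.asarray(self.stack, dtype=float)
        if self.stack.ndim != 3 or self.stack.shape[1] != self.stack.shape[2]:
            raise ValueError("fold stack must be (n_folds, k, k)")

    @property
    def n_folds(self) -> int:
        return self.stack.shape[0]

    @property
    def k(self) -> int:
        return self.stack.shape[1]

    def mean_symmetric(self) -> np.ndarray:
        """Fold-averaged matrix, symmetrised by (M + M.T)/2 for RSA."""
        m = self.stack.mean(axis=0)
        return 0.5 * (m + m.T)


@dataclass
class NoiseCeiling:
    lower: float
    upper: float


def hrf(t: np.ndarray) -> np.ndarray:
    """Single-gamma hemodynamic response (mode 6 s, SD 3 s), peak-normalised."""
    t = np.asarray(t, dtype=float)
    h = stats.gamma.pdf(t, a=_HRF_SHAPE, scale=_HRF_SCALE)
    peak = stats.gamma.pdf((_HRF_SHAPE - 1.0) * _HRF_SCALE, a=_HRF_SHAPE, scale=_HRF_SCALE)
    return h / peak


def build_design(n_conditions: int = 10, reps: int = 4, images_per_block: int = 6,
                 image_on: float = 0.75, image_off: float = 0.25, rest: float = 9.0,
                 tr: float = 3.0, order_seed: int = 0,
                 confounds: np.ndarray | None = None) -> DesignMatrix:
    """Blocked design: condition blocks in seeded pseudo-random order.

    Each block shows ``images_per_block`` images of one condition
    (``image_on`` s on, ``image_off`` s off => 6 s blocks under defaults);
    blocks are separated by ``rest`` s of fixation, with an initial rest
    period. Boxcars are convolved with the single-gamma HRF at 50 ms
    resolution and sampled at the TR.
    """
    if min(reps, n_conditions, images_per_block) < 1:
        raise ValueError("n_conditions, reps and images_per_block must be >= 1")
    if min(image_on, image_off, rest, tr) <= 0:
        raise ValueError("durations must be positive")
    rng = np.random.default_rng(order_seed)
    order = rng.permutation(np.repeat(np.arange(n_conditions), reps))
    block_len = images_per_block * (image_on + image_off)
    onsets = rest + np.arange(order.size) * (block_len + rest)
    total = onsets[-1] + block_len + rest
    dt = 0.05
    n_hi = int(np.ceil(total / dt))
    t_hi = np.arange(n_hi) * dt
    boxcars = np.zeros((n_hi, n_conditions))
    for onset, cond in zip(onsets, order):
        boxcars[(t_hi >= onset) & (t_hi < onset + block_len), cond] = 1.0
    kernel = hrf(np.arange(0, 32.0, dt))
    convolved = np.empty_like(boxcars)
    for c in range(n_conditions):
        convolved[:, c] = np.convolve(boxcars[:, c], kernel)[:n_hi] * dt
    n_tr = int(np.floor(total / tr))
    frame_times = np.arange(n_tr) * tr
    sample_idx = np.clip((frame_times / dt).astype(int), 0, n_hi - 1)
    task = convolved[sample_idx]
    if confounds is not None:
        confounds = np.asarray(confounds, dtype=float)
        if confounds.shape[0] != n_tr:
            raise ValueError(f"confounds have {confounds.shape[0]} rows, design has {n_tr}")
        matrix = np.column_stack([task, confounds])
    else:
        matrix = task
    return DesignMatrix(matrix, n_task=n_conditions, tr=tr, condition_order=order,
                        frame_times=frame_times, block_onsets=onsets)


def fit_glm(series: np.ndarray, design: DesignMatrix,
            affine: np.ndarray | None = None) -> BetaMaps:
    """Voxel-wise OLS; returns the task-column betas only.

    ``series`` may be 4D (nx, ny, nz, t) or 2D (t, n_voxels); the 2D form
    returns a BetaMaps on a flat (n_voxels, 1, 1) grid. A rank-deficient
    design is rejected, naming the collinear columns.
    """
    x = design.matrix
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        _, r = np.linalg.qr(x)
        bad = np.flatnonzero(np.abs(np.diag(r)) < 1e-10 * np.abs(np.diag(r)).max())
        raise ValueError(f"design matrix is rank-deficient; collinear columns: {bad.tolist()}")
    if series.ndim == 4:
        vol_shape = series.shape[:3]
        y = series.reshape(-1, series.shape[3]).T
    elif series.ndim == 2:
        vol_shape = (series.shape[1], 1, 1)
        y = series
    else:
        raise ValueError("series must be 4D (x,y,z,t) or 2D (t, voxels)")
    if y.shape[0] != x.shape[0]:
        raise ValueError(f"series has {y.shape[0]} timepoints, design has {x.shape[0]} rows")
    betas, *_ = np.linalg.lstsq(x, y, rcond=None)
    task_betas = betas[:design.n_task]
    data = task_betas.reshape(design.n_task, *vol_shape)
    if affine is None:
        affine = np.eye(4)
    return BetaMaps(data, affine=affine)


def define_roi_floodfill(statmap: np.ndarray, seed_voxel: tuple[int, int, int],
                         affine: np.ndarray | None = None, target_size: int = 500,
                         tolerance: int = 2, max_iter: int = 60) -> RoiMask:
    """Grow a contiguous ROI of approximately ``target_size`` voxels.

    Bisects a statistic threshold between the map minimum and the seed's
    value; at each step the 6-connected component of the supra-threshold
    mask containing the seed is measured, and the best size so far is kept.
    The threshold never exceeds the seed value, so the seed is always a
    member.
    """
    statmap = np.asarray(statmap, dtype=float)
    seed_val = statmap[seed_voxel]
    if not np.isfinite(seed_val) or seed_val <= statmap.min():
        raise ValueError("seed voxel must be finite and above the global minimum")
    if affine is None:
        affine = np.eye(4)
    structure = ndimage.generate_binary_structure(3, 1)  # 6-connectivity
    lo, hi = float(statmap.min()), float(seed_val)
    best: tuple[int, float, np.ndarray] | None = None
    for _ in range(max_iter):
        thr = 0.5 * (lo + hi)
        labels, _ = ndimage.label(statmap >= thr, structure=structure)
        comp = labels == labels[seed_voxel]
        size = int(comp.sum())
        if best is None or abs(size - target_size) < abs(best[0] - target_size):
            best = (size, thr, comp)
        if abs(size - target_size) <= tolerance:
            break
        if size > target_size:
            lo = thr
        else:
            hi = thr
    assert best is not None
    size, thr, comp = best
    idx = np.nonzero(comp)
    return RoiMask(indices=idx, vol_shape=statmap.shape, affine=affine,
                   achieved_size=size, threshold_used=thr)


def _demean_voxelwise(patterns: np.ndarray) -> np.ndarray:
    """Subtract each voxel's mean across conditions."""
    return patterns - patterns.mean(axis=0, keepdims=True)


def _cross_correlate(group: np.ndarray, left_out: np.ndarray) -> np.ndarray:
    """Row-wise Pearson correlations: out[a, b] = r(group[a], left_out[b])."""
    g = group - group.mean(axis=1, keepdims=True)
    l = left_out - left_out.mean(axis=1, keepdims=True)
    gn = np.linalg.norm(g, axis=1)
    ln = np.linalg.norm(l, axis=1)
    if np.any(gn == 0) or np.any(ln == 0):
        warnings.warn("zero-variance pattern; affected correlations set to 0")
    gn = np.where(gn == 0, 1.0, gn)
    ln = np.where(ln == 0, 1.0, ln)
    return np.clip((g / gn[:, None]) @ (l / ln[:, None]).T, -1.0, 1.0)


def lopo_rdms(betas: list[BetaMaps], roi: RoiMask | None = None,
              patterns: list[np.ndarray] | None = None) -> FoldRdms:
    """Leave-one-participant-out correlation MVPA.

    Per fold, the group pattern is the mean of the other subjects' ROI
    betas; both group and left-out patterns are normalised by subtracting
    the voxel-wise mean across conditions, then every group condition
    pattern is correlated with every left-out condition pattern
    (rows = group, cols = left-out).

    Either ``roi`` (applied to each BetaMaps) or precomputed ``patterns``
    (list of (k, n_voxels) arrays) may be given.
    """
    if patterns is None:
        if roi is None:
            raise ValueError("either roi or patterns must be provided")
        patterns = [b.extract(roi) for b in betas]
    n_subjects = len(patterns)
    if n_subjects < 3:
        raise ValueError("LOPO needs at least 3 subjects")
    shapes = {p.shape for p in patterns}
    if len(shapes) != 1:
        raise ValueError(f"subjects disagree on (conditions, voxels): {shapes}")
    arr = np.stack([np.asarray(p, dtype=float) for p in patterns])
    total = arr.sum(axis=0)
    k = arr.shape[1]
    folds = np.empty((n_subjects, k, k))
    for f in range(n_subjects):
        group = _demean_voxelwise((total - arr[f]) / (n_subjects - 1))
        left = _demean_voxelwise(arr[f])
        folds[f] = _cross_correlate(group, left)
    return FoldRdms(folds)


def within_between_discrimination(folds: FoldRdms) -> PairedTResult:
    """Paired t-test of within-cluster vs between-cluster correlations.

    Per fold, the Fisher-z matrix's mean diagonal (within) is compared with
    its mean off-diagonal (between); the paired test runs across folds, so
    20 folds give df = 19.
    """
    if folds.n_folds < 2:
        raise ValueError("need at least 2 folds")
    k = folds.k
    z = np.arctanh(np.clip(folds.stack, -(1 - 1e-7), 1 - 1e-7))
    eye = np.eye(k, dtype=bool)
    within = z[:, eye].mean(axis=1)
    between = z[:, ~eye].mean(axis=1)
    return paired_ttest(within, between)


@dataclass
class UnivariateResult:
    condition_means: np.ndarray        # across-subject mean of ROI-mean betas
    t: np.ndarray
    df: int
    p: np.ndarray
    undefined: np.ndarray              # per-condition flag for zero-variance cases


def univariate_amplitude(betas: list[BetaMaps], roi: RoiMask) -> UnivariateResult:
    """Per-condition mean ROI amplitude with a one-sample t across subjects."""
    if len(betas) < 2:
        raise ValueError("need at least 2 subjects")
    amp = np.stack([b.extract(roi).mean(axis=1) for b in betas])  # (subjects, k)
    n = amp.shape[0]
    means = amp.mean(axis=0)
    sd = amp.std(axis=0, ddof=1)
    undefined = sd == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        t = np.where(undefined, np.nan, means / (sd / np.sqrt(n)))
        p = np.where(undefined, np.nan, 2.0 * stats.t.sf(np.abs(t), n - 1))
    if np.any(undefined):
        warnings.warn("zero across-subject variance for some conditions; t undefined")
    return UnivariateResult(means, t, n - 1, p, undefined)


def noise_ceiling(folds: FoldRdms) -> NoiseCeiling:
    """Upper/lower bounds on achievable model-RDM correlation.

    Each fold's symmetrised matrix is vectorised (off-diagonals) and
    Fisher-z transformed. The upper bound correlates each fold with the
    mean of all folds (the fold participates in its own target, an
    optimistic estimate); the lower bound correlates each fold with the
    mean of the remaining folds.
    """
    if folds.n_folds < 3:
        raise ValueError("need at least 3 folds")
    vecs = []
    for f in range(folds.n_folds):
        m = 0.5 * (folds.stack[f] + folds.stack[f].T)
        vecs.append(np.arctanh(np.clip(offdiag_vector(m).values, -(1 - 1e-7), 1 - 1e-7)))
    z = np.stack(vecs)
    if np.any(z.std(axis=1) == 0):
        warnings.warn("constant fold vector; noise ceiling degenerate")
    grand = z.mean(axis=0)
    n = z.shape[0]
    upper = np.mean([np.corrcoef(z[f], grand)[0, 1] for f in range(n)])
    lower = np.mean([
        np.corrcoef(z[f], (grand * n - z[f]) / (n - 1))[0, 1] for f in range(n)
    ])
    return NoiseCeiling(lower=float(lower), upper=float(upper))


def smooth_volume(volume: np.ndarray, fwhm_mm: float, voxel_size_mm: float = 2.0) -> np.ndarray:
    """Optional Gaussian spatial smoothing of a 3D volume (off by default upstream)."""
    sigma = fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0))) / voxel_size_mm
    return ndimage.gaussian_filter(np.asarray(volume, dtype=float), sigma)
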