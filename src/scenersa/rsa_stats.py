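"""Representational similarity statistics.

Fisher z-transform for correlation matrices, off-diagonal vectorisation,
Pearson RSA with parametric p-values (df = n - 2), partial and semi-partial
correlations via OLS residualisation, Holm-Bonferroni step-down adjustment,
and paired t-tests. For 10x10 matrices the 45 unique off-diagonals give the
familiar df = 43 for a simple RSA and df = 42 with one covariate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core import KIND_CORRELATION, RSAResult, SimilarityMatrix

_CLIP = 1.0 - 1e-7


def fisher_z(m: SimilarityMatrix | np.ndarray) -> np.ndarray:
    """Element-wise Fisher z (atanh) of a correlation-kind matrix.

    Entries at exactly +/-1 (e.g. a matrix diagonal) are clipped to
    +/-(1 - 1e-7) with a warning. Dot-product matrices are rejected: they
    are not correlations and are analysed on their raw scale.
    """
    if isinstance(m, SimilarityMatrix):
        if m.kind != KIND_CORRELATION:
            raise ValueError(f"Fisher z applies to correlation matrices, not kind={m.kind!r}")
        values = m.entries
    else:
        values = np.asarray(m, dtype=float)
    if np.any(np.abs(values) > 1.0 + 1e-12):
        raise ValueError("correlation entries must lie in [-1, 1]")
    if np.any(np.abs(values) >= 1.0):
        warnings.warn("entries at +/-1 clipped before atanh")
    return np.arctanh(np.clip(values, -_CLIP, _CLIP))


@dataclass
class RdmVector:
    """The k(k-1)/2 unique off-diagonals of a symmetric matrix."""

    values: np.ndarray
    source: str = ""


def offdiag_vector(m: np.ndarray | SimilarityMatrix, source: str = "",
                   tol: float = 1e-6) -> RdmVector:
    """Lower-triangle (row > col) off-diagonals in row-major order."""
    values = m.entries if isinstance(m, SimilarityMatrix) else np.asarray(m, dtype=float)
    if values.ndim != 2 or values.shape[0] != values.shape[1]:
        raise ValueError(f"expected a square matrix, got {values.shape}")
    asym = np.max(np.abs(values - values.T)) if values.size else 0.0
    if asym > tol:
        warnings.warn(f"matrix asymmetric by {asym:.3g}; symmetrising")
        values = 0.5 * (values + values.T)
    rows, cols = np.tril_indices(values.shape[0], k=-1)
    order = np.lexsort((cols, rows))  # row-major over the lower triangle
    return RdmVector(values[rows[order], cols[order]], source=source)


def _as_values(x) -> np.ndarray:
    v = x.values if isinstance(x, RdmVector) else np.asarray(x, dtype=float)
    return v.ravel()


def _r_to_p(r: float, df: int) -> float:
    if df <= 0:
        return float("nan")
    r = float(np.clip(r, -1.0, 1.0))
    if abs(r) >= 1.0:
        return 0.0
    t = r * np.sqrt(df / (1.0 - r * r))
    return float(2.0 * stats.t.sf(abs(t), df))


def rsa_correlation(x, y) -> RSAResult:
    """Simple Pearson RSA with two-tailed parametric p (df = n - 2)."""
    xv, yv = _as_values(x), _as_values(y)
    if xv.shape != yv.shape:
        raise ValueError("vectors must have equal length")
    n = xv.size
    if n < 3:
        raise ValueError("need at least 3 elements")
    if np.std(xv) == 0 or np.std(yv) == 0:
        warnings.warn("zero-variance vector; RSA undefined")
        return RSAResult(r=np.nan, df=n - 2, p=np.nan, undefined=True)
    r = float(np.corrcoef(xv, yv)[0, 1])
    return RSAResult(r=r, df=n - 2, p=_r_to_p(r, n - 2))


def _residualise(v: np.ndarray, design: np.ndarray) -> np.ndarray:
    beta, *_ = np.linalg.lstsq(design, v, rcond=None)
    return v - design @ beta


def partial_correlation(x, y, covariates: list) -> RSAResult:
    """Partial correlation: both x and y residualised on the covariates.

    df = n - 2 - n_covariates. Collinear (or constant) covariates are
    rejected rather than silently absorbed by the intercept.
    """
    xv, yv = _as_values(x), _as_values(y)
    covs = [_as_values(c) for c in covariates]
    if not covs:
        raise ValueError("partial correlation needs at least one covariate")
    n = xv.size
    if any(c.size != n for c in covs) or yv.size != n:
        raise ValueError("all vectors must have equal length")
    design = np.column_stack([np.ones(n)] + covs)
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("covariates are collinear (or constant)")
    rx = _residualise(xv, design)
    ry = _residualise(yv, design)
    df = n - 2 - len(covs)
    if np.std(rx) == 0 or np.std(ry) == 0:
        warnings.warn("zero-variance residual; partial correlation undefined")
        return RSAResult(r=np.nan, df=df, p=np.nan, kind="partial", undefined=True)
    r = float(np.corrcoef(rx, ry)[0, 1])
    names = [c.source if isinstance(c, RdmVector) and c.source else f"cov{i}"
             for i, c in enumerate(covariates)]
    return RSAResult(r=r, df=df, p=_r_to_p(r, df), kind="partial", covariates=names)


def semipartial_correlation(x, y, z) -> RSAResult:
    """Semi-partial correlation r_x(y.z): z removed from the predictor y only.

    Shared variance between the competing predictors y and z is held
    constant, but the outcome x is left unfiltered. df = n - 3.
    """
    xv, yv, zv = _as_values(x), _as_values(y), _as_values(z)
    n = xv.size
    if yv.size != n or zv.size != n:
        raise ValueError("all vectors must have equal length")
    design = np.column_stack([np.ones(n), zv])
    if np.linalg.matrix_rank(design) < 2:
        raise ValueError("competing predictor is constant")
    ry = _residualise(yv, design)
    df = n - 3
    if np.std(xv) == 0 or np.std(ry) == 0:
        warnings.warn("zero-variance vector; semi-partial correlation undefined")
        return RSAResult(r=np.nan, df=df, p=np.nan, kind="semipartial", undefined=True)
    r = float(np.corrcoef(xv, ry)[0, 1])
    return RSAResult(r=r, df=df, p=_r_to_p(r, df), kind="semipartial")


def holm_bonferroni(pvals) -> np.ndarray:
    """Holm-Bonferroni step-down adjusted p-values, in input order.

    Sorted ascending, adjusted_i = max_{j<=i} (m - j) * p_(j) (0-based j),
    capped at 1.
    """
    p = np.asarray(pvals, dtype=float).ravel()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    raw_sorted = p[order]
    factors = m - np.arange(m)
    stepped = np.maximum.accumulate(factors * raw_sorted)
    adjusted_sorted = np.minimum(stepped, 1.0)
    out = np.empty(m)
    out[order] = adjusted_sorted
    return out


@dataclass
class PairedTResult:
    t: float
    df: int
    p: float
    d: float
    undefined: bool = False


def paired_ttest(a, b) -> PairedTResult:
    """Paired-samples t-test with Cohen's d = mean(diff)/sd(diff)."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    n = a.size
    if n < 2:
        raise ValueError("need at least 2 pairs")
    diff = a - b
    sd = diff.std(ddof=1)
    if sd == 0:
        if np.allclose(diff, 0):
            # identical samples: conventionally t = 0, p = 1
            return PairedTResult(t=0.0, df=n - 1, p=1.0, d=0.0)
        warnings.warn("zero-variance nonzero differences; t undefined")
        return PairedTResult(t=np.nan, df=n - 1, p=np.nan, d=np.nan, undefined=True)
    t = diff.mean() / (sd / np.sqrt(n))
    p = float(2.0 * stats.t.sf(abs(t), n - 1))
    return PairedTResult(t=float(t), df=n - 1, p=p, d=float(diff.mean() / sd))
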