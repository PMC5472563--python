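"""GIST scene descriptor: oriented band-pass energy pooled over a spatial grid.

An image is represented by the energy of a bank of frequency-domain Gabor
filters (4 scales x 8 orientations by default) averaged within each cell of a
4x4 spatial grid, giving the canonical 512-value descriptor. The module also
provides the stimulus preprocessing used before descriptor computation:
grayscale conversion, center crop, resize to 256x256, and equalisation of
mean luminance and RMS contrast.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from numpy.fft import fft2, fftfreq, ifft2
from skimage.transform import resize as _sk_resize

# ITU-R BT.601 luma weights for grayscale conversion.
_BT601 = np.array([0.299, 0.587, 0.114])

# Radial bandwidth of the log-Gabor envelope (ratio sigma_f / f0).
_SIGMA_RADIAL = 0.65


@dataclass
class Image:
    """A square grayscale stimulus image with luminance in [0, 1]."""

    pixels: np.ndarray
    contrast_warning: bool = False  # set when contrast could not be equated
    clipped: bool = False  # set when equalisation pushed values outside [0, 1]

    @property
    def size(self) -> int:
        return self.pixels.shape[0]


@dataclass
class GaborFilterBank:
    """Frequency-domain Gabor transfer functions, scale-major order."""

    transfer_functions: np.ndarray  # (scales * orientations, size, size)
    scales: int
    orientations: int
    size: int

    @property
    def n_filters(self) -> int:
        return self.scales * self.orientations

    def center_frequency(self, scale: int) -> float:
        """Peak frequency of a scale in cycles/pixel (0.25 / 2**scale)."""
        return 0.25 / (2.0 ** scale)


def to_grayscale(raw: np.ndarray) -> np.ndarray:
    """Convert an array in any channel layout to 2D float luminance in [0, 1]."""
    raw = np.asarray(raw)
    if raw.size == 0:
        raise ValueError("empty input image")
    if np.issubdtype(raw.dtype, np.integer):
        raw = raw.astype(float) / 255.0
    else:
        raw = raw.astype(float)
    if raw.ndim == 3:
        if raw.shape[2] >= 3:
            raw = raw[..., :3] @ _BT601
        else:
            raw = raw[..., 0]
    elif raw.ndim != 2:
        raise ValueError(f"expected a 2D or 2D+channels image, got ndim={raw.ndim}")
    if not np.all(np.isfinite(raw)):
        raise ValueError("image contains non-finite values")
    return raw


def center_crop_square(img: np.ndarray) -> np.ndarray:
    """Crop a 2D image to its central square."""
    h, w = img.shape
    side = min(h, w)
    top = (h - side) // 2
    left = (w - side) // 2
    return img[top:top + side, left:left + side]


def preprocess_image(
    raw: np.ndarray,
    target_size: int = 256,
    target_mean: float = 0.5,
    target_rms: float = 0.14,
) -> Image:
    """Grayscale, center-crop, resize, and equate mean luminance / RMS contrast.

    RMS contrast is the standard deviation of luminance. After equalisation
    values are clipped to [0, 1]; if clipping fired the ``clipped`` flag is
    set (the mean/contrast match may then be perturbed). A zero-variance
    input with ``target_rms > 0`` is returned as a constant ``target_mean``
    image with ``contrast_warning`` set.
    """
    if target_rms < 0:
        raise ValueError("target_rms must be nonnegative")
    gray = center_crop_square(to_grayscale(raw))
    if gray.shape[0] != target_size:
        gray = _sk_resize(gray, (target_size, target_size), order=1,
                          mode="reflect", anti_aliasing=False, preserve_range=True)
    sd = float(gray.std())
    if sd < 1e-12:
        if target_rms > 0:
            return Image(np.full_like(gray, target_mean), contrast_warning=True)
        return Image(np.full_like(gray, target_mean))
    out = (gray - gray.mean()) / sd * target_rms + target_mean
    clipped = bool(out.min() < 0.0 or out.max() > 1.0)
    return Image(np.clip(out, 0.0, 1.0), clipped=clipped)


def _frequency_grid(size: int) -> tuple[np.ndarray, np.ndarray]:
    """Return (fx, fy) in cycles/pixel on the unshifted FFT grid."""
    f = fftfreq(size)
    fx, fy = np.meshgrid(f, f, indexing="xy")
    return fx, fy


def gabor_transfer(fx: np.ndarray, fy: np.ndarray, f0: float,
                   theta0: float, sigma_theta: float) -> np.ndarray:
    """Evaluate one log-Gabor transfer function at frequency coordinates.

    Radial term is a log-Gaussian centered on ``f0``; angular term is a
    Gaussian in orientation distance wrapped modulo pi (so the filter is
    symmetric under point reflection and its impulse response is real).
    The DC bin is exactly zero.
    """
    r = np.hypot(fx, fy)
    theta = np.arctan2(fy, fx)
    with np.errstate(divide="ignore"):
        radial = np.exp(-(np.log(np.where(r > 0, r, 1.0) / f0) ** 2)
                        / (2.0 * np.log(_SIGMA_RADIAL) ** 2))
    radial = np.where(r > 0, radial, 0.0)
    d = np.mod(theta - theta0 + np.pi / 2.0, np.pi) - np.pi / 2.0
    angular = np.exp(-(d ** 2) / (2.0 * sigma_theta ** 2))
    return radial * angular


def build_filterbank(size: int = 256, scales: int = 4, orientations: int = 8) -> GaborFilterBank:
    """Build the frequency-domain Gabor filterbank (scale-major ordering)."""
    if size < 2 or (size & (size - 1)) != 0:
        raise ValueError("size must be a power of two")
    if scales < 1 or orientations < 1:
        raise ValueError("scales and orientations must be >= 1")
    fx, fy = _frequency_grid(size)
    sigma_theta = 0.5 * np.pi / orientations
    filters = np.empty((scales * orientations, size, size))
    for s in range(scales):
        f0 = 0.25 / (2.0 ** s)
        for o in range(orientations):
            theta0 = o * np.pi / orientations
            filters[s * orientations + o] = gabor_transfer(fx, fy, f0, theta0, sigma_theta)
    return GaborFilterBank(filters, scales=scales, orientations=orientations, size=size)


def prefilter(pixels: np.ndarray, cycles_per_image: float = 4.0,
              epsilon: float = 0.2) -> np.ndarray:
    """Local luminance subtraction and divisive contrast normalisation.

    Subtracts a Gaussian low-pass estimate of local luminance (cutoff
    ``cycles_per_image``) and divides by a low-passed local contrast
    estimate, so descriptor energies reflect structure rather than local
    lighting. A constant image maps exactly to zero.
    """
    size = pixels.shape[0]
    fx, fy = _frequency_grid(size)
    r_img = np.hypot(fx, fy) * size  # cycles per image
    lowpass = np.exp(-(r_img / cycles_per_image) ** 2)
    f = fft2(pixels)
    local_mean = ifft2(f * lowpass).real
    out = pixels - local_mean
    local_energy = ifft2(fft2(out ** 2) * lowpass).real
    local_contrast = np.sqrt(np.clip(local_energy, 0.0, None))
    return out / (epsilon + local_contrast)


def _block_average(grid_img: np.ndarray, grid: int) -> np.ndarray:
    size = grid_img.shape[0]
    if size % grid != 0:
        raise ValueError(f"image size {size} not divisible by grid {grid}")
    cell = size // grid
    return grid_img.reshape(grid, cell, grid, cell).mean(axis=(1, 3)).ravel()


def compute_gist(img: Image | np.ndarray, bank: GaborFilterBank,
                 grid: int = 4, apply_prefilter: bool = True) -> np.ndarray:
    """Compute the GIST descriptor of a square image.

    Per filter, the magnitude of the complex filtered image is averaged
    within each ``grid x grid`` block; the descriptor is ordered
    (scale, orientation, grid_row, grid_col) and has length
    ``scales * orientations * grid**2`` (512 under defaults).
    """
    pixels = img.pixels if isinstance(img, Image) else np.asarray(img, dtype=float)
    if pixels.ndim != 2 or pixels.shape[0] != pixels.shape[1]:
        raise ValueError("compute_gist expects a square 2D image")
    if pixels.shape[0] != bank.size:
        raise ValueError(f"image size {pixels.shape[0]} != filterbank size {bank.size}")
    if apply_prefilter:
        pixels = prefilter(pixels)
    spectrum = fft2(pixels)
    out = np.empty(bank.n_filters * grid * grid)
    for i, tf in enumerate(bank.transfer_functions):
        energy = np.abs(ifft2(spectrum * tf))
        out[i * grid * grid:(i + 1) * grid * grid] = _block_average(energy, grid)
    return out


def gist_matrix(images: list[np.ndarray] | np.ndarray, bank: GaborFilterBank,
                grid: int = 4, apply_prefilter: bool = True) -> np.ndarray:
    """Stack descriptors of many images into an (n_images, n_features) matrix."""
    rows = [compute_gist(im, bank, grid=grid, apply_prefilter=apply_prefilter)
            for im in images]
    if not rows:
        warnings.warn("gist_matrix called with no images")
        return np.empty((0, bank.n_filters * grid * grid))
    return np.vstack(rows)
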