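"""Spatial-envelope (GIST) scene descriptor.

The descriptor characterizes a scene by the power distribution across
orientations and spatial frequencies: the image is multiplied in the Fourier
domain by a bank of oriented band-pass (log-Gabor) filters — by default eight
orientations times six octave-spaced spatial frequencies, 48 filters — the
magnitude of each filtered image is averaged over a coarse spatial grid
(default 4x4), and the pooled values are concatenated into one feature vector
(default 48 x 16 = 768 entries).

Filters are single-lobed in the frequency half-plane; the inverse transform is
therefore a complex analytic response whose magnitude is the local band
energy.  Boundary handling is periodic (FFT-native).  Feature ordering is
scale-major, then orientation, then row-major grid blocks.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage.transform import resize

from .types import GistFeatures, SceneImage


@dataclass
class FilterBank:
    """Frequency-domain transfer functions of the oriented band-pass bank."""

    transfer_functions: np.ndarray          # (n_filters, size_px, size_px), >= 0
    n_orientations: int
    n_scales: int
    size_px: int
    bank_id: str = "log-gabor"

    @property
    def n_filters(self) -> int:
        return self.n_orientations * self.n_scales

    def __post_init__(self) -> None:
        if self.transfer_functions.shape != (self.n_filters, self.size_px, self.size_px):
            raise ValueError("transfer function stack has wrong shape")
        if np.any(self.transfer_functions[:, 0, 0] != 0):
            raise ValueError("filters must have zero DC response")


def preprocess_image(
    raw: np.ndarray,
    target_px: int = 256,
    normalize_contrast: bool = True,
    sigma: Optional[float] = None,
    eps: float = 0.01,
) -> SceneImage:
    """Grayscale conversion, resampling, and local contrast normalization.

    Local contrast normalization subtracts a Gaussian-blurred local mean and
    divides by the locally estimated standard deviation (same Gaussian kernel,
    default ``sigma = target_px / 16``), then rescales to [0, 1].  A constant
    input maps to uniform mid-gray.
    """
    raw = np.asarray(raw, dtype=float)
    if not np.all(np.isfinite(raw)):
        raise ValueError("input image contains non-finite values")
    if raw.ndim == 3:                      # color -> luminance
        raw = raw.mean(axis=2)
    if raw.ndim != 2 or min(raw.shape) < 2:
        raise ValueError("input must be a 2-D image with >= 2 rows/cols")
    if raw.shape != (target_px, target_px):
        raw = resize(raw, (target_px, target_px), anti_aliasing=True,
                     preserve_range=True)
    x = raw
    if normalize_contrast:
        if sigma is None:
            sigma = target_px / 16.0
        local_mean = gaussian_filter(x, sigma, mode="wrap")
        d = x - local_mean
        local_sd = np.sqrt(np.maximum(gaussian_filter(d * d, sigma, mode="wrap"), 0.0))
        x = d / (eps + local_sd)
    lo, hi = x.min(), x.max()
    if hi - lo < np.finfo(float).eps:
        pixels = np.full_like(x, 0.5)
    else:
        pixels = (x - lo) / (hi - lo)
    return SceneImage(pixels=pixels, deg_per_px=40.0 / target_px)


def build_filter_bank(
    size_px: int = 256,
    n_orientations: int = 8,
    n_scales: int = 6,
    f_max: float = 0.25,
    octave_spacing: float = 2.0,
    radial_bandwidth: float = 0.65,
    angular_overlap: float = 1.3,
) -> FilterBank:
    """Polar-separable log-Gabor bank in the frequency domain.

    The radial component is a log-Gaussian centred on octave-spaced
    frequencies starting at ``f_max`` cycles/pixel; ``radial_bandwidth`` is
    the ratio sigma/f0 in log-frequency (0.65 ~ one octave).  The angular
    component is a raised-cosine lobe of half-width
    ``angular_overlap * pi / n_orientations`` around each orientation, single
    lobed so conjugate symmetry covers the opposite half-plane.
    """
    if size_px % 2:
        raise ValueError("size_px must be even")
    if n_orientations < 1 or n_scales < 1:
        raise ValueError("need at least one orientation and one scale")
    freqs = np.fft.fftfreq(size_px)
    FX, FY = np.meshgrid(freqs, freqs)
    r = np.hypot(FX, FY)
    theta = np.arctan2(FY, FX)

    log_r = np.zeros_like(r)
    np.log(r, out=log_r, where=r > 0)

    tfs = np.empty((n_orientations * n_scales, size_px, size_px))
    half_width = angular_overlap * np.pi / n_orientations
    k = 0
    for s in range(n_scales):
        f0 = f_max / octave_spacing ** s
        radial = np.exp(-((log_r - np.log(f0)) ** 2)
                        / (2.0 * np.log(radial_bandwidth) ** 2))
        radial[r == 0] = 0.0
        for o in range(n_orientations):
            angle = o * np.pi / n_orientations
            dt = np.angle(np.exp(1j * (theta - angle)))  # wrapped to [-pi, pi]
            angular = np.where(
                np.abs(dt) < half_width,
                np.cos(np.pi * dt / (2.0 * half_width)) ** 2,
                0.0,
            )
            tf = radial * angular
            tf[0, 0] = 0.0
            tfs[k] = tf
            k += 1
    return FilterBank(
        transfer_functions=tfs,
        n_orientations=n_orientations,
        n_scales=n_scales,
        size_px=size_px,
    )


def filter_response(image: np.ndarray, transfer_function: np.ndarray) -> np.ndarray:
    """Magnitude of the analytic filter response (periodic boundaries)."""
    F = np.fft.fft2(image)
    return np.abs(np.fft.ifft2(F * transfer_function))


def _block_average(mag: np.ndarray, grid: int) -> np.ndarray:
    n = mag.shape[0]
    b = n // grid
    return mag.reshape(grid, b, grid, b).mean(axis=(1, 3))


def extract_gist(image: SceneImage, bank: FilterBank, grid: int = 4) -> GistFeatures:
    """Pooled filter magnitudes: one value per filter x grid block.

    For each filter the image is filtered in the Fourier domain, the response
    magnitude is averaged within each of ``grid x grid`` equal blocks, and
    blocks are concatenated scale-major, then orientation, then row-major.
    """
    if image.size_px != bank.size_px:
        raise ValueError(
            f"image size {image.size_px} != bank size {bank.size_px}"
        )
    if bank.size_px % grid:
        raise ValueError("grid must divide the image size")
    F = np.fft.fft2(image.pixels)
    values = np.empty(bank.n_filters * grid * grid)
    for k, tf in enumerate(bank.transfer_functions):
        mag = np.abs(np.fft.ifft2(F * tf))
        values[k * grid * grid:(k + 1) * grid * grid] = _block_average(mag, grid).ravel()
    return GistFeatures(
        values=values,
        grid=grid,
        n_orientations=bank.n_orientations,
        n_scales=bank.n_scales,
        image_id=image.image_id,
        bank_id=bank.bank_id,
    )


def gist_matrix(images, bank: FilterBank, grid: int = 4) -> np.ndarray:
    """Feature matrix (n_images, n_features) for a list of SceneImages."""
    return np.vstack([extract_gist(im, bank, grid).values for im in images])
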