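"""Stimulus manipulations: set equalization, pink-noise SNR degradation,
occlusion from visual-field-defect masks, central occlusion, and
perimetry-to-mask rasterization.

The canonical order of operations is equalize -> noise -> occlusion
(central occlusion first, then the field-defect mask), mirroring how degraded
stimuli are constructed before the occluding mask is applied.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import griddata

from .types import SceneImage, VFDMap, circular_aperture

logger = logging.getLogger(__name__)

#: The four stimulus signal-to-noise levels, in dB.
DEFAULT_SNR_LEVELS_DB = (-2.0, 5.0, 10.0, 25.0)


@dataclass
class DegradationSpec:
    """Bundle of stimulus-degradation settings for one condition."""

    snr_db: Optional[float] = None          # None = clean
    vfd: Optional[VFDMap] = None
    central_occlusion_deg: float = 5.0      # diameter; 0 disables
    fill_value: Optional[float] = None      # None = set mean luminance
    seed: int = 0

    def __post_init__(self) -> None:
        if self.central_occlusion_deg < 0:
            raise ValueError("central_occlusion_deg must be >= 0")


def equalize_set(images: Sequence[SceneImage]) -> list[SceneImage]:
    """Match every image's mean luminance and RMS contrast to the set average.

    Each image is affinely rescaled so its mean equals the grand mean and its
    standard deviation equals the grand (average) standard deviation, then
    clipped to [0, 1].  A warning is logged if clipping moves either moment by
    more than 1% of its target.
    """
    if len(images) < 2:
        raise ValueError("equalize_set needs at least 2 images")
    sizes = {im.size_px for im in images}
    if len(sizes) != 1:
        raise ValueError("all images must share the same size")
    means = np.array([im.pixels.mean() for im in images])
    stds = np.array([im.pixels.std() for im in images])
    grand_mean = means.mean()
    grand_std = stds.mean()
    out = []
    for im, m, s in zip(images, means, stds):
        if s < np.finfo(float).eps:
            eq = np.full_like(im.pixels, grand_mean)
        else:
            eq = (im.pixels - m) / s * grand_std + grand_mean
        clipped = np.clip(eq, 0.0, 1.0)
        if (
            abs(clipped.mean() - grand_mean) > 0.01 * max(grand_mean, 1e-9)
            or abs(clipped.std() - grand_std) > 0.01 * max(grand_std, 1e-9)
        ):
            logger.warning(
                "clipping moved moments of image %s beyond 1%% of target",
                im.image_id,
            )
        out.append(im.with_pixels(clipped))
    return out


def make_pink_noise(
    size_px: int,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """Unit-variance pink-noise field (amplitude spectrum ~ 1/f, DC = 0)."""
    if size_px % 2:
        raise ValueError("size_px must be even")
    if rng is None:
        rng = np.random.default_rng(seed)
    white = rng.standard_normal((size_px, size_px))
    freqs = np.fft.fftfreq(size_px)
    FX, FY = np.meshgrid(freqs, freqs)
    r = np.hypot(FX, FY)
    with np.errstate(divide="ignore"):
        envelope = np.where(r > 0, 1.0 / r, 0.0)
    noise = np.fft.ifft2(np.fft.fft2(white) * envelope).real
    noise -= noise.mean()
    return noise / noise.std()


def apply_snr(
    image: SceneImage,
    snr_db: float,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> SceneImage:
    """Add pink noise at a fixed signal-to-noise ratio in dB.

    The noise field is scaled so that ``10*log10(var(signal)/var(noise))``
    equals ``snr_db`` exactly before clipping, where the signal variance is
    taken about the image mean; the mean is preserved (zero-mean noise) and
    the result is clipped to [0, 1].
    """
    if not np.isfinite(snr_db):
        raise ValueError("snr_db must be finite")
    var_s = image.pixels.var()
    noise = make_pink_noise(image.size_px, seed=seed, rng=rng)
    target_var_n = var_s / 10.0 ** (snr_db / 10.0)
    degraded = image.pixels + noise * np.sqrt(target_var_n)
    return image.with_pixels(np.clip(degraded, 0.0, 1.0))


def realized_snr_db(signal: np.ndarray, noise: np.ndarray) -> float:
    """Measured 10*log10(var(signal)/var(noise))."""
    return float(10.0 * np.log10(signal.var() / noise.var()))


def rasterize_perimetry(
    points: pd.DataFrame,
    size_px: int = 256,
    extent_deg: float = 20.0,
    blind_threshold_db: float = 10.0,
) -> VFDMap:
    """Interpolate a perimetry point set onto the pixel grid and binarize.

    Sensitivity is interpolated by scattered (triangulation-based) linear
    interpolation with nearest-neighbour extrapolation outside the convex
    hull; pixels whose interpolated sensitivity falls below
    ``blind_threshold_db`` are marked occluded.  The raster is restricted to
    the circular aperture.
    """
    pts = np.asarray(points[["x_deg", "y_deg"]], dtype=float)
    vals = np.asarray(points["sensitivity_db"], dtype=float)
    if pts.shape[0] < 4:
        raise ValueError("need at least 4 perimetry points")
    if np.linalg.matrix_rank(pts - pts.mean(axis=0)) < 2:
        raise ValueError("perimetry points are collinear")
    lo, hi = vals.min(), vals.max()
    if not (lo <= blind_threshold_db <= hi) and lo != hi:
        logger.warning(
            "blind threshold %.1f dB lies outside the data range [%.1f, %.1f]",
            blind_threshold_db, lo, hi,
        )
    c = (size_px - 1) / 2.0
    deg_per_px = 2.0 * extent_deg / size_px
    idx = np.arange(size_px)
    x = (idx - c) * deg_per_px
    y = (c - idx) * deg_per_px
    X, Y = np.meshgrid(x, y)
    interp = griddata(pts, vals, (X, Y), method="linear")
    nearest = griddata(pts, vals, (X, Y), method="nearest")
    interp = np.where(np.isnan(interp), nearest, interp)
    ap = circular_aperture(size_px)
    raster = ((interp < blind_threshold_db) & ap).astype(np.uint8)
    return VFDMap(
        points=points,
        raster=raster,
        extent_deg=extent_deg,
        blind_threshold_db=blind_threshold_db,
    )


def apply_occlusion(
    image: SceneImage, vfd: VFDMap, fill_value: float
) -> SceneImage:
    """Replace masked pixels with a constant fill (mid-gray by convention)."""
    if vfd.raster is None:
        raise ValueError("VFDMap has no raster; rasterize the perimetry first")
    if vfd.raster.shape != image.pixels.shape:
        raise ValueError("mask size does not match the image")
    out = image.pixels.copy()
    out[vfd.raster == 1] = fill_value
    return image.with_pixels(out)


def apply_central_occlusion(
    image: SceneImage, diameter_deg: float, fill_value: float
) -> SceneImage:
    """Occlude a central disc of the given angular diameter."""
    if diameter_deg < 0:
        raise ValueError("diameter_deg must be >= 0")
    if diameter_deg == 0:
        return image
    n = image.size_px
    c = (n - 1) / 2.0
    yy, xx = np.mgrid[0:n, 0:n]
    r_px = np.hypot(xx - c, yy - c)
    radius_px = (diameter_deg / 2.0) / image.deg_per_px
    out = image.pixels.copy()
    out[r_px <= radius_px] = fill_value
    return image.with_pixels(out)


def degrade(
    image: SceneImage,
    spec: DegradationSpec,
    set_mean: Optional[float] = None,
    rng: Optional[np.random.Generator] = None,
) -> SceneImage:
    """Apply the full degradation chain: noise, central occlusion, VFD mask."""
    fill = spec.fill_value
    if fill is None:
        fill = image.pixels.mean() if set_mean is None else set_mean
    out = image
    if spec.snr_db is not None:
        out = apply_snr(out, spec.snr_db, seed=spec.seed, rng=rng)
    if spec.central_occlusion_deg > 0:
        out = apply_central_occlusion(out, spec.central_occlusion_deg, fill)
    if spec.vfd is not None and spec.vfd.kind != "none":
        out = apply_occlusion(out, spec.vfd, fill)
    return out
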