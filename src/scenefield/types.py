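"""Core containers shared across the pipeline.

Geometry convention: stimuli are square luminance rasters covering a circular
aperture of 20 degrees radius (40 degrees diameter), so ``deg_per_px`` defaults
to ``40 / size_px``.  Visual-field coordinates put +x to the right and +y up,
with (0, 0) at the image centre.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

#: Angular diameter of the stimulus in degrees (20 degree radius aperture).
FULL_FIELD_DEG = 40.0


def circular_aperture(size_px: int) -> np.ndarray:
    """Boolean mask of pixels inside the circular stimulus aperture."""
    c = (size_px - 1) / 2.0
    yy, xx = np.mgrid[0:size_px, 0:size_px]
    r = np.hypot(xx - c, yy - c)
    return r <= size_px / 2.0


def pixel_coords_deg(size_px: int, deg_per_px: Optional[float] = None):
    """Return (x_deg, y_deg) visual-field coordinate grids for a raster."""
    if deg_per_px is None:
        deg_per_px = FULL_FIELD_DEG / size_px
    c = (size_px - 1) / 2.0
    idx = np.arange(size_px)
    x_deg = (idx - c) * deg_per_px            # columns, + to the right
    y_deg = (c - idx) * deg_per_px            # rows, + upward
    return np.meshgrid(x_deg, y_deg)[0], np.meshgrid(x_deg, y_deg)[1]


@dataclass
class SceneImage:
    """Square luminance raster in [0, 1] with an optional category label."""

    pixels: np.ndarray
    task: Optional[str] = None          # "naturalness" | "concealment" | None
    label: Optional[int] = None         # binary category (0 / 1) or None
    deg_per_px: float = FULL_FIELD_DEG / 256
    image_id: Optional[str] = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2 or self.pixels.shape[0] != self.pixels.shape[1]:
            raise ValueError("SceneImage requires a square 2-D array")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("SceneImage pixels must be finite")

    @property
    def size_px(self) -> int:
        return self.pixels.shape[0]

    def with_pixels(self, pixels: np.ndarray) -> "SceneImage":
        return replace(self, pixels=pixels)


@dataclass
class VFDMap:
    """Visual-field defect: perimetry point set and/or a binary occlusion raster.

    ``raster`` marks occluded pixels with 1.  Area fractions only count pixels
    inside the circular aperture; ``points`` is a DataFrame with columns
    ``x_deg, y_deg, sensitivity_db``.
    """

    points: Optional[pd.DataFrame] = None
    raster: Optional[np.ndarray] = None
    extent_deg: float = 20.0            # aperture radius
    blind_threshold_db: float = 10.0
    kind: Optional[str] = None

    def __post_init__(self) -> None:
        if self.points is None and self.raster is None:
            raise ValueError("VFDMap needs at least one of points / raster")
        if self.raster is not None:
            self.raster = np.asarray(self.raster)
            vals = np.unique(self.raster)
            if not np.all(np.isin(vals, [0, 1])):
                raise ValueError("VFDMap raster must be binary (0/1)")
            self.raster = self.raster.astype(np.uint8)

    @property
    def size_px(self) -> Optional[int]:
        return None if self.raster is None else self.raster.shape[0]

    def occluded_fraction(self) -> float:
        """Fraction of within-aperture pixels that are occluded."""
        if self.raster is None:
            raise ValueError("VFDMap has no raster")
        ap = circular_aperture(self.raster.shape[0])
        return float(self.raster[ap].mean())


@dataclass
class GistFeatures:
    """Pooled Gabor-magnitude feature vector for one image."""

    values: np.ndarray
    grid: int = 4
    n_orientations: int = 8
    n_scales: int = 6
    image_id: Optional[str] = None
    bank_id: Optional[str] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        expected = self.n_orientations * self.n_scales * self.grid ** 2
        if self.values.size != expected:
            raise ValueError(
                f"feature length {self.values.size} != "
                f"{self.n_orientations}x{self.n_scales}x{self.grid}^2 = {expected}"
            )


@dataclass(frozen=True)
class ConfusionCounts:
    """2x2 confusion counts for one condition (signal = label 1)."""

    hits: int
    misses: int
    false_alarms: int
    correct_rejections: int

    def __post_init__(self) -> None:
        for v in (self.hits, self.misses, self.false_alarms, self.correct_rejections):
            if v < 0:
                raise ValueError("counts must be nonnegative")


@dataclass
class ResponseTable:
    """Per-condition confusion counts for one observer (human or model).

    Label convention: category 1 is "signal"; responding "1" on a label-1
    trial is a hit, on a label-0 trial a false alarm.
    """

    counts: dict[str, ConfusionCounts] = field(default_factory=dict)
    observer_id: Optional[str] = None

    def __getitem__(self, condition: str) -> ConfusionCounts:
        return self.counts[condition]

    def conditions(self) -> list[str]:
        return list(self.counts)
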