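"""Synthetic inputs: parametric scene categories, field-defect masks,
perimetry grids, and simulated binary-choice observers.

Scene categories are spectral families: white Gaussian noise shaped in the
Fourier domain by a 1/f^alpha radial falloff modulated by per-orientation and
per-spatial-frequency band weights.  Two categories whose orientation or
spatial-frequency weights differ are separable by a spectral-envelope
descriptor at a margin controlled by the weight contrast, which is exactly the
information a pooled Gabor-energy descriptor reads out.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.stats import norm

from .types import ConfusionCounts, ResponseTable, SceneImage, VFDMap, circular_aperture

VFD_KINDS = (
    "none",
    "hemi_left",
    "hemi_right",
    "quad_left_up",
    "quad_left_down",
    "quad_right_up",
    "quad_right_down",
)


@dataclass
class SceneParams:
    """Spectral-family parameters for one synthetic scene category.

    ``orientation_profile`` weights power over orientation bands in [0, pi);
    ``sf_profile`` weights power over log-spaced spatial-frequency bands.
    Both are normalized to sum to 1.  ``spectral_exponent`` is the amplitude
    falloff alpha in amplitude ~ f^-alpha (1.0 mimics natural-image statistics).
    """

    size_px: int = 256
    spectral_exponent: float = 1.0
    orientation_profile: np.ndarray = field(
        default_factory=lambda: np.ones(8) / 8.0
    )
    sf_profile: np.ndarray = field(default_factory=lambda: np.ones(6) / 6.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.size_px % 2:
            raise ValueError("size_px must be even")
        self.orientation_profile = np.asarray(self.orientation_profile, dtype=float)
        self.sf_profile = np.asarray(self.sf_profile, dtype=float)
        for name in ("orientation_profile", "sf_profile"):
            w = getattr(self, name)
            if np.any(w < 0) or w.sum() <= 0:
                raise ValueError(f"{name} must be nonnegative with positive sum")
            setattr(self, name, w / w.sum())

    @classmethod
    def cardinal(cls, size_px: int = 256, strength: float = 1.5, **kw) -> "SceneParams":
        """Category dominated by horizontal/vertical power (urban-like)."""
        w = np.ones(8)
        w[[0, 4]] = strength
        return cls(size_px=size_px, orientation_profile=w, **kw)

    @classmethod
    def oblique(cls, size_px: int = 256, strength: float = 1.5, **kw) -> "SceneParams":
        """Category dominated by oblique power (natural-like)."""
        w = np.ones(8)
        w[[2, 6]] = strength
        return cls(size_px=size_px, orientation_profile=w, **kw)


def _spectral_envelope(params: SceneParams) -> np.ndarray:
    n = params.size_px
    fx = np.fft.fftfreq(n)
    fy = np.fft.fftfreq(n)
    FX, FY = np.meshgrid(fx, fy)
    r = np.hypot(FX, FY)
    theta = np.mod(np.arctan2(FY, FX), np.pi)  # orientation, period pi

    with np.errstate(divide="ignore"):
        radial = np.where(r > 0, r ** (-params.spectral_exponent), 0.0)

    n_or = params.orientation_profile.size
    # circular interpolation over orientation bands centred at k*pi/n_or
    centres = np.arange(n_or) * np.pi / n_or
    ext_centres = np.concatenate([centres, [np.pi]])
    ext_w = np.concatenate([params.orientation_profile,
                            params.orientation_profile[:1]])
    w_theta = np.interp(theta, ext_centres, ext_w)

    n_sf = params.sf_profile.size
    f_lo, f_hi = 2.0 / n, 0.5  # from ~2 cycles/image to Nyquist
    edges = np.geomspace(f_lo, f_hi, n_sf + 1)
    # interpolate band weights in log-frequency
    log_centres = 0.5 * (np.log(edges[:-1]) + np.log(edges[1:]))
    w_sf = np.interp(np.log(np.clip(r, f_lo, f_hi)), log_centres,
                     params.sf_profile,
                     left=params.sf_profile[0], right=params.sf_profile[-1])

    env = radial * np.sqrt(w_theta * w_sf)
    env[0, 0] = 0.0
    return env


def synthesize_scene(params: SceneParams, rng: np.random.Generator) -> np.ndarray:
    """One scene: spectrally shaped Gaussian noise rescaled to [0, 1]."""
    n = params.size_px
    white = rng.standard_normal((n, n))
    shaped = np.fft.ifft2(np.fft.fft2(white) * _spectral_envelope(params)).real
    lo, hi = shaped.min(), shaped.max()
    if hi - lo < np.finfo(float).eps:
        return np.full_like(shaped, 0.5)
    return (shaped - lo) / (hi - lo)


def generate_scene_set(
    params_a: SceneParams,
    params_b: SceneParams,
    n_per_category: int,
    seed: int,
    task: str = "naturalness",
) -> list[SceneImage]:
    """Generate ``2 * n_per_category`` labelled scenes (labels 0 and 1)."""
    if n_per_category < 1:
        raise ValueError("n_per_category must be >= 1")
    if params_a.size_px != params_b.size_px:
        raise ValueError("categories must share size_px")
    rng = np.random.default_rng(seed)
    deg_per_px = 40.0 / params_a.size_px
    images = []
    for label, params in ((0, params_a), (1, params_b)):
        for i in range(n_per_category):
            images.append(
                SceneImage(
                    pixels=synthesize_scene(params, rng),
                    task=task,
                    label=label,
                    deg_per_px=deg_per_px,
                    image_id=f"{task}-cat{label}-{i:04d}",
                )
            )
    return images


def orientation_band_energy(image: np.ndarray, n_bands: int = 8) -> np.ndarray:
    """Fourier power per orientation band; the band-energy oracle used in tests."""
    f = np.fft.fft2(image - image.mean())
    power = np.abs(f) ** 2
    n = image.shape[0]
    FX, FY = np.meshgrid(np.fft.fftfreq(n), np.fft.fftfreq(n))
    theta = np.mod(np.arctan2(FY, FX), np.pi)
    band = np.floor(
        np.mod(theta + np.pi / (2 * n_bands), np.pi) / (np.pi / n_bands)
    ).astype(int)
    return np.array([power[band == b].sum() for b in range(n_bands)])


# ---------------------------------------------------------------------------
# Visual-field defects and perimetry
# ---------------------------------------------------------------------------

def generate_vfd(kind: str, size_px: int = 256) -> VFDMap:
    """Binary occlusion raster for a simulated field defect.

    Hemifield masks split the circular aperture at the vertical meridian;
    quadrant masks additionally split at the horizontal meridian.
    """
    if kind not in VFD_KINDS:
        raise ValueError(f"unknown VFD kind {kind!r}; one of {VFD_KINDS}")
    if size_px % 2:
        raise ValueError("size_px must be even")
    ap = circular_aperture(size_px)
    c = (size_px - 1) / 2.0
    yy, xx = np.mgrid[0:size_px, 0:size_px]
    x = xx - c          # + to the right
    y = c - yy          # + upward
    if kind == "none":
        sel = np.zeros_like(ap)
    elif kind == "hemi_left":
        sel = x < 0
    elif kind == "hemi_right":
        sel = x > 0
    else:
        _, side, vert = kind.split("_")
        sel = (x < 0) if side == "left" else (x > 0)
        sel = sel & ((y > 0) if vert == "up" else (y < 0))
    raster = (sel & ap).astype(np.uint8)
    return VFDMap(raster=raster, extent_deg=20.0, kind=kind)


#: Humphrey 30-2 lattice: 6 degree spacing, offset 3 degrees from meridians.
def humphrey_30_2_lattice() -> np.ndarray:
    """(76, 2) array of 30-2 test-point coordinates in degrees (x right, y up)."""
    rows = {27: 9, 21: 15, 15: 21, 9: 27, 3: 27}
    pts = []
    for ay, xmax in rows.items():
        for sy in (1, -1):
            y = sy * ay
            for x in range(-xmax, xmax + 1, 6):
                pts.append((x, y))
    return np.array(sorted(set(pts)), dtype=float)


def generate_perimetry_grid(
    vfd: VFDMap,
    grid: str = "humphrey_30_2",
    floor_db: float = 0.0,
    ceiling_db: float = 30.0,
    jitter_db: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulated perimetry: sensitivity at each lattice point given a defect map.

    Points inside the defect read ``floor_db``, points outside ``ceiling_db``,
    with optional seeded Gaussian measurement jitter.  Lattice points beyond
    the raster's aperture are sampled at the nearest within-aperture position
    along the ray from fixation, so the defect geometry extends radially.
    """
    if grid != "humphrey_30_2":
        raise ValueError(f"unsupported perimetry grid {grid!r}")
    if not ceiling_db > floor_db >= 0:
        raise ValueError("require ceiling_db > floor_db >= 0")
    if vfd.raster is None:
        raise ValueError("perimetry simulation needs a raster VFDMap")
    n = vfd.raster.shape[0]
    c = (n - 1) / 2.0
    deg_per_px = 2 * vfd.extent_deg / n
    pts = humphrey_30_2_lattice()
    rng = np.random.default_rng(seed)
    rows = []
    for x_deg, y_deg in pts:
        r = np.hypot(x_deg, y_deg)
        if r > 0.95 * vfd.extent_deg:
            scale = 0.95 * vfd.extent_deg / r
            xs, ys = x_deg * scale, y_deg * scale
        else:
            xs, ys = x_deg, y_deg
        col = int(round(c + xs / deg_per_px))
        row = int(round(c - ys / deg_per_px))
        inside_defect = bool(vfd.raster[row, col])
        s = floor_db if inside_defect else ceiling_db
        if jitter_db > 0:
            s = float(np.clip(s + rng.normal(0.0, jitter_db), floor_db, ceiling_db))
        rows.append((x_deg, y_deg, s))
    return pd.DataFrame(rows, columns=["x_deg", "y_deg", "sensitivity_db"])


def write_perimetry_csv(points: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        fh.write("# perimetry point set: x_deg,y_deg,sensitivity_db\n")
        points.to_csv(fh, index=False)


def read_perimetry_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    expected = {"x_deg", "y_deg", "sensitivity_db"}
    if not expected.issubset(df.columns):
        raise ValueError(f"perimetry CSV must have columns {sorted(expected)}")
    return df


# ---------------------------------------------------------------------------
# Simulated observers
# ---------------------------------------------------------------------------

@dataclass
class ObserverSpec:
    """Equal-variance Gaussian observer.

    ``criterion`` is measured from the midpoint between the two class means,
    so ``criterion = 0`` means unbiased.  ``lapse_rate`` (default 0) is the
    probability of a uniformly random response regardless of the stimulus.
    """

    dprime: Union[float, Mapping[str, float]]
    criterion: Union[float, Mapping[str, float]] = 0.0
    n_trials_per_condition: int = 100
    lapse_rate: float = 0.0
    seed: int = 0
    observer_id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.n_trials_per_condition < 1:
            raise ValueError("n_trials_per_condition must be >= 1")
        if not 0.0 <= self.lapse_rate <= 1.0:
            raise ValueError("lapse_rate must be in [0, 1]")

    def _get(self, mapping, condition):
        if isinstance(mapping, Mapping):
            return float(mapping[condition])
        return float(mapping)

    def dprime_for(self, condition: str) -> float:
        d = self._get(self.dprime, condition)
        if not np.isfinite(d):
            raise ValueError("dprime must be finite")
        return d

    def criterion_for(self, condition: str) -> float:
        return self._get(self.criterion, condition)


def simulate_observer(
    spec: ObserverSpec,
    stimuli: Mapping[str, Sequence[int]],
    rng: Optional[np.random.Generator] = None,
) -> ResponseTable:
    """Simulate one observer's binary responses over per-condition trials.

    Internal evidence is N(0, 1) for label-0 stimuli and N(d', 1) for label-1
    stimuli; the observer responds "1" when evidence exceeds ``c + d'/2``.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    table = ResponseTable(observer_id=spec.observer_id)
    for condition, labels in stimuli.items():
        labels = np.asarray(labels, dtype=int)
        if labels.size == 0 or len(np.unique(labels)) < 2:
            raise ValueError(
                f"condition {condition!r} needs stimuli of both labels"
            )
        d = spec.dprime_for(condition)
        c = spec.criterion_for(condition)
        evidence = rng.standard_normal(labels.size) + d * labels
        resp = (evidence > c + d / 2.0).astype(int)
        if spec.lapse_rate > 0:
            lapse = rng.random(labels.size) < spec.lapse_rate
            resp = np.where(lapse, rng.integers(0, 2, labels.size), resp)
        table.counts[condition] = ConfusionCounts(
            hits=int(np.sum((labels == 1) & (resp == 1))),
            misses=int(np.sum((labels == 1) & (resp == 0))),
            false_alarms=int(np.sum((labels == 0) & (resp == 1))),
            correct_rejections=int(np.sum((labels == 0) & (resp == 0))),
        )
    return table


def balanced_trial_labels(n_trials: int, rng: np.random.Generator) -> np.ndarray:
    """A shuffled label sequence with (as close as possible to) equal counts."""
    labels = np.array([0, 1] * (n_trials // 2) + [0] * (n_trials % 2))
    rng.shuffle(labels)
    return labels


def expected_response_rates(dprime: float, criterion: float) -> tuple[float, float]:
    """Closed-form (hit rate, false-alarm rate) for the Gaussian observer."""
    return (
        float(norm.cdf(dprime / 2.0 - criterion)),
        float(norm.cdf(-dprime / 2.0 - criterion)),
    )
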