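"""Signal-detection and Bayesian statistics.

Observed sensitivity d' = z(H) - z(FA) and criterion c = -(z(H) + z(FA))/2
are computed from 2x2 confusion counts under the equal-variance Gaussian
model.  Model-vs-observer comparisons use the sensitivity difference
r = d_hat - d_obs, a one-sample t-test, a BIC-approximated Bayes factor
(unit-information prior), and Benjamini-Hochberg FDR control.  Field-defect
extent is summarized by the Blind Field Index BFI = VFI - 1, where the VFI
is the unoccluded fraction of the aperture (0 = no blind field, -1 = blind).
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .types import ConfusionCounts, VFDMap

#: ln(BF) magnitude above which evidence is labelled "strong".
STRONG_EVIDENCE_LN_BF = 4.6

#: BFI at or below which a defect is classed as hemianopia (strict "<").
HEMIANOPIA_BFI_THRESHOLD = -0.375


@dataclass
class SDTEstimate:
    d_prime: float
    criterion_c: float
    n_trials: int
    correction_applied: bool


@dataclass
class BayesTTestResult:
    t_stat: float
    df: int
    p_value: float
    bf01: float
    ln_bf01: float

    @property
    def strong_evidence(self) -> bool:
        return abs(self.ln_bf01) > STRONG_EVIDENCE_LN_BF


@dataclass
class SensitivityComparison:
    r_hat: float
    direction: str
    t_stat: float
    df: int
    p_value: float
    bf01: float
    ln_bf: float
    fdr_significant: bool = False


@dataclass
class BlindFieldIndex:
    bfi: float
    vfi: float
    source: str = "mask"

    def __post_init__(self) -> None:
        if not -1.0 - 1e-9 <= self.bfi <= 1e-9:
            raise ValueError("BFI must lie in [-1, 0]")


def compute_dprime(counts: ConfusionCounts) -> SDTEstimate:
    """Sensitivity and criterion from confusion counts.

    Extreme rates (0 or 1) are handled by the log-linear rule: 0.5 is added
    to every cell before rates are formed, and ``correction_applied`` is set.
    """
    h, m = counts.hits, counts.misses
    fa, cr = counts.false_alarms, counts.correct_rejections
    if h + m == 0 or fa + cr == 0:
        raise ValueError("each stimulus class needs at least one trial")
    hr = h / (h + m)
    far = fa / (fa + cr)
    corrected = hr in (0.0, 1.0) or far in (0.0, 1.0)
    if corrected:
        hr = (h + 0.5) / (h + m + 1.0)
        far = (fa + 0.5) / (fa + cr + 1.0)
    zh, zf = stats.norm.ppf(hr), stats.norm.ppf(far)
    return SDTEstimate(
        d_prime=float(zh - zf),
        criterion_c=float(-(zh + zf) / 2.0),
        n_trials=h + m + fa + cr,
        correction_applied=corrected,
    )


def sensitivity_difference(
    d_hat: float,
    d_obs: float,
    direction: Literal["model_minus_observer", "observer_minus_model"]
    = "model_minus_observer",
) -> float:
    """Signed difference between model and observed sensitivity.

    ``model_minus_observer`` (r = d_hat - d_obs) is the healthy-control
    convention: positive r means the model is the more sensitive.  The
    reversed direction is used when benchmarking lesion participants against
    the model's prediction from their own field defect.
    """
    if not (np.isfinite(d_hat) and np.isfinite(d_obs)):
        raise ValueError("sensitivities must be finite")
    if direction == "model_minus_observer":
        return float(d_hat - d_obs)
    if direction == "observer_minus_model":
        return float(d_obs - d_hat)
    raise ValueError(f"unknown direction {direction!r}")


def bayes_ttest_one_sample(values: Sequence[float], mu0: float = 0.0) -> BayesTTestResult:
    """One-sample t-test with a BIC-approximated Bayes factor.

    BF01 = sqrt(n) * (1 + t^2/(n-1))^(-n/2), the unit-information-prior
    approximation obtained from the BIC difference between the null model
    (mean fixed at mu0) and the alternative (free mean).  BF01 > 1 favours
    the null; |ln BF| > 4.6 is labelled strong evidence.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 values")
    if x.std(ddof=1) == 0:
        raise ValueError("zero variance")
    n = x.size
    t, p = stats.ttest_1samp(x, popmean=mu0)
    t = float(t)
    bf01 = float(np.sqrt(n) * (1.0 + t * t / (n - 1)) ** (-n / 2.0))
    return BayesTTestResult(
        t_stat=t, df=n - 1, p_value=float(p), bf01=bf01, ln_bf01=float(np.log(bf01))
    )


def fdr_adjust(p_values: Sequence[float], q: float = 0.05):
    """Benjamini-Hochberg step-up correction.

    Returns ``(adjusted_p, reject)`` where ``reject[i]`` is True when the
    adjusted p-value is at most ``q``.
    """
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if not 0.0 < q < 1.0:
        raise ValueError("q must lie in (0, 1)")
    reject, p_adj, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return p_adj, reject


def compute_bfi(vfd: VFDMap) -> BlindFieldIndex:
    """Blind Field Index of a rasterized defect map.

    VFI = unoccluded fraction of within-aperture pixels (unweighted area
    fraction); BFI = VFI - 1, so 0 means no blind field and -1 fully blind.
    """
    if vfd.raster is None:
        raise ValueError("VFDMap has no raster")
    occluded = vfd.occluded_fraction()
    vfi = 1.0 - occluded
    return BlindFieldIndex(bfi=vfi - 1.0, vfi=vfi, source="mask")


def classify_vfd(bfi: float, side: Literal["left", "right"]) -> str:
    """Crude defect class from BFI: hemianopia iff BFI < -0.375, else quadrant.

    The boundary is strict: BFI exactly -0.375 is classed as quadrantanopia.
    """
    if not -1.0 - 1e-9 <= bfi <= 1e-9:
        raise ValueError("BFI must lie in [-1, 0]")
    if side not in ("left", "right"):
        raise ValueError("side must be 'left' or 'right'")
    extent = "hemi" if bfi < HEMIANOPIA_BFI_THRESHOLD else "quadrant"
    return f"{side}_{extent}"
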