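"""Image- and agreement-quality statistics: MAE, UQI, and Lin's CCC.

MAE (mean absolute error, HU) and the Wang-Bovik universal quality index
(UQI) grade a synthetic CT against the planning CT it stands in for; Lin's
concordance correlation coefficient (CCC) grades the agreement of paired
dosimetric or toxicity quantities derived from the two CTs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import uniform_filter

from .grids import ImageVolume, StructureMask

__all__ = ["mae", "uqi", "ccc", "ccc_band", "MetricResult"]


@dataclass
class MetricResult:
    name: str
    value: float
    scope: str = "all"  # "all" or "body"
    per_case: tuple[float, ...] = ()

    @property
    def mean(self) -> float:
        return float(np.mean(self.per_case)) if self.per_case else self.value

    @property
    def sd(self) -> float:
        return float(np.std(self.per_case, ddof=1)) if len(self.per_case) > 1 else 0.0


def _paired_arrays(a, b, mask=None) -> tuple[np.ndarray, np.ndarray]:
    xa = a.data if isinstance(a, ImageVolume) else np.asarray(a)
    xb = b.data if isinstance(b, ImageVolume) else np.asarray(b)
    if xa.shape != xb.shape:
        raise ValueError(f"shape mismatch: {xa.shape} vs {xb.shape}")
    if mask is not None:
        m = mask.data if isinstance(mask, StructureMask) else np.asarray(mask, bool)
        if m.shape != xa.shape:
            raise ValueError("mask shape does not match images")
        if not m.any():
            raise ValueError("empty mask")
        return xa[m].astype(np.float64), xb[m].astype(np.float64)
    return xa.astype(np.float64).ravel(), xb.astype(np.float64).ravel()


def mae(a, b, mask=None) -> float:
    """Mean absolute intensity difference, by default over all voxels."""
    xa, xb = _paired_arrays(a, b, mask)
    return float(np.mean(np.abs(xa - xb)))


def _uqi_from_moments(mu_a, mu_b, var_a, var_b, cov):
    num = 4.0 * cov * mu_a * mu_b
    den = (var_a + var_b) * (mu_a**2 + mu_b**2)
    return num, den


def uqi(a, b, mode: str = "global", window: int = 8, mask=None) -> float:
    """Universal quality index Q in [-1, 1]; 1 means identical images.

    Q = 4 cov(a,b) mu_a mu_b / ((var_a + var_b)(mu_a^2 + mu_b^2)) combines
    loss of correlation, luminance distortion and contrast distortion.
    ``global`` evaluates the formula once over the (masked) volume;
    ``windowed`` averages it over sliding cubic windows, skipping windows
    where the denominator vanishes.
    """
    if mode == "global":
        xa, xb = _paired_arrays(a, b, mask)
        mu_a, mu_b = xa.mean(), xb.mean()
        var_a, var_b = xa.var(), xb.var()
        cov = ((xa - mu_a) * (xb - mu_b)).mean()
        num, den = _uqi_from_moments(mu_a, mu_b, var_a, var_b, cov)
        if den == 0.0:
            raise ValueError("UQI undefined: both images constant (zero denominator)")
        return float(num / den)
    if mode != "windowed":
        raise ValueError(f"unknown UQI mode {mode!r}")

    xa = (a.data if isinstance(a, ImageVolume) else np.asarray(a)).astype(np.float64)
    xb = (b.data if isinstance(b, ImageVolume) else np.asarray(b)).astype(np.float64)
    if xa.shape != xb.shape:
        raise ValueError(f"shape mismatch: {xa.shape} vs {xb.shape}")
    size = min(window, *xa.shape)
    mu_a = uniform_filter(xa, size)
    mu_b = uniform_filter(xb, size)
    var_a = uniform_filter(xa * xa, size) - mu_a**2
    var_b = uniform_filter(xb * xb, size) - mu_b**2
    cov = uniform_filter(xa * xb, size) - mu_a * mu_b
    num, den = _uqi_from_moments(mu_a, mu_b, var_a, var_b, cov)
    ok = np.abs(den) > 1e-12
    if not ok.any():
        raise ValueError("UQI undefined everywhere (constant images)")
    return float(np.clip(np.mean(num[ok] / den[ok]), -1.0, 1.0))


def ccc(x, y) -> float:
    """Lin's concordance correlation coefficient with population (1/n) moments.

    rho_c = 2 s_xy / (s_x^2 + s_y^2 + (xbar - ybar)^2); equals Pearson's r
    scaled by a bias-correction factor, so |rho_c| <= |r|.
    """
    x = np.asarray(x, dtype=np.float64).ravel()
    y = np.asarray(y, dtype=np.float64).ravel()
    if x.shape != y.shape:
        raise ValueError("sequences must have equal length")
    n = x.size
    if n < 2:
        raise ValueError("CCC requires at least 2 paired values")
    sx2 = x.var()
    sy2 = y.var()
    sxy = ((x - x.mean()) * (y - y.mean())).mean()
    denom = sx2 + sy2 + (x.mean() - y.mean()) ** 2
    if denom == 0.0:
        raise ValueError("CCC undefined: both sequences constant and equal")
    return float(2.0 * sxy / denom)


_CCC_BANDS = (
    (0.99, "near-perfect"),
    (0.95, "substantial"),
    (0.90, "moderate"),
)


def ccc_band(value: float) -> str:
    """Qualitative agreement label for a CCC value.

    >= 0.99 near-perfect; [0.95, 0.99) substantial; [0.90, 0.95) moderate;
    < 0.90 poor.  Boundaries are closed on the lower edge of each band.
    """
    if not -1.0 <= value <= 1.0:
        raise ValueError(f"CCC must lie in [-1, 1], got {value}")
    for lo, label in _CCC_BANDS:
        if value >= lo:
            return label
    return "poor"
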