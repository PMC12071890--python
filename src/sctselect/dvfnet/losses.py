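"""SSIM and the registration training loss.

The training objective is

    loss = (1 - SSIM(warp(dCT, u), pCT)) + lambda * R(u)

with SSIM computed on intensities normalized to [0, 1] by a fixed HU window,
and R the diffusion regularizer (mean squared spatial gradient of the
displacement components), discouraging non-smooth fields.
"""

from __future__ import annotations

import numpy as np

from ..grids import ImageVolume
from . import autodiff as ad
from .network import normalize_hu

__all__ = ["ssim", "ssim_volumes", "registration_loss"]

# SSIM stabilizing constants for a [0, 1] dynamic range
C1 = 0.01**2
C2 = 0.03**2


def ssim(a: ad.Tensor, b: ad.Tensor, window: int = 7) -> ad.Tensor:
    """Mean structural similarity over sliding 3D windows.

    Inputs are (N, C, D, H, W) tensors already scaled to [0, 1].  Uses the
    standard luminance-contrast-structure product with constants C1, C2.
    """
    if any(n < window for n in a.shape[-3:]):
        raise ValueError(f"SSIM window {window} larger than volume {a.shape[-3:]}")
    mu_a = ad.boxfilter_valid(a, window)
    mu_b = ad.boxfilter_valid(b, window)
    a2 = ad.boxfilter_valid(a * a, window)
    b2 = ad.boxfilter_valid(b * b, window)
    ab = ad.boxfilter_valid(a * b, window)
    var_a = a2 - mu_a * mu_a
    var_b = b2 - mu_b * mu_b
    cov = ab - mu_a * mu_b
    num = (2.0 * mu_a * mu_b + C1) * (2.0 * cov + C2)
    den = (mu_a * mu_a + mu_b * mu_b + C1) * (var_a + var_b + C2)
    return (num / den).mean()


def ssim_volumes(a: ImageVolume, b: ImageVolume, window: int = 7) -> float:
    """SSIM between two HU volumes (normalized internally); plain float."""
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    ta = ad.Tensor(normalize_hu(np.asarray(a.data))[None, None])
    tb = ad.Tensor(normalize_hu(np.asarray(b.data))[None, None])
    return float(ssim(ta, tb, window).data)


def registration_loss(
    dct_norm: np.ndarray,
    pct_norm: np.ndarray,
    dvf_mm: ad.Tensor,
    spacing,
    lam: float = 0.01,
    window: int = 7,
) -> ad.Tensor:
    """(1 - SSIM) image term plus weighted diffusion regularization.

    ``dct_norm``/``pct_norm`` are (N, 1, D, H, W) arrays already normalized
    to [0, 1]; ``dvf_mm`` is the network output in mm.
    """
    if lam < 0:
        raise ValueError("regularization weight must be non-negative")
    sp = np.asarray(spacing, dtype=np.float64).reshape(1, 3, 1, 1, 1)
    disp_vox = dvf_mm * (1.0 / sp)
    warped = ad.warp3d(dct_norm, disp_vox)
    image_term = 1.0 - ssim(warped, ad.Tensor(pct_norm), window)
    if lam == 0:
        return image_term
    return image_term + lam * ad.grad_penalty(dvf_mm, np.asarray(spacing))
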