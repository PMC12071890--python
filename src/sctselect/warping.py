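"""Backward warping of volumes by displacement fields (plain numpy path).

``warp`` resamples a volume through a displacement field: the output voxel at
index x takes the input value at x + u(x), with u stored in mm and converted
to voxel units via the grid spacing.  Trilinear interpolation is used for
images and doses, nearest-neighbour for masks (keeps them binary).  Samples
falling outside the grid take the border value.

The differentiable counterpart used inside the registration network lives in
``sctselect.dvfnet``; this module is the reference implementation both share
semantics with.
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import map_coordinates

from .grids import DisplacementField, ImageVolume, StructureMask

__all__ = ["warp", "warp_array", "invert_dvf", "resample_dvf", "jacobian_determinant"]


def warp_array(
    data: np.ndarray, disp_vox: np.ndarray, order: int = 1
) -> np.ndarray:
    """Backward-warp ``data`` by a displacement given in voxel units (3, ...)."""
    if disp_vox.shape != (3, *data.shape):
        raise ValueError(f"displacement shape {disp_vox.shape} does not match data {data.shape}")
    idx = np.indices(data.shape, dtype=np.float64)
    coords = idx + disp_vox
    return map_coordinates(data.astype(np.float64), coords, order=order, mode="nearest")


def _disp_vox(dvf: DisplacementField) -> np.ndarray:
    sp = np.asarray(dvf.spacing, dtype=np.float64).reshape(3, 1, 1, 1)
    return dvf.data / sp


def warp(volume, dvf: DisplacementField, interpolation: str = "trilinear"):
    """Apply a DVF (mm) to an ImageVolume or StructureMask on the same grid."""
    if volume.shape != dvf.grid_shape:
        raise ValueError(f"volume grid {volume.shape} does not match DVF grid {dvf.grid_shape}")
    if interpolation not in ("trilinear", "nearest"):
        raise ValueError(f"unknown interpolation {interpolation!r}")
    order = 1 if interpolation == "trilinear" else 0
    disp = _disp_vox(dvf)
    if isinstance(volume, StructureMask):
        out = warp_array(volume.data.astype(np.float64), disp, order=0) > 0.5
        return volume.with_data(out)
    out = warp_array(np.asarray(volume.data, dtype=np.float64), disp, order=order)
    return volume.with_data(out)


def invert_dvf(dvf: DisplacementField, n_iter: int = 10) -> DisplacementField:
    """Fixed-point inverse of a small smooth displacement field.

    Solves u(x) = -g(x + u(x)); for invertible fields (max amplitude below
    the deformation length scale) the iteration converges quickly.
    """
    g_vox = _disp_vox(dvf)
    u = -g_vox.copy()
    idx = np.indices(dvf.grid_shape, dtype=np.float64)
    for _ in range(n_iter):
        coords = idx + u
        u = -np.stack(
            [map_coordinates(g_vox[a], coords, order=1, mode="nearest") for a in range(3)]
        )
    sp = np.asarray(dvf.spacing, dtype=np.float64).reshape(3, 1, 1, 1)
    return DisplacementField(u * sp, dvf.spacing, dvf.origin)


def resample_dvf(dvf: DisplacementField, target_shape, target_spacing=None) -> DisplacementField:
    """Trilinearly resample a DVF onto another grid spanning the same extent.

    Displacements are in mm, so only the sampling grid changes, not the
    stored vectors.
    """
    src_shape = np.asarray(dvf.grid_shape, dtype=np.float64)
    tgt_shape = np.asarray(target_shape, dtype=np.float64)
    if target_spacing is None:
        target_spacing = tuple(
            s * a / b for s, a, b in zip(dvf.spacing, src_shape, tgt_shape)
        )
    scale = src_shape / tgt_shape
    idx = np.indices(tuple(int(s) for s in target_shape), dtype=np.float64)
    coords = [(idx[a] + 0.5) * scale[a] - 0.5 for a in range(3)]
    comps = [
        map_coordinates(dvf.data[a], coords, order=1, mode="nearest") for a in range(3)
    ]
    return DisplacementField(np.stack(comps), target_spacing, dvf.origin)


def jacobian_determinant(dvf: DisplacementField) -> np.ndarray:
    """det(I + du/dx) of the deformation x -> x + u(x), per voxel.

    Positive everywhere means the mapping is locally orientation-preserving
    (no folding).  Central differences in mm.
    """
    sp = dvf.spacing
    J = np.empty((3, 3) + dvf.grid_shape)
    for a in range(3):
        for b in range(3):
            J[a, b] = np.gradient(dvf.data[a], sp[b], axis=b)
    det = (
        (1 + J[0, 0]) * ((1 + J[1, 1]) * (1 + J[2, 2]) - J[1, 2] * J[2, 1])
        - J[0, 1] * (J[1, 0] * (1 + J[2, 2]) - J[1, 2] * J[2, 0])
        + J[0, 2] * (J[1, 0] * J[2, 1] - (1 + J[1, 1]) * J[2, 0])
    )
    return det
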