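"""CT preprocessing: couch removal, HU normalization, rigid alignment,
resampling, and training augmentation.

Diagnostic and planning scans differ in couch hardware, scanner protocol
(systematic HU offsets), patient position, and grid resolution.  Before the
registration network sees a pair, both volumes are stripped to the body,
intensity-normalized by quantile (histogram) matching, translation-aligned,
and resampled to the network grid.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.morphology import ball

from .grids import ImageVolume, StructureMask
from .phantom import AIR_HU

__all__ = [
    "HistogramLUT",
    "QAFlags",
    "remove_couch",
    "build_hu_lut",
    "apply_lut",
    "rigid_align",
    "resample",
    "augment",
]

HU_MIN, HU_MAX = -1024.0, 3071.0


@dataclass
class QAFlags:
    """Quality flags raised during body extraction."""

    truncation: bool = False
    notes: tuple[str, ...] = ()

    def __bool__(self) -> bool:
        return self.truncation


@dataclass
class HistogramLUT:
    """Monotone HU -> HU mapping from quantile (histogram) matching.

    ``source_hu[i]`` maps to ``mapped_hu[i]``; application interpolates
    linearly between knots and clamps outside the covered domain.
    """

    source_hu: np.ndarray
    mapped_hu: np.ndarray

    def __post_init__(self) -> None:
        self.source_hu = np.asarray(self.source_hu, dtype=np.float64)
        self.mapped_hu = np.asarray(self.mapped_hu, dtype=np.float64)
        if self.source_hu.shape != self.mapped_hu.shape or self.source_hu.ndim != 1:
            raise ValueError("LUT arrays must be equal-length 1D")
        if np.any(np.diff(self.source_hu) <= 0):
            raise ValueError("LUT source knots must be strictly increasing")
        if np.any(np.diff(self.mapped_hu) < 0):
            raise ValueError("LUT mapping must be monotonically non-decreasing")

    @property
    def bin_width(self) -> float:
        return float(np.max(np.diff(self.source_hu)))

    @classmethod
    def identity(cls) -> "HistogramLUT":
        knots = np.array([HU_MIN, HU_MAX])
        return cls(knots, knots.copy())


def _truncation_flag(body: np.ndarray) -> QAFlags:
    """Detect field-of-view truncation of the body.

    Two signatures: (a) the body reaches three or more of the four lateral
    volume faces (body larger than the reconstructed FOV); (b) the body ends
    laterally in a large flat cross-section -- smooth anatomy tapers to a
    small end-cap, a reconstruction cut does not.
    """
    notes = []
    faces = [body[0].any(), body[-1].any(), body[:, 0].any(), body[:, -1].any()]
    if sum(faces) >= 3:
        notes.append("body touches >=3 lateral volume faces")
    areas = body.sum(axis=(1, 2)).astype(float)
    occ = np.nonzero(areas > 0)[0]
    if occ.size >= 3:
        amax = areas.max()
        for side, i, inward in (("left", occ[0], occ[0] + 1), ("right", occ[-1], occ[-1] - 1)):
            # smooth anatomy tapers plane-to-plane; a cut profile stays flat
            # right up to the end
            if areas[i] > 0.05 * amax and areas[i] > 0.8 * areas[inward]:
                notes.append(
                    f"body cut off laterally ({side}): flat end-plane profile "
                    f"({areas[i]:.0f} vs {areas[inward]:.0f} one plane inward; "
                    "FOV truncation)"
                )
    return QAFlags(truncation=bool(notes), notes=tuple(notes))


def remove_couch(
    volume: ImageVolume,
    air_threshold: float = -250.0,
    closing_radius_mm: float = 5.0,
) -> tuple[ImageVolume, StructureMask, QAFlags]:
    """Strip everything outside the patient body (couch, bed, cables).

    The body is the largest 3D connected component of voxels above
    ``air_threshold`` after morphological closing and hole filling; all other
    voxels are set to air.  Idempotent on already-clean volumes.  Raises a
    truncation QA flag (warning, not error) when the body outline looks cut
    off by the field of view.
    """
    fg = volume.data > air_threshold
    if not fg.any():
        raise ValueError(f"no voxels above the air threshold {air_threshold} HU")
    r_vox = max(1, int(round(closing_radius_mm / min(volume.spacing))))
    # edge-replicate so closing does not erode anatomy that runs off the grid
    fg = np.pad(fg, r_vox, mode="edge")
    fg = ndimage.binary_closing(fg, structure=ball(r_vox))
    fg = fg[r_vox:-r_vox, r_vox:-r_vox, r_vox:-r_vox]
    labels, n = ndimage.label(fg)
    if n == 0:
        raise ValueError("no connected component found above the air threshold")
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    body = labels == (1 + int(np.argmax(sizes)))
    body = ndimage.binary_fill_holes(body)
    flags = _truncation_flag(body)
    out = np.where(body, volume.data, AIR_HU)
    return (
        volume.with_data(out),
        StructureMask(body, volume.spacing, volume.origin, name="body"),
        flags,
    )


def build_hu_lut(
    source: ImageVolume,
    reference: ImageVolume,
    source_body: StructureMask,
    reference_body: StructureMask,
    n_bins: int = 256,
) -> HistogramLUT:
    """Histogram-match the source HU distribution to the reference's.

    Classical quantile mapping restricted to body voxels (air and residual
    couch would otherwise dominate the histograms): the HU at each source
    quantile maps to the reference HU at the same quantile.
    """
    if n_bins < 64:
        raise ValueError("n_bins must be >= 64")
    s = source.data[source_body.data]
    r = reference.data[reference_body.data]
    if s.size == 0 or r.size == 0:
        raise ValueError("empty body mask")
    q = np.linspace(0.0, 1.0, n_bins + 1)
    src_q = np.quantile(s, q)
    ref_q = np.quantile(r, q)
    # collapse duplicate source knots (flat histogram regions)
    keep = np.concatenate(([True], np.diff(src_q) > 1e-9))
    src_q, ref_q = src_q[keep], ref_q[keep]
    ref_q = np.maximum.accumulate(ref_q)  # enforce monotone mapping
    # extend to the full HU domain with identity-slope tails
    lo_pad = src_q[0] - HU_MIN
    hi_pad = HU_MAX - src_q[-1]
    src = np.concatenate(([HU_MIN], src_q, [HU_MAX]))
    mapped = np.concatenate(([ref_q[0] - lo_pad], ref_q, [ref_q[-1] + hi_pad]))
    return HistogramLUT(src, np.maximum.accumulate(mapped))


def apply_lut(volume: ImageVolume, lut: HistogramLUT) -> ImageVolume:
    """Apply a monotone HU LUT voxel-wise with linear interpolation."""
    out = np.interp(volume.data, lut.source_hu, lut.mapped_hu)
    return volume.with_data(out)


def _ncc(a: np.ndarray, b: np.ndarray, mask: np.ndarray) -> float:
    x = a[mask]
    y = b[mask]
    x = x - x.mean()
    y = y - y.mean()
    d = np.sqrt((x**2).sum() * (y**2).sum())
    return float((x * y).sum() / d) if d > 0 else 0.0


def _shift_volume(data: np.ndarray, shift_vox: np.ndarray) -> np.ndarray:
    if np.allclose(shift_vox, np.round(shift_vox)):
        out = np.full_like(data, AIR_HU)
        src = [slice(None)] * 3
        dst = [slice(None)] * 3
        for a, s in enumerate(np.round(shift_vox).astype(int)):
            n = data.shape[a]
            if abs(s) >= n:
                return out
            if s >= 0:
                dst[a], src[a] = slice(s, n), slice(0, n - s)
            else:
                dst[a], src[a] = slice(0, n + s), slice(-s, n)
        out[tuple(dst)] = data[tuple(src)]
        return out
    return ndimage.shift(data, shift_vox, order=1, mode="constant", cval=AIR_HU)


def rigid_align(
    moving: ImageVolume,
    fixed: ImageVolume,
    moving_body: StructureMask,
    fixed_body: StructureMask,
    search_mm: float = 10.0,
    coarse_step_mm: float = 2.0,
    fine_step_mm: float = 0.5,
) -> tuple[ImageVolume, tuple[float, float, float]]:
    """Translation-only rigid registration of ``moving`` onto ``fixed``.

    Initialized at the body-centroid difference, then refined by exhaustive
    normalized-cross-correlation search (+-``search_mm`` at the coarse step,
    then a local pass at the fine step) over the union of the body masks.
    Returns the trilinearly resampled moving volume and the translation (mm,
    amount the moving volume was shifted).  Rotation is assumed negligible
    for supine thorax scans.
    """
    if moving.shape != fixed.shape:
        raise ValueError("rigid_align expects volumes on a common grid")
    sp = np.asarray(fixed.spacing)
    c_mov = np.array(ndimage.center_of_mass(moving_body.data))
    c_fix = np.array(ndimage.center_of_mass(fixed_body.data))
    init_vox = c_fix - c_mov  # shift moving so its centroid lands on fixed's

    region = fixed_body.data | moving_body.data
    best = (-np.inf, np.zeros(3))

    def search(center_vox, radius_mm, step_mm):
        nonlocal best
        steps = np.arange(-radius_mm, radius_mm + 0.5 * step_mm, step_mm)
        for off in itertools.product(steps, steps, steps):
            shift_vox = center_vox + np.asarray(off) / sp
            cand = _shift_volume(moving.data, shift_vox)
            score = _ncc(cand, fixed.data, region)
            if score > best[0]:
                best = (score, shift_vox)

    search(np.round(init_vox), search_mm, coarse_step_mm)
    coarse_best = best[1].copy()
    search(coarse_best, 0.75 * coarse_step_mm, fine_step_mm)
    if np.any(np.abs((best[1] - np.round(init_vox)) * sp) >= search_mm - 1e-9):
        import warnings

        warnings.warn(
            "rigid_align hit the search boundary; possible gross misalignment",
            stacklevel=2,
        )
    shift_vox = best[1]
    aligned = moving.with_data(_shift_volume(moving.data, shift_vox))
    translation = tuple(float(v) for v in shift_vox * sp)
    return aligned, translation


def resample(
    volume: ImageVolume | StructureMask,
    target_shape: tuple[int, int, int] = (128, 128, 64),
) -> ImageVolume | StructureMask:
    """Resample onto ``target_shape`` preserving the physical extent.

    Trilinear for images (nearest-neighbour for masks); the spacing is
    rescaled so shape x spacing is unchanged, with voxel centers mapped
    center-to-center.
    """
    if any(n <= 0 for n in target_shape):
        raise ValueError("target shape must be positive")
    src_shape = np.asarray(volume.shape, dtype=np.float64)
    tgt_shape = np.asarray(target_shape, dtype=np.float64)
    if tuple(volume.shape) == tuple(target_shape):
        return volume
    scale = src_shape / tgt_shape
    idx = np.indices(tuple(target_shape), dtype=np.float64)
    coords = [(idx[a] + 0.5) * scale[a] - 0.5 for a in range(3)]
    new_spacing = tuple(s * sc for s, sc in zip(volume.spacing, scale))
    is_mask = isinstance(volume, StructureMask)
    order = 0 if is_mask else 1
    data = ndimage.map_coordinates(
        volume.data.astype(np.float64), coords, order=order, mode="nearest"
    )
    # keep the grid centered on the same world extent
    new_origin = tuple(
        o + 0.5 * (ns - s) for o, s, ns in zip(volume.origin, volume.spacing, new_spacing)
    )
    if is_mask:
        return StructureMask(data > 0.5, new_spacing, new_origin, name=volume.name)
    return ImageVolume(data, new_spacing, new_origin)


def augment(
    volume: ImageVolume | StructureMask, op: str
) -> ImageVolume | StructureMask:
    """Training augmentation: in-plane 45-degree clockwise rotation or
    horizontal (left-right) flip.

    Rotation is about the axial-slice center in the viewer frame, padding
    with air; apply the same op to both members of a (dCT, pCT) pair and to
    their masks (masks rotate nearest-neighbour, staying binary).
    """
    is_mask = isinstance(volume, StructureMask)
    if op == "hflip":
        return volume.with_data(volume.data[::-1].copy())
    if op == "rot45cw":
        order = 0 if is_mask else 1
        cval = 0 if is_mask else AIR_HU
        data = ndimage.rotate(
            volume.data.astype(float),
            angle=-45.0,
            axes=(0, 1),
            reshape=False,
            order=order,
            mode="constant",
            cval=cval,
        )
        return volume.with_data(data > 0.5 if is_mask else data)
    raise ValueError(f"unknown augmentation op {op!r}")
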