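"""Synthetic thorax phantoms: paired diagnostic/planning CTs with ground truth.

Patient CT pairs for this workflow are not publicly deposited, so this module
generates geometric thorax phantoms that emulate the features the pipeline
must cope with: a body of soft tissue with fat/muscle layers, two lungs, a
heart, an esophagus, a spine, and a target lesion (CTV) in the upper lung;
a curved diagnostic-scanner bed vs a flat treatment couch; protocol HU
offsets between scanners; contrast enhancement present only at diagnosis;
field-of-view truncation; smooth anatomical deformation between the two
scans; and photon-like vs proton-like dose fields whose organ-at-risk
ordering is controllable, giving ground-truth signs for modality selection.

Every generator is a pure function of its spec (including the seed):
identical inputs give bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .grids import DisplacementField, DoseVolume, ImageVolume, StructureMask
from .warping import invert_dvf, warp

__all__ = [
    "PhantomSpec",
    "DeformationSpec",
    "DoseSpec",
    "SyntheticCase",
    "make_thorax_phantom",
    "add_couch",
    "make_smooth_dvf",
    "make_dose",
    "add_contrast",
    "truncate_fov",
    "synthesize_case",
]

AIR_HU = -1000.0


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, tissue HU assignments and acquisition quirks of one phantom."""

    grid_shape: tuple[int, int, int] = (64, 64, 32)
    spacing_mm: tuple[float, float, float] = (5.0, 5.0, 5.0)
    # organ geometry, mm
    body_radii_mm: tuple[float, float] = (130.0, 90.0)
    lung_radii_mm: tuple[float, float, float] = (42.0, 52.0, 70.0)
    heart_radius_mm: float = 38.0
    esophagus_radius_mm: float = 7.0
    spine_radius_mm: float = 14.0
    ctv_radius_mm: float = 16.0
    # HU assignments (all within the scanner range [-1024, 3071])
    hu: dict = field(
        default_factory=lambda: {
            "air": -1000.0,
            "lung": -700.0,
            "soft": 20.0,
            "muscle": 40.0,
            "fat": -90.0,
            "bone": 400.0,
            "contrast": 240.0,
            "couch": 200.0,
            "ctv": 30.0,
        }
    )
    couch_kind: str = "none"  # "curved" | "flat" | "none"
    contrast_enabled: bool = False
    truncation_fraction: float = 0.0
    hu_offset: float = 0.0  # global protocol shift applied inside the body
    noise_sigma: float = 5.0
    random_seed: int = 0

    @classmethod
    def scaled_to(cls, grid_shape, spacing_mm, **overrides) -> "PhantomSpec":
        """Default anatomy proportionally rescaled to another field of view.

        The default organ radii are tuned to the default 320x320x160 mm FOV;
        this keeps the same anatomy-to-FOV proportions on any grid.
        """
        ref = cls()
        fov_ref = [n * s for n, s in zip(ref.grid_shape, ref.spacing_mm)]
        fov_new = [n * s for n, s in zip(grid_shape, spacing_mm)]
        fx, fy, fz = (a / b for a, b in zip(fov_new, fov_ref))
        fmin = min(fx, fy, fz)
        fields = dict(
            grid_shape=tuple(grid_shape),
            spacing_mm=tuple(spacing_mm),
            body_radii_mm=(ref.body_radii_mm[0] * fx, ref.body_radii_mm[1] * fy),
            lung_radii_mm=(
                ref.lung_radii_mm[0] * fx,
                ref.lung_radii_mm[1] * fy,
                ref.lung_radii_mm[2] * fz,
            ),
            heart_radius_mm=ref.heart_radius_mm * fmin,
            esophagus_radius_mm=ref.esophagus_radius_mm * fmin,
            spine_radius_mm=ref.spine_radius_mm * fmin,
            ctv_radius_mm=ref.ctv_radius_mm * fmin,
        )
        fields.update(overrides)
        return cls(**fields)

    def validate(self) -> None:
        if any(s <= 0 for s in self.grid_shape) or any(s <= 0 for s in self.spacing_mm):
            raise ValueError("grid shape and spacing must be positive")
        if self.couch_kind not in ("curved", "flat", "none"):
            raise ValueError(f"unknown couch kind {self.couch_kind!r}")
        if not 0.0 <= self.truncation_fraction <= 0.3:
            raise ValueError("truncation_fraction must lie in [0, 0.3]")
        for k, v in self.hu.items():
            if not -1024.0 <= v <= 3071.0:
                raise ValueError(f"HU for {k!r} outside [-1024, 3071]: {v}")
        radii = {
            "lung": max(self.lung_radii_mm),
            "heart": self.heart_radius_mm,
            "esophagus": self.esophagus_radius_mm,
            "spine": self.spine_radius_mm,
            "ctv": self.ctv_radius_mm,
        }
        for name, r in radii.items():
            if r <= 0:
                raise ValueError(f"{name} radius must be positive")


@dataclass(frozen=True)
class DeformationSpec:
    """Sum-of-Gaussian-blobs displacement: smooth and invertible by design."""

    n_blobs: int = 4
    amplitude_mm: tuple[float, float] = (3.0, 8.0)
    width_mm: tuple[float, float] = (30.0, 60.0)
    random_seed: int = 0

    def validate(self) -> None:
        if self.n_blobs < 0:
            raise ValueError("n_blobs must be non-negative")
        if self.amplitude_mm[1] >= self.width_mm[0]:
            raise ValueError(
                "max amplitude must stay below min blob width (folding risk): "
                f"{self.amplitude_mm[1]} >= {self.width_mm[0]}"
            )


@dataclass(frozen=True)
class DoseSpec:
    """Geometric dose model: prescription inside the target, falloff outside.

    Not a physics model -- a controllable stand-in for planned photon (broad
    falloff plus entrance dose along the beam axis) and proton (sharp falloff,
    zero beyond the distal edge) dose distributions.
    """

    modality: str = "photon"  # "photon" | "proton"
    prescription_gy: float = 60.0
    target: str = "ctv"
    falloff_mm: float = 28.0  # lateral/proximal exponential length
    distal_margin_mm: float = 15.0  # proton: dose is zero beyond this distal margin
    entrance_fraction: float = 0.35  # photon: entrance-channel dose as fraction of Rx

    def validate(self) -> None:
        if self.modality not in ("photon", "proton"):
            raise ValueError(f"unknown modality {self.modality!r}")
        if self.prescription_gy < 0:
            raise ValueError("prescription must be non-negative")
        if not 0.0 <= self.entrance_fraction <= 1.0:
            raise ValueError("entrance fraction must lie in [0, 1]")
        if self.falloff_mm <= 0 or self.distal_margin_mm < 0:
            raise ValueError("falloff/margin must be positive")


PHOTON_DEFAULT = DoseSpec(modality="photon", falloff_mm=28.0, entrance_fraction=0.35)
PROTON_DEFAULT = DoseSpec(
    modality="proton", falloff_mm=9.0, distal_margin_mm=15.0, entrance_fraction=0.0
)


def _world_grids(spec: PhantomSpec):
    nx, ny, nz = spec.grid_shape
    sx, sy, sz = spec.spacing_mm
    x = (np.arange(nx) - (nx - 1) / 2.0) * sx
    y = (np.arange(ny) - (ny - 1) / 2.0) * sy
    z = (np.arange(nz) - (nz - 1) / 2.0) * sz
    return np.meshgrid(x, y, z, indexing="ij")


def make_thorax_phantom(
    spec: PhantomSpec,
) -> tuple[ImageVolume, dict[str, StructureMask]]:
    """Build the HU volume and the named ground-truth masks for one phantom.

    Returned masks: body, lung_left, lung_right, total_lung, heart,
    esophagus, spine, ctv, vessel, and couch when a couch is requested.
    Organ masks are subsets of the body; the couch is disjoint from it.
    """
    spec.validate()
    X, Y, Z = _world_grids(spec)
    rx, ry = spec.body_radii_mm
    lx, ly, lz = spec.lung_radii_mm
    hu = spec.hu

    body_r2 = (X / rx) ** 2 + (Y / ry) ** 2
    body = body_r2 <= 1.0

    vol = np.full(spec.grid_shape, hu["air"], dtype=np.float64)
    vol[body] = hu["soft"]
    vol[(body_r2 > 0.72) & body] = hu["muscle"]
    vol[(body_r2 > 0.85) & body] = hu["fat"]

    def ellipsoid(cx, cy, cz, ax, ay, az):
        return ((X - cx) / ax) ** 2 + ((Y - cy) / ay) ** 2 + ((Z - cz) / az) ** 2 <= 1.0

    lung_l = ellipsoid(-0.45 * rx, -0.08 * ry, 0.0, lx, ly, lz)
    lung_r = ellipsoid(+0.45 * rx, -0.08 * ry, 0.0, lx, ly, lz)
    heart = ellipsoid(-0.10 * rx, 0.02 * ry, -0.25 * lz, *(spec.heart_radius_mm,) * 3)
    spine = (X**2 + (Y - 0.62 * ry) ** 2) <= spec.spine_radius_mm**2
    eso = (X**2 + (Y - 0.38 * ry) ** 2) <= spec.esophagus_radius_mm**2
    # target lesion in the upper (superior) part of the right lung
    ctv = ellipsoid(+0.45 * rx, -0.08 * ry, 0.55 * lz, *(spec.ctv_radius_mm,) * 3)
    # contrast-enhanced vessel (aortic arch stand-in) near the heart
    vessel = ((X + 0.05 * rx) ** 2 + (Y - 0.18 * ry) ** 2) <= 10.0**2
    vessel &= np.abs(Z) < 0.6 * lz

    for name, m in (
        ("lung", lung_l | lung_r),
        ("heart", heart),
        ("esophagus", eso),
        ("spine", spine),
        ("ctv", ctv),
    ):
        if (m & ~body).any():
            raise ValueError(f"organ {name!r} exceeds the body outline")

    # precedence: lesion sits inside lung; lungs carved by mediastinal organs
    ctv &= lung_l | lung_r
    lung_l &= ~(heart | spine | eso | ctv)
    lung_r &= ~(heart | spine | eso | ctv)
    vessel &= body & ~(lung_l | lung_r | spine | eso)
    if not ctv.any():
        raise ValueError("CTV does not fit inside the lung")

    vol[lung_l | lung_r] = hu["lung"]
    vol[heart] = hu["muscle"]
    vol[eso] = hu["muscle"]
    vol[spine] = hu["bone"]
    vol[ctv] = hu["ctv"]

    origin = tuple(-(n - 1) / 2.0 * s for n, s in zip(spec.grid_shape, spec.spacing_mm))
    volume = ImageVolume(vol, spec.spacing_mm, origin)
    masks = {
        "body": body,
        "lung_left": lung_l,
        "lung_right": lung_r,
        "total_lung": lung_l | lung_r,
        "heart": heart,
        "esophagus": eso,
        "spine": spine,
        "ctv": ctv,
        "vessel": vessel,
    }
    mask_objs = {
        k: StructureMask(v, spec.spacing_mm, origin, name=k) for k, v in masks.items()
    }

    if spec.hu_offset:
        volume.data[body] += spec.hu_offset
    if spec.contrast_enabled:
        volume = add_contrast(volume, mask_objs["vessel"], delta_hu=hu["contrast"] - hu["muscle"])
    if spec.couch_kind != "none":
        volume, couch = add_couch(
            volume, mask_objs["body"], kind=spec.couch_kind, couch_hu=hu["couch"]
        )
        mask_objs["couch"] = couch
    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.random_seed)
        volume = volume.with_data(
            volume.data + rng.normal(0.0, spec.noise_sigma, size=spec.grid_shape)
        )
    if spec.truncation_fraction > 0:
        volume = truncate_fov(volume, spec.truncation_fraction)
    return volume, mask_objs


def add_couch(
    volume: ImageVolume,
    body_mask: StructureMask,
    kind: str = "flat",
    couch_hu: float = 200.0,
    thickness_mm: float = 25.0,
    gap_mm: float = 20.0,
    curvature_radius_mm: float = 400.0,
) -> tuple[ImageVolume, StructureMask]:
    """Insert a treatment couch (flat slab) or scanner bed (curved shell).

    The couch sits posterior to the body (+y) with a small air gap; the
    curved kind follows an arc so lateral columns start more posterior.
    The body itself is not modified -- anatomical differences between the
    curved-bed and flat-couch scans are modelled by the deformation field of
    ``synthesize_case``, not here.
    """
    if kind not in ("flat", "curved"):
        raise ValueError(f"unknown couch kind {kind!r}")
    if not body_mask.same_grid(volume):
        raise ValueError("body mask grid does not match volume grid")
    nx, ny, nz = volume.shape
    sx, sy, sz = volume.spacing
    body = body_mask.data
    # posterior-most body voxel per x column (over all z)
    any_body = body.any(axis=(1, 2))
    if not any_body.any():
        raise ValueError("empty body mask")
    y_max = np.where(any_body, ny - 1 - np.argmax(body[:, ::-1, :].any(axis=2), axis=1), -1)
    # ceil: guarantee at least gap_mm of air between body and couch at any
    # spacing (couch removal's morphological closing must not weld them)
    y0 = int(y_max[any_body].max()) + 1 + max(1, int(np.ceil(gap_mm / sy)))
    thick = max(1, int(round(thickness_mm / sy)))
    x_c = (nx - 1) / 2.0
    couch = np.zeros(volume.shape, dtype=bool)
    xs = np.where(any_body)[0]
    for i in range(xs.min(), xs.max() + 1):
        sag = 0.0
        if kind == "curved":
            dx_mm = (i - x_c) * sx
            sag = (dx_mm**2) / (2.0 * curvature_radius_mm)
        start = y0 + int(round(sag / sy))
        if start >= ny:
            continue
        couch[i, start : min(ny, start + thick), :] = True
    if (couch & body).any():
        raise ValueError("couch would overlap the body interior")
    out = volume.data.copy()
    out[couch] = couch_hu
    return volume.with_data(out), StructureMask(
        couch, volume.spacing, volume.origin, name="couch"
    )


def make_smooth_dvf(spec: DeformationSpec, grid) -> DisplacementField:
    """Sum of Gaussian-windowed displacement blobs on the grid of ``grid``.

    Smooth by construction; with every blob amplitude below the smallest
    blob width the deformation is diffeomorphic (positive Jacobian).  The
    field magnitude is capped at the spec's maximum amplitude.
    """
    spec.validate()
    if isinstance(grid, (ImageVolume, StructureMask)):
        shape, spacing, origin = grid.shape, grid.spacing, grid.origin
    else:
        shape, spacing, origin = tuple(grid), (1.0, 1.0, 1.0), (0.0, 0.0, 0.0)
    if any(n <= 0 for n in shape):
        raise ValueError("grid dimensions must be positive")
    rng = np.random.default_rng(spec.random_seed)
    u = np.zeros((3, *shape), dtype=np.float64)
    idx = np.indices(shape, dtype=np.float64)
    coords_mm = [idx[a] * spacing[a] for a in range(3)]
    extent = [(n - 1) * s for n, s in zip(shape, spacing)]
    for _ in range(spec.n_blobs):
        center = rng.uniform(0.2, 0.8, size=3) * extent
        width = rng.uniform(*spec.width_mm)
        amp = rng.uniform(*spec.amplitude_mm)
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        r2 = sum((coords_mm[a] - center[a]) ** 2 for a in range(3))
        g = np.exp(-r2 / (2.0 * width**2))
        for a in range(3):
            u[a] += amp * direction[a] * g
    mag = np.sqrt((u**2).sum(axis=0))
    peak = mag.max()
    if peak > spec.amplitude_mm[1] > 0:
        u *= spec.amplitude_mm[1] / peak
    return DisplacementField(u, spacing, origin)


def make_dose(
    masks: dict[str, StructureMask], spec: DoseSpec, body: str = "body"
) -> DoseVolume:
    """Geometric dose field: prescription in the target, modality-shaped falloff.

    Photon: broad exponential falloff with distance from the target plus an
    entrance channel along the anterior beam axis (-y).  Proton: sharp
    exponential falloff, cut to zero beyond the distal margin (the target's
    posterior edge plus ``distal_margin_mm`` along +y), emulating the finite
    particle range.  Dose is zero outside the body.
    """
    spec.validate()
    if spec.target not in masks:
        raise KeyError(f"target mask {spec.target!r} not found")
    target = masks[spec.target]
    if not target.data.any():
        raise ValueError("empty target mask")
    sp = target.spacing
    P = spec.prescription_gy
    if P == 0.0:
        return DoseVolume(np.zeros(target.shape), sp, target.origin)

    dist = ndimage.distance_transform_edt(~target.data, sampling=sp)
    dose = P * np.exp(-dist / spec.falloff_mm)

    if spec.modality == "photon" and spec.entrance_fraction > 0:
        # entrance channel: anterior of the target, within its x-z shadow
        shadow = target.data.any(axis=1)  # (nx, nz)
        sh_dist = ndimage.distance_transform_edt(~shadow, sampling=(sp[0], sp[2]))
        lateral = np.exp(-sh_dist / spec.falloff_mm)[:, None, :]
        y_idx = np.arange(target.shape[1])[None, :, None]
        y_front = np.where(
            target.data.any(axis=(0, 2)).any(), np.argmax(target.data.any(axis=(0, 2))), 0
        )
        entrance = spec.entrance_fraction * P * lateral * (y_idx <= y_front)
        dose = np.maximum(dose, np.broadcast_to(entrance, dose.shape))
    if spec.modality == "proton":
        # no dose beyond the distal (posterior) edge of the target + margin
        y_back = np.max(np.nonzero(target.data.any(axis=(0, 2)))[0])
        cut = y_back + int(round(spec.distal_margin_mm / sp[1]))
        y_idx = np.arange(target.shape[1])[None, :, None]
        dose = np.where(y_idx > cut, 0.0, dose)

    dose[target.data] = P
    if body in masks:
        dose = np.where(masks[body].data, dose, 0.0)
    return DoseVolume(dose, sp, target.origin)


def add_contrast(
    volume: ImageVolume, vessel_mask: StructureMask, delta_hu: float = 200.0
) -> ImageVolume:
    """Raise HU inside the vessel mask, emulating IV contrast at diagnosis."""
    if not vessel_mask.same_grid(volume):
        raise ValueError("vessel mask grid does not match volume grid")
    out = volume.data.copy()
    out[vessel_mask.data] += delta_hu
    return volume.with_data(out)


def truncate_fov(volume: ImageVolume, fraction: float) -> ImageVolume:
    """Replace the outer lateral fraction of every slice with air.

    ``fraction`` of the lateral field of view is removed from each side,
    producing the cut-off failure mode that must trip preprocessing QA.
    """
    if not 0.0 <= fraction <= 0.3:
        raise ValueError("truncation fraction must lie in [0, 0.3]")
    if fraction == 0.0:
        return volume
    nx = volume.shape[0]
    cut = int(round(fraction * nx))
    if cut == 0:
        return volume
    out = volume.data.copy()
    out[:cut] = AIR_HU
    out[nx - cut :] = AIR_HU
    return volume.with_data(out)


@dataclass
class SyntheticCase:
    """One complete synthetic patient: pCT, dCT, masks, and ground truth."""

    pct: ImageVolume
    dct: ImageVolume
    masks_pct: dict[str, StructureMask]
    masks_dct: dict[str, StructureMask]
    true_dvf: DisplacementField  # field mapping dCT geometry onto pCT geometry
    dose: dict[str, DoseVolume] = field(default_factory=dict)  # "photon"/"proton" on pCT
    name: str = "case"


def synthesize_case(
    spec: PhantomSpec | None = None,
    deform: DeformationSpec | None = None,
    seed: int = 0,
    photon: DoseSpec | None = None,
    proton: DoseSpec | None = None,
    name: str = "case",
) -> SyntheticCase:
    """Generate a paired dCT/pCT case with ground-truth deformation and doses.

    The planning CT is the base phantom on a flat couch; the diagnostic CT is
    the same anatomy backward-warped by a smooth random field, with a curved
    bed, a protocol HU offset, and contrast in the vessel.  ``true_dvf`` is
    the (numerically inverted) field a perfect registration network would
    predict to map the diagnostic anatomy back onto the planning anatomy.
    """
    base = spec or PhantomSpec()
    base = replace(base, couch_kind="none", noise_sigma=0.0, random_seed=seed)
    clean, masks = make_thorax_phantom(base)

    dspec = deform or DeformationSpec(random_seed=seed + 1)
    g = make_smooth_dvf(dspec, clean)
    dct_clean = warp(clean, g, interpolation="trilinear")
    masks_dct = {k: warp(m, g, interpolation="nearest") for k, m in masks.items()}

    rng = np.random.default_rng(seed + 2)
    noise_sigma = (spec or PhantomSpec()).noise_sigma

    # planning CT: flat treatment couch + noise
    pct, couch_p = add_couch(clean, masks["body"], kind="flat", couch_hu=base.hu["couch"])
    masks_p = dict(masks)
    masks_p["couch"] = couch_p
    if noise_sigma > 0:
        pct = pct.with_data(pct.data + rng.normal(0.0, noise_sigma, size=pct.shape))

    # diagnostic CT: deformed anatomy, protocol HU shift, contrast, curved bed
    d = dct_clean.with_data(dct_clean.data.copy())
    d.data[masks_dct["body"].data] += 30.0
    d = add_contrast(d, masks_dct["vessel"], delta_hu=base.hu["contrast"] - base.hu["muscle"])
    d, couch_d = add_couch(d, masks_dct["body"], kind="curved", couch_hu=base.hu["couch"])
    masks_d = dict(masks_dct)
    masks_d["couch"] = couch_d
    if noise_sigma > 0:
        d = d.with_data(d.data + rng.normal(0.0, noise_sigma, size=d.shape))

    case = SyntheticCase(
        pct=pct,
        dct=d,
        masks_pct=masks_p,
        masks_dct=masks_d,
        true_dvf=invert_dvf(g),
        name=name,
    )
    ph = photon or PHOTON_DEFAULT
    pr = proton or PROTON_DEFAULT
    case.dose = {"photon": make_dose(masks_p, ph), "proton": make_dose(masks_p, pr)}
    return case
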