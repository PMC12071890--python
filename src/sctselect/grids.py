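"""Grid-aligned volume containers and NIfTI round-tripping.

Every object in the pipeline (CT volume in HU, binary structure mask, dose
grid in Gy, displacement field in mm) lives on a regular 3D grid described by
a voxel ``spacing`` (mm) and a world-space ``origin`` (mm).  Arrays are
indexed ``[i, j, k]`` with world coordinate ``origin + index * spacing``;
axis 0/1 are the axial in-plane axes (axis 1 points anterior -> posterior)
and axis 2 is superior-inferior.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = [
    "ImageVolume",
    "StructureMask",
    "DoseVolume",
    "DisplacementField",
    "load_volume",
    "load_mask",
    "load_dvf",
]


def _as_triple(x) -> tuple[float, float, float]:
    t = tuple(float(v) for v in np.broadcast_to(x, (3,)))
    return t  # type: ignore[return-value]


@dataclass
class ImageVolume:
    """A scalar 3D grid (HU for CT, Gy for dose)."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"volume must be 3D, got shape {self.data.shape}")
        self.spacing = _as_triple(self.spacing)
        self.origin = _as_triple(self.origin)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_volume_cc(self) -> float:
        sx, sy, sz = self.spacing
        return sx * sy * sz / 1000.0

    def same_grid(self, other: "ImageVolume | StructureMask") -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing)
            and np.allclose(self.origin, other.origin)
        )

    def with_data(self, data: np.ndarray) -> "ImageVolume":
        return replace(self, data=data)

    def affine(self) -> np.ndarray:
        aff = np.diag(list(self.spacing) + [1.0])
        aff[:3, 3] = self.origin
        return aff

    def save(self, path: str | Path) -> None:
        img = nib.Nifti1Image(np.asarray(self.data, dtype=np.float32), self.affine())
        nib.save(img, str(path))


# A dose grid is structurally an ImageVolume whose data are Gy.
DoseVolume = ImageVolume


@dataclass
class StructureMask:
    """A binary organ/target mask on the same grid convention as ImageVolume."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    name: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)
        if self.data.ndim != 3:
            raise ValueError(f"mask must be 3D, got shape {self.data.shape}")
        self.spacing = _as_triple(self.spacing)
        self.origin = _as_triple(self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_count(self) -> int:
        return int(self.data.sum())

    @property
    def volume_cc(self) -> float:
        sx, sy, sz = self.spacing
        return self.voxel_count * sx * sy * sz / 1000.0

    def same_grid(self, other) -> bool:
        return ImageVolume.same_grid(self, other)  # type: ignore[arg-type]

    def with_data(self, data: np.ndarray) -> "StructureMask":
        return replace(self, data=data)

    def save(self, path: str | Path) -> None:
        aff = np.diag(list(self.spacing) + [1.0])
        aff[:3, 3] = self.origin
        nib.save(nib.Nifti1Image(self.data.astype(np.uint8), aff), str(path))


@dataclass
class DisplacementField:
    """Per-voxel 3-vector displacement in mm, component-first: shape (3, nx, ny, nz).

    Displacements are stored in millimetres (not voxels) so a field survives
    resampling to another grid; the warp operator converts to voxel units
    using the grid spacing.
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 4 or self.data.shape[0] != 3:
            raise ValueError(
                f"displacement field must have shape (3, nx, ny, nz), got {self.data.shape}"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValueError("displacement field contains non-finite values")
        self.spacing = _as_triple(self.spacing)
        self.origin = _as_triple(self.origin)

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.data.shape[1:]  # type: ignore[return-value]

    def magnitude(self) -> np.ndarray:
        return np.sqrt((self.data**2).sum(axis=0))

    def save(self, path: str | Path) -> None:
        aff = np.diag(list(self.spacing) + [1.0])
        aff[:3, 3] = self.origin
        # stored as 4D NIfTI, last axis = vector component
        arr = np.moveaxis(self.data, 0, -1).astype(np.float32)
        nib.save(nib.Nifti1Image(arr, aff), str(path))


def _grid_from_nifti(img) -> tuple[np.ndarray, tuple, tuple]:
    aff = img.affine
    spacing = tuple(float(v) for v in np.abs(np.diag(aff)[:3]))
    origin = tuple(float(v) for v in aff[:3, 3])
    return np.asanyarray(img.dataobj), spacing, origin


def load_volume(path: str | Path) -> ImageVolume:
    data, spacing, origin = _grid_from_nifti(nib.load(str(path)))
    return ImageVolume(np.asarray(data, dtype=np.float64), spacing, origin)


def load_mask(path: str | Path, name: str = "") -> StructureMask:
    data, spacing, origin = _grid_from_nifti(nib.load(str(path)))
    stem = Path(path).name.removesuffix(".gz").removesuffix(".nii")
    return StructureMask(data > 0.5, spacing, origin, name=name or stem)


def load_dvf(path: str | Path) -> DisplacementField:
    data, spacing, origin = _grid_from_nifti(nib.load(str(path)))
    if data.ndim != 4 or data.shape[-1] != 3:
        raise ValueError(f"expected 4D NIfTI with 3 components, got shape {data.shape}")
    return DisplacementField(np.moveaxis(np.asarray(data, np.float64), -1, 0), spacing, origin)
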