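"""In-memory volume containers and NIfTI round-trip I/O.

A volume is an axis-aligned 3D scalar grid with per-axis voxel spacing in
millimetres and a world-space origin.  Voxel indices are 0-based and the
world position of voxel ``(i, j, k)`` is ``origin + index * spacing``; no
direction-cosine handling beyond axis-aligned grids is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = [
    "ImageVolume",
    "SegmentationMask",
    "read_volume",
    "write_volume",
    "read_mask",
    "write_mask",
    "check_aligned",
    "require_aligned",
]

#: geometric comparison tolerance for spacing/origin, in mm
GEOM_TOL_MM = 1e-6


@dataclass
class ImageVolume:
    """3D scalar image with voxel spacing (mm) and origin (mm)."""

    voxels: np.ndarray
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError(
                f"expected a 3D grid, got {self.voxels.ndim} dimensions"
            )
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        self.origin_mm = tuple(float(o) for o in self.origin_mm)
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"spacing must be positive, got {self.spacing_mm}")
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("image contains non-finite intensities")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    def copy(self) -> "ImageVolume":
        return ImageVolume(self.voxels.copy(), self.spacing_mm, self.origin_mm)


@dataclass
class SegmentationMask:
    """Binary 3D mask aligned to an :class:`ImageVolume`."""

    voxels: np.ndarray
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        arr = np.asarray(self.voxels)
        if arr.ndim != 3:
            raise ValueError(f"expected a 3D mask, got {arr.ndim} dimensions")
        uniq = np.unique(arr)
        if not np.all(np.isin(uniq, (0, 1))):
            raise ValueError("mask values must be 0 or 1")
        self.voxels = arr.astype(bool)
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        self.origin_mm = tuple(float(o) for o in self.origin_mm)
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"spacing must be positive, got {self.spacing_mm}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def n_foreground(self) -> int:
        return int(self.voxels.sum())

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing_mm))

    def copy(self) -> "SegmentationMask":
        return SegmentationMask(self.voxels.copy(), self.spacing_mm, self.origin_mm)


def _affine(spacing_mm, origin_mm) -> np.ndarray:
    aff = np.diag(list(spacing_mm) + [1.0])
    aff[:3, 3] = origin_mm
    return aff


def _load_geometry(img: nib.Nifti1Image, path) -> tuple[np.ndarray, tuple, tuple]:
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected 3D data, found {data.ndim} dimensions")
    zooms = img.header.get_zooms()[:3]
    origin = tuple(float(v) for v in img.affine[:3, 3])
    return data, tuple(float(z) for z in zooms), origin


def read_volume(path: str | Path) -> ImageVolume:
    """Read a 3D NIfTI image; raises on missing/malformed/non-3D input."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such volume: {path}")
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several parse error types
        raise ValueError(f"cannot parse NIfTI file {path}: {exc}") from exc
    data, spacing, origin = _load_geometry(img, path)
    return ImageVolume(data.astype(np.float32), spacing, origin)


def write_volume(vol: ImageVolume, path: str | Path) -> None:
    """Write an image as 32-bit float NIfTI, preserving spacing and origin."""
    img = nib.Nifti1Image(
        vol.voxels.astype(np.float32), _affine(vol.spacing_mm, vol.origin_mm)
    )
    img.header.set_zooms(vol.spacing_mm)
    nib.save(img, str(path))


def read_mask(path: str | Path) -> SegmentationMask:
    """Read a binary 3D NIfTI mask (any nonzero voxel is foreground)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such mask: {path}")
    try:
        img = nib.load(str(path))
    except Exception as exc:
        raise ValueError(f"cannot parse NIfTI file {path}: {exc}") from exc
    data, spacing, origin = _load_geometry(img, path)
    return SegmentationMask((data > 0).astype(np.uint8), spacing, origin)


def write_mask(mask: SegmentationMask, path: str | Path) -> None:
    """Write a mask as unsigned 8-bit NIfTI (lossless for binary data)."""
    img = nib.Nifti1Image(
        mask.voxels.astype(np.uint8), _affine(mask.spacing_mm, mask.origin_mm)
    )
    img.header.set_zooms(mask.spacing_mm)
    nib.save(img, str(path))


def check_aligned(vol, mask, tol_mm: float = GEOM_TOL_MM) -> bool:
    """True iff shape, spacing and origin match within ``tol_mm``."""
    if vol.shape != mask.shape:
        return False
    sp_ok = all(
        abs(a - b) <= tol_mm for a, b in zip(vol.spacing_mm, mask.spacing_mm)
    )
    or_ok = all(
        abs(a - b) <= tol_mm for a, b in zip(vol.origin_mm, mask.origin_mm)
    )
    return sp_ok and or_ok


def require_aligned(vol, mask) -> None:
    if not check_aligned(vol, mask):
        raise ValueError(
            "image and mask are not geometrically aligned: "
            f"shapes {vol.shape} vs {mask.shape}, "
            f"spacing {vol.spacing_mm} vs {mask.spacing_mm}, "
            f"origin {vol.origin_mm} vs {mask.origin_mm}"
        )
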