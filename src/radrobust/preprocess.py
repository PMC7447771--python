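"""Image pre-processing: normalization, resampling, discretization, wavelets.

Two normalization conventions are supported, mirroring the two feature
extraction programs whose behaviour the analysis reproduces:

* ``whole_image`` — z-score over every voxel of the volume;
* ``foreground`` — z-score with mean and standard deviation computed over
  non-background voxels only (background = air detected by Otsu
  thresholding), the transform then applied to all voxels.

Intensities are discretized with a fixed bin width; the bin width itself
may be selected automatically so as to maximize the number of ROIs whose
bin count lands in a target interval (default 16-128).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt
from scipy import ndimage
from skimage.filters import threshold_otsu

from .volumes import ImageVolume, SegmentationMask, require_aligned

__all__ = [
    "DiscretizationSpec",
    "DiscretizedROI",
    "normalize",
    "resample_isotropic",
    "select_bin_width",
    "discretize",
    "wavelet_decompose",
    "DEFAULT_BIN_WIDTH_CANDIDATES",
    "WAVELET_SUBBANDS",
]

DEFAULT_BIN_WIDTH_CANDIDATES = (0.01, 0.02, 0.05, 0.1, 0.2, 0.5, 1.0)

#: sub-band labels, L/H = low/high-pass per axis, in pywt key order
WAVELET_SUBBANDS = ("LLL", "LLH", "LHL", "LHH", "HLL", "HLH", "HHL", "HHH")


@dataclass
class DiscretizationSpec:
    """Fixed-bin-width discretization settings."""

    bin_width: float = 0.1
    target_bin_range: tuple[int, int] = (16, 128)

    def __post_init__(self) -> None:
        lo, hi = self.target_bin_range
        if self.bin_width <= 0:
            raise ValueError("bin_width must be positive")
        if lo <= 0 or hi < lo:
            raise ValueError("target_bin_range must satisfy 0 < low <= high")


@dataclass
class DiscretizedROI:
    """Integer gray levels over the ROI bounding box (0 outside the ROI)."""

    levels: np.ndarray
    n_levels: int
    bin_width: float

    def __post_init__(self) -> None:
        if self.n_levels < 1:
            raise ValueError("n_levels must be >= 1")

    @property
    def roi_mask(self) -> np.ndarray:
        return self.levels > 0

    @property
    def roi_levels(self) -> np.ndarray:
        """Flat array of in-ROI levels."""
        return self.levels[self.levels > 0]


def normalize(vol: ImageVolume, mode: str = "whole_image") -> ImageVolume:
    """Z-score an image over the whole grid or over foreground voxels only.

    ``foreground`` mode identifies air as the largest connected
    below-Otsu-threshold component, computes mean/std over the remaining
    voxels, and applies the transform everywhere.
    """
    data = vol.voxels.astype(np.float64)
    if np.ptp(data) == 0:
        raise ValueError("degenerate image: all intensities identical")
    if mode == "whole_image":
        support = np.ones(data.shape, dtype=bool)
    elif mode == "foreground":
        thr = threshold_otsu(data)
        below = data < thr
        labels, n = ndimage.label(below)
        if n == 0:
            support = np.ones(data.shape, dtype=bool)
        else:
            sizes = np.bincount(labels.ravel())
            sizes[0] = 0
            air = labels == np.argmax(sizes)
            support = ~air
    else:
        raise ValueError(f"unknown normalization mode {mode!r}")
    mu = data[support].mean()
    sd = data[support].std()
    if sd == 0:
        raise ValueError("degenerate image: zero variance over normalization support")
    return ImageVolume(
        ((data - mu) / sd).astype(np.float32), vol.spacing_mm, vol.origin_mm
    )


def _resample_grid(shape, spacing, target_mm):
    """New axis lengths covering the original extent at isotropic spacing."""
    return tuple(
        max(1, int(np.ceil(n * s / target_mm))) for n, s in zip(shape, spacing)
    )


def _map_to_old_index(new_shape, spacing, target_mm):
    # world position of new voxel k is origin + k * target; old index =
    # world / old_spacing (shared origin, axis-aligned grids)
    return [
        np.arange(n_new) * target_mm / s for n_new, s in zip(new_shape, spacing)
    ]


def resample_isotropic(
    vol: ImageVolume,
    masks: list[SegmentationMask] | None = None,
    target_mm: float = 1.0,
) -> tuple[ImageVolume, list[SegmentationMask]]:
    """Resample image (trilinear) and masks (nearest-neighbor) to an
    isotropic grid of ``target_mm`` voxels covering the original extent."""
    if target_mm <= 0:
        raise ValueError("target_mm must be positive")
    masks = masks or []
    for m in masks:
        require_aligned(vol, m)
    new_shape = _resample_grid(vol.shape, vol.spacing_mm, target_mm)
    coords1d = _map_to_old_index(new_shape, vol.spacing_mm, target_mm)
    grid = np.meshgrid(*coords1d, indexing="ij")
    coords = np.stack(grid)
    new_spacing = (target_mm,) * 3
    out_img = ndimage.map_coordinates(
        vol.voxels.astype(np.float64), coords, order=1, mode="nearest"
    )
    new_vol = ImageVolume(out_img.astype(np.float32), new_spacing, vol.origin_mm)
    new_masks = []
    for m in masks:
        out_m = ndimage.map_coordinates(
            m.voxels.astype(np.uint8), coords, order=0, mode="constant", cval=0
        )
        new_masks.append(SegmentationMask(out_m, new_spacing, m.origin_mm))
    return new_vol, new_masks


def n_bins(roi_range: float, width: float) -> int:
    """Number of occupied bins for a given ROI intensity range: ceil(range/w),
    at least 1 (a constant ROI occupies one bin)."""
    return max(1, int(np.ceil(roi_range / width)))


def select_bin_width(
    roi_ranges: list[float],
    candidates: list[float] = DEFAULT_BIN_WIDTH_CANDIDATES,
    spec: DiscretizationSpec | None = None,
) -> float:
    """Choose the candidate width that puts the most ROIs in the target
    bin-count interval; ties broken by the smallest width."""
    roi_ranges = list(roi_ranges)
    candidates = list(candidates)
    if not roi_ranges or not candidates:
        raise ValueError("roi_ranges and candidates must be nonempty")
    if any(r <= 0 for r in roi_ranges) or any(w <= 0 for w in candidates):
        raise ValueError("ranges and candidate widths must be positive")
    lo, hi = (spec or DiscretizationSpec()).target_bin_range
    best_w, best_count = None, -1
    for w in sorted(candidates):
        count = sum(1 for r in roi_ranges if lo <= n_bins(r, w) <= hi)
        if count > best_count:
            best_w, best_count = w, count
    return float(best_w)


def discretize(
    vol: ImageVolume, mask: SegmentationMask, spec: DiscretizationSpec | None = None
) -> DiscretizedROI:
    """Map ROI intensities to integer levels with fixed-width bins.

    Bin edges are anchored at integer multiples of the bin width:
    ``level(x) = floor(I(x)/w) - floor(min_ROI/w) + 1``.  The result is
    cropped to the mask's bounding box; voxels outside the ROI get level 0.
    """
    require_aligned(vol, mask)
    if mask.n_foreground == 0:
        raise ValueError("cannot discretize an empty ROI")
    spec = spec or DiscretizationSpec()
    w = spec.bin_width
    bbox = ndimage.find_objects(mask.voxels.astype(np.uint8))[0]
    roi_mask = mask.voxels[bbox]
    vals = vol.voxels[bbox].astype(np.float64)
    binned = np.floor(vals / w).astype(np.int64)
    base = int(np.floor(vals[roi_mask].min() / w))
    levels = np.where(roi_mask, binned - base + 1, 0)
    return DiscretizedROI(
        levels=levels.astype(np.int32),
        n_levels=int(levels.max()),
        bin_width=float(w),
    )


def wavelet_decompose(
    vol: ImageVolume, wavelet: str = "haar"
) -> dict[str, ImageVolume]:
    """Single-level 3D stationary (undecimated) wavelet transform.

    Returns the 8 sub-bands labelled LLL..HHH on the original grid, so the
    original segmentation masks apply unchanged.  With ``norm=True`` and an
    orthogonal wavelet the transform is energy-preserving: the input energy
    equals the sum of sub-band energies.  Odd axis lengths are handled by
    symmetric padding to even length followed by cropping.
    """
    data = vol.voxels.astype(np.float64)
    if any(n < 2 for n in data.shape):
        raise ValueError(f"every axis must have length >= 2, got {data.shape}")
    pad = [(0, n % 2) for n in data.shape]
    padded = np.pad(data, pad, mode="symmetric") if any(p[1] for p in pad) else data
    coeffs = pywt.swtn(padded, wavelet=wavelet, level=1, norm=True)[0]
    out = {}
    for key, arr in coeffs.items():
        label = key.upper().replace("A", "L").replace("D", "H")
        sub = arr[tuple(slice(0, n) for n in data.shape)]
        out[label] = ImageVolume(
            sub.astype(np.float32), vol.spacing_mm, vol.origin_mm
        )
    return {label: out[label] for label in WAVELET_SUBBANDS}
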