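"""Full per-ROI feature extraction: preprocessing chain plus all families."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..preprocess import (
    DiscretizationSpec,
    discretize,
    normalize,
    resample_isotropic,
    wavelet_decompose,
)
from ..volumes import ImageVolume, SegmentationMask, require_aligned
from .firstorder import extract_firstorder
from .manifest import INTENSITY_GROUPS, feature_names
from .shape import extract_shape
from .texture import compute_texture, texture_features

_GROUP_TO_KIND = {
    "glcm": "GLCM",
    "glrlm": "GLRLM",
    "glszm": "GLSZM",
    "ngtdm": "NGTDM",
    "gldm": "GLDM",
}


@dataclass
class ExtractionConfig:
    """Settings of the preprocessing + extraction chain.

    The processing order is normalize -> resample -> (wavelet) ->
    discretize per ROI -> features.
    """

    normalization_mode: str = "whole_image"
    resample_target_mm: float = 1.0
    resample: bool = True
    bin_width: float = 0.1
    target_bin_range: tuple[int, int] = (16, 128)
    wavelet: bool = True
    wavelet_family: str = "haar"

    def disc_spec(self) -> DiscretizationSpec:
        return DiscretizationSpec(
            bin_width=self.bin_width, target_bin_range=self.target_bin_range
        )


def _intensity_block(
    vol: ImageVolume, mask: SegmentationMask, spec: DiscretizationSpec
) -> dict[str, float]:
    out = {}
    fo = extract_firstorder(vol, mask, spec)
    out.update({f"firstorder_{k}": v for k, v in fo.items()})
    disc = discretize(vol, mask, spec)
    for group, kind in _GROUP_TO_KIND.items():
        tm = compute_texture(disc, kind)
        out.update({f"{group}_{k}": v for k, v in texture_features(tm).items()})
    return out


def extract_all(
    vol: ImageVolume,
    mask: SegmentationMask,
    config: ExtractionConfig | None = None,
) -> dict[str, float]:
    """All features for one (image, segmentation) pair.

    Returns an ordered name -> value map matching
    :func:`radrobust.features.manifest.feature_names`; undefined values are
    NaN.  Deterministic: identical inputs give bit-identical vectors.
    """
    cfg = config or ExtractionConfig()
    require_aligned(vol, mask)
    if mask.n_foreground == 0:
        raise ValueError("cannot extract features from an empty ROI")

    img = normalize(vol, cfg.normalization_mode)
    if cfg.resample:
        img, (rmask,) = resample_isotropic(img, [mask], cfg.resample_target_mm)
    else:
        rmask = mask
    if rmask.n_foreground == 0:
        raise ValueError("ROI vanished during resampling")

    spec = cfg.disc_spec()
    out: dict[str, float] = {}
    for name, val in extract_shape(rmask).items():
        out[f"original_shape_{name}"] = val
    for name, val in _intensity_block(img, rmask, spec).items():
        out[f"original_{name}"] = val
    if cfg.wavelet:
        bands = wavelet_decompose(img, wavelet=cfg.wavelet_family)
        for band, sub in bands.items():
            for name, val in _intensity_block(sub, rmask, spec).items():
                out[f"wavelet-{band}_{name}"] = val

    order = feature_names(wavelet=cfg.wavelet)
    return {k: float(out[k]) for k in order}
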