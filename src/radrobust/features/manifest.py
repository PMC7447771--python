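"""Versioned manifest of the feature names this package computes.

Feature names follow the ``<filter>_<group>_<name>`` convention with
filter ``original`` or ``wavelet-XXX`` (XXX in LLL..HHH) and group in
{shape, firstorder, glcm, glrlm, glszm, ngtdm, gldm}.  Shape features are
geometry-only and appear under the ``original`` filter exclusively.
"""

from __future__ import annotations

import json
from pathlib import Path

from ..preprocess import WAVELET_SUBBANDS
from .firstorder import FIRSTORDER_FEATURES
from .shape import SHAPE_FEATURES
from .texture import TEXTURE_FEATURE_NAMES

MANIFEST_VERSION = "1.0"

GROUP_FEATURES: dict[str, tuple[str, ...]] = {
    "shape": SHAPE_FEATURES,
    "firstorder": FIRSTORDER_FEATURES,
    "glcm": TEXTURE_FEATURE_NAMES["GLCM"],
    "glrlm": TEXTURE_FEATURE_NAMES["GLRLM"],
    "glszm": TEXTURE_FEATURE_NAMES["GLSZM"],
    "ngtdm": TEXTURE_FEATURE_NAMES["NGTDM"],
    "gldm": TEXTURE_FEATURE_NAMES["GLDM"],
}

INTENSITY_GROUPS = ("firstorder", "glcm", "glrlm", "glszm", "ngtdm", "gldm")


def feature_names(wavelet: bool = True) -> list[str]:
    """Ordered full feature-name list: unfiltered set first, then one
    intensity/texture block per wavelet sub-band."""
    names = [f"original_shape_{n}" for n in GROUP_FEATURES["shape"]]
    for group in INTENSITY_GROUPS:
        names += [f"original_{group}_{n}" for n in GROUP_FEATURES[group]]
    if wavelet:
        for band in WAVELET_SUBBANDS:
            for group in INTENSITY_GROUPS:
                names += [f"wavelet-{band}_{group}_{n}" for n in GROUP_FEATURES[group]]
    return names


def parse_feature_name(name: str) -> tuple[str, str, str]:
    """Split ``<filter>_<group>_<name>`` into its three parts."""
    filt, group, feat = name.split("_", 2)
    return filt, group, feat


def manifest_records(wavelet: bool = True) -> list[dict]:
    records = []
    for name in feature_names(wavelet=wavelet):
        filt, group, feat = parse_feature_name(name)
        records.append(
            {"name": name, "filter": filt, "group": group, "feature": feat}
        )
    return records


def write_manifest(path: str | Path, wavelet: bool = True) -> None:
    payload = {
        "version": MANIFEST_VERSION,
        "n_features": len(feature_names(wavelet=wavelet)),
        "features": manifest_records(wavelet=wavelet),
    }
    Path(path).write_text(json.dumps(payload, indent=2))
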