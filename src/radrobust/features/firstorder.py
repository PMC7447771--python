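"""First-order intensity statistics over an ROI.

Moment-based quantities use the raw (continuous) intensities; the
histogram-based quantities Entropy and Uniformity are computed on the
fixed-bin-width discretized levels, consistent with how the texture
matrices consume the image.
"""

from __future__ import annotations

import numpy as np

from ..preprocess import DiscretizationSpec, discretize
from ..volumes import ImageVolume, SegmentationMask, require_aligned

FIRSTORDER_FEATURES = (
    "Mean",
    "Median",
    "Minimum",
    "Maximum",
    "Range",
    "Variance",
    "StandardDeviation",
    "Skewness",
    "Kurtosis",
    "Energy",
    "Entropy",
    "Uniformity",
    "Percentile10",
    "Percentile90",
    "InterquartileRange",
    "MeanAbsoluteDeviation",
    "RobustMeanAbsoluteDeviation",
    "RootMeanSquared",
)


def extract_firstorder(
    vol: ImageVolume,
    mask: SegmentationMask,
    disc_spec: DiscretizationSpec | None = None,
) -> dict[str, float]:
    """First-order features with population (biased) moments.

    Skewness and kurtosis of a zero-variance ROI are reported as 0.
    """
    require_aligned(vol, mask)
    if mask.n_foreground == 0:
        raise ValueError("first-order features require a nonempty ROI")
    x = vol.voxels[mask.voxels].astype(np.float64)
    n = x.size
    mu = x.mean()
    m2 = ((x - mu) ** 2).mean()
    sd = np.sqrt(m2)
    p10, p25, p75, p90 = np.percentile(x, [10, 25, 75, 90])

    out: dict[str, float] = {
        "Mean": mu,
        "Median": float(np.median(x)),
        "Minimum": float(x.min()),
        "Maximum": float(x.max()),
        "Range": float(np.ptp(x)),
        "Variance": m2,
        "StandardDeviation": sd,
        "Energy": float((x**2).sum()),
        "Percentile10": float(p10),
        "Percentile90": float(p90),
        "InterquartileRange": float(p75 - p25),
        "MeanAbsoluteDeviation": float(np.abs(x - mu).mean()),
        "RootMeanSquared": float(np.sqrt((x**2).mean())),
    }
    if m2 > 0:
        out["Skewness"] = float(((x - mu) ** 3).mean() / sd**3)
        out["Kurtosis"] = float(((x - mu) ** 4).mean() / m2**2)
    else:
        out["Skewness"] = 0.0
        out["Kurtosis"] = 0.0

    robust = x[(x >= p10) & (x <= p90)]
    out["RobustMeanAbsoluteDeviation"] = (
        float(np.abs(robust - robust.mean()).mean()) if robust.size else 0.0
    )

    disc = discretize(vol, mask, disc_spec or DiscretizationSpec())
    counts = np.bincount(disc.roi_levels)[1:]
    p = counts[counts > 0] / counts.sum()
    out["Entropy"] = float(-(p * np.log2(p)).sum())
    out["Uniformity"] = float((p**2).sum())

    return {k: float(out[k]) for k in FIRSTORDER_FEATURES}
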