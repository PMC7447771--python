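"""Shared fixtures: small deterministic phantoms and cohorts."""

from __future__ import annotations

import numpy as np
import pytest

from radrobust import (
    CohortConfig,
    ImageVolume,
    PerturbationSpec,
    PhantomSpec,
    SegmentationMask,
    make_cohort,
    make_phantom,
)


def random_levels(rng, shape=(6, 6, 6), n_levels=4, roi_prob=0.7) -> np.ndarray:
    """Random small discretized ROI: levels 1..n_levels inside, 0 outside."""
    L = rng.integers(1, n_levels + 1, size=shape)
    roi = rng.random(shape) < roi_prob
    if not roi.any():
        roi[tuple(s // 2 for s in shape)] = True
    return (L * roi).astype(np.int32)


def random_mask(rng, shape=(10, 10, 10)) -> SegmentationMask:
    """Random nonempty blob mask."""
    m = rng.random(shape) < 0.4
    if not m.any():
        m[tuple(s // 2 for s in shape)] = True
    return SegmentationMask(m.astype(np.uint8))


@pytest.fixture(scope="session")
def small_cohort_config() -> CohortConfig:
    """Desk-scale cohort: smaller grid and lesions, default perturbations."""
    return CohortConfig(
        grid_shape=(44, 44, 44),
        easy_volume_cm3=1.6,
        challenging_volume_cm3=3.0,
        spicule_length_mm=4.0,
    )


@pytest.fixture(scope="session")
def small_cohort(small_cohort_config):
    return make_cohort(3, 2, 3, base_seed=11, config=small_cohort_config)


@pytest.fixture(scope="session")
def easy_phantom():
    spec = PhantomSpec(
        grid_shape=(40, 40, 40),
        difficulty="easy",
        radius_mm=(8.0, 8.0, 8.0),
        texture_sigma=0.15,
        noise_sigma=0.15,
        seed=7,
    )
    return make_phantom(spec)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260922)
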