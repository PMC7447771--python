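"""Synthetic tumor phantoms and simulated observer segmentations.

Emulates a cohort of contrast-enhanced breast lesions in two
segmentation-difficulty classes:

* ``easy`` — homogeneous, near-spherical lesions with sharp margins and
  low internal texture; observers disagree only mildly at the boundary.
* ``challenging`` — larger, anisotropic, spiculated lesions with strong
  internal texture; observers additionally disagree on whether individual
  spicules belong to the lesion.

The observer model composes three perturbations of the ground-truth mask,
mirroring the failure modes of manual contouring: (1) a spatially smooth
random displacement of the boundary surface, (2) a global random
over-/under-segmentation offset (morphological dilation/erosion via the
signed distance transform), and (3) random per-spicule dropout.

Everything is a pure function of its spec and seed: identical inputs give
bit-identical volumes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy import ndimage

from .volumes import (
    ImageVolume,
    SegmentationMask,
    check_aligned,
    read_mask,
    read_volume,
    write_mask,
    write_volume,
)

__all__ = [
    "PhantomSpec",
    "PerturbationSpec",
    "ObserverSet",
    "CohortConfig",
    "make_phantom",
    "simulate_observer",
    "make_cohort",
    "save_cohort",
    "load_cohort",
    "HOMOGENEOUS_TEXTURE_BOUND",
]

#: upper bound on ``texture_sigma`` for a lesion to count as homogeneous
HOMOGENEOUS_TEXTURE_BOUND = 0.35

#: correlation length (mm) of the smooth fields (texture, displacement)
_FIELD_SMOOTH_MM = 3.0

_DIFFICULTIES = ("easy", "challenging")


@dataclass
class PhantomSpec:
    """Parameters of one synthetic lesion.

    ``radius_mm`` are the ellipsoid semi-axes; ``intensity_contrast`` is the
    lesion-minus-background mean intensity in arbitrary (post-normalization
    scale) units; ``texture_sigma`` scales a smooth intra-lesion intensity
    field and ``noise_sigma`` the additive voxel noise.
    """

    grid_shape: tuple[int, int, int] = (64, 64, 64)
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    difficulty: str = "easy"
    radius_mm: tuple[float, float, float] = (10.0, 10.0, 10.0)
    n_spicules: int = 0
    spicule_length_mm: float = 5.0
    spicule_radius_mm: tuple[float, float] = (1.2, 1.8)
    intensity_contrast: float = 3.0
    rim_enhancement: float = 0.0
    texture_sigma: float = 0.1
    noise_sigma: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        self.grid_shape = tuple(int(n) for n in self.grid_shape)
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        self.radius_mm = tuple(float(r) for r in self.radius_mm)
        if self.difficulty not in _DIFFICULTIES:
            raise ValueError(f"difficulty must be one of {_DIFFICULTIES}")
        if any(s <= 0 for s in self.spacing_mm) or any(
            r <= 0 for r in self.radius_mm
        ):
            raise ValueError("spacing and radii must be positive")
        if self.spicule_length_mm <= 0:
            raise ValueError("spicule_length_mm must be positive")
        if self.texture_sigma < 0 or self.noise_sigma < 0:
            raise ValueError("sigma parameters must be non-negative")
        if self.rim_enhancement < 0:
            raise ValueError("rim_enhancement must be non-negative")
        if self.difficulty == "easy":
            if self.n_spicules != 0:
                raise ValueError("easy lesions have no spicules")
            if self.texture_sigma > HOMOGENEOUS_TEXTURE_BOUND:
                raise ValueError(
                    "easy lesions must be homogeneous: texture_sigma "
                    f"{self.texture_sigma} > {HOMOGENEOUS_TEXTURE_BOUND}"
                )
        else:
            if self.n_spicules < 3:
                raise ValueError("challenging lesions need >= 3 spicules")


@dataclass
class PerturbationSpec:
    """Observer perturbation parameters.

    ``boundary_sigma_mm`` is the pointwise standard deviation of the smooth
    boundary-displacement field; ``morph_radius_range_mm`` is a signed
    interval for a random uniform morphological offset (negative = erosion,
    positive = dilation, applied through the signed distance transform);
    ``spicule_keep_prob`` is the probability that a protruding structure is
    included by the observer.
    """

    boundary_sigma_mm: float = 1.0
    morph_radius_range_mm: tuple[float, float] = (0.0, 0.0)
    spicule_keep_prob: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.morph_radius_range_mm
        if self.boundary_sigma_mm < 0:
            raise ValueError("boundary_sigma_mm must be >= 0")
        if hi < lo:
            raise ValueError("morph_radius_range_mm must satisfy lo <= hi")
        if not 0.0 <= self.spicule_keep_prob <= 1.0:
            raise ValueError("spicule_keep_prob must be in [0, 1]")
        self.morph_radius_range_mm = (float(lo), float(hi))


@dataclass
class ObserverSet:
    """One tumor: image, ground truth and the simulated observer masks."""

    tumor_id: str
    image: ImageVolume
    truth_mask: SegmentationMask
    observer_masks: dict[str, SegmentationMask]
    difficulty: str

    def __post_init__(self) -> None:
        if len(self.observer_masks) < 2:
            raise ValueError("an ObserverSet needs at least 2 observer masks")
        if self.difficulty not in _DIFFICULTIES:
            raise ValueError(f"difficulty must be one of {_DIFFICULTIES}")
        for name, m in {"truth": self.truth_mask, **self.observer_masks}.items():
            if m.n_foreground == 0:
                raise ValueError(f"mask {name!r} of {self.tumor_id} is empty")
            if not check_aligned(self.image, m):
                raise ValueError(
                    f"mask {name!r} of {self.tumor_id} is not aligned with image"
                )


def _voxel_centers_mm(shape, spacing):
    axes = [np.arange(n) * s for n, s in zip(shape, spacing)]
    return np.meshgrid(*axes, indexing="ij")


def _smooth_unit_field(rng, shape, spacing_mm, smooth_mm=_FIELD_SMOOTH_MM):
    """Gaussian-smoothed white noise rescaled to unit standard deviation."""
    sig = [smooth_mm / s for s in spacing_mm]
    f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=sig)
    sd = f.std()
    if sd == 0:
        return np.zeros(shape)
    return f / sd


def make_phantom(spec: PhantomSpec) -> tuple[ImageVolume, SegmentationMask]:
    """Voxelize one lesion and synthesize its image.

    The mask is the exact voxelized lesion (ellipsoid core plus tapered
    capsule spicules); the image is background noise plus
    ``intensity_contrast`` and a smooth texture field inside the lesion.
    """
    rng = np.random.default_rng(spec.seed)
    shape, spacing = spec.grid_shape, spec.spacing_mm
    center = np.array(
        [(n - 1) * s / 2.0 for n, s in zip(shape, spacing)]
    )
    extent = max(spec.radius_mm) + (
        spec.spicule_length_mm if spec.n_spicules > 0 else 0.0
    )
    for ax in range(3):
        half = (shape[ax] - 1) * spacing[ax] / 2.0
        if extent + 1.0 > half:
            raise ValueError(
                f"lesion (extent {extent:.1f} mm + 1 mm margin) exceeds grid "
                f"bounds on axis {ax} (half-extent {half:.1f} mm)"
            )

    xs = _voxel_centers_mm(shape, spacing)
    rel = [(x - c) / r for x, c, r in zip(xs, center, spec.radius_mm)]
    rho = np.sqrt(sum(u * u for u in rel))
    mask = rho <= 1.0

    # spicules: tapered capsules rooted on the ellipsoid surface
    for _ in range(spec.n_spicules):
        u = rng.standard_normal(3)
        u /= np.linalg.norm(u)
        surf_r = 1.0 / np.sqrt(sum((u[i] / spec.radius_mm[i]) ** 2 for i in range(3)))
        p0 = center + u * (surf_r - 1.0)  # rooted 1 mm inside the surface
        length = spec.spicule_length_mm * rng.uniform(0.7, 1.0) + 1.0
        r_base = rng.uniform(*spec.spicule_radius_mm)
        r_tip = 0.6
        d = [x - p for x, p in zip(xs, p0)]
        t = sum(di * ui for di, ui in zip(d, u))  # projection along axis (mm)
        tc = np.clip(t, 0.0, length)
        dist2 = (
            (d[0] - tc * u[0]) ** 2
            + (d[1] - tc * u[1]) ** 2
            + (d[2] - tc * u[2]) ** 2
        )
        radius = r_base + (r_tip - r_base) * tc / length
        mask |= dist2 <= radius**2

    image = np.zeros(shape, dtype=np.float64)
    image[mask] += spec.intensity_contrast
    if spec.rim_enhancement > 0:
        # heterogeneous enhancement: brighter rim decaying toward the core,
        # so the sampled intensity mix depends on where the boundary is drawn
        depth = ndimage.distance_transform_edt(mask, sampling=spacing)
        rim = spec.rim_enhancement * np.exp(-np.maximum(depth - 1.0, 0.0) / 2.5)
        image[mask] += rim[mask]
    if spec.texture_sigma > 0:
        tex = _smooth_unit_field(rng, shape, spacing) * spec.texture_sigma
        image[mask] += tex[mask]
    if spec.noise_sigma > 0:
        image += rng.standard_normal(shape) * spec.noise_sigma

    vol = ImageVolume(image.astype(np.float32), spacing)
    return vol, SegmentationMask(mask.astype(np.uint8), spacing)


def _signed_distance_mm(mask: np.ndarray, spacing) -> np.ndarray:
    """Positive inside the mask, negative outside, in millimetres."""
    inside = ndimage.distance_transform_edt(mask, sampling=spacing)
    outside = ndimage.distance_transform_edt(~mask, sampling=spacing)
    return inside - outside


def _drop_spicules(mask: np.ndarray, spacing, keep_prob: float, rng) -> np.ndarray:
    """Randomly remove protruding structures (spicule dropout).

    Protrusions are connected components of ``mask`` minus its morphological
    opening; tiny digitization fragments (< 10 voxels) are never dropped.
    """
    open_r = [max(1, int(round(2.0 / s))) for s in spacing]
    struct = np.ones([2 * r + 1 for r in open_r], dtype=bool)
    opened = ndimage.binary_opening(mask, structure=struct)
    if not opened.any():
        return mask
    protrusions = mask & ~opened
    labels, n = ndimage.label(protrusions, structure=np.ones((3, 3, 3)))
    if n == 0:
        return mask
    out = mask.copy()
    sizes = np.bincount(labels.ravel())
    for comp in range(1, n + 1):
        if sizes[comp] < 10:
            continue
        if rng.uniform() >= keep_prob:
            out[labels == comp] = False
    return out


def simulate_observer(
    truth: SegmentationMask, pert: PerturbationSpec, max_retries: int = 10
) -> SegmentationMask:
    """Perturb a ground-truth mask into one simulated observer contour.

    The all-zero perturbation (``boundary_sigma_mm=0``, morph range (0, 0),
    ``spicule_keep_prob=1``) reproduces the input exactly.  Raises if the
    perturbation repeatedly annihilates the lesion.
    """
    if truth.n_foreground == 0:
        raise ValueError("truth mask is empty")
    rng = np.random.default_rng(pert.seed)
    spacing = truth.spacing_mm
    lo, hi = pert.morph_radius_range_mm

    for _ in range(max_retries):
        m = truth.voxels
        if pert.spicule_keep_prob < 1.0:
            m = _drop_spicules(m, spacing, pert.spicule_keep_prob, rng)
            if not m.any():
                continue
        d = _signed_distance_mm(m, spacing)
        if pert.boundary_sigma_mm > 0:
            d = d + _smooth_unit_field(rng, m.shape, spacing) * pert.boundary_sigma_mm
        if lo != 0.0 or hi != 0.0:
            d = d + rng.uniform(lo, hi)
        out = d > 0
        if out.any():
            return SegmentationMask(
                out.astype(np.uint8), spacing, truth.origin_mm
            )
    raise ValueError(
        "observer perturbation produced an empty mask in "
        f"{max_retries} attempts: perturbation parameters are too large for "
        f"a lesion of {truth.n_foreground} voxels"
    )


@dataclass
class CohortConfig:
    """Population-level parameters of the synthetic study.

    Mean lesion volumes are in cm^3 (easy 5.3, challenging 10.4); observer
    perturbations are stronger for the challenging class, and only that
    class has spicules subject to dropout.
    """

    grid_shape: tuple[int, int, int] = (64, 64, 64)
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    easy_volume_cm3: float = 5.3
    challenging_volume_cm3: float = 10.4
    volume_jitter: float = 0.3  # lognormal sigma of the per-tumor volume (2-sigma clipped)
    easy_anisotropy: float = 0.05
    challenging_anisotropy: float = 0.22
    spicule_count_range: tuple[int, int] = (3, 6)
    spicule_length_mm: float = 7.0
    spicule_radius_mm: tuple[float, float] = (2.2, 3.2)
    intensity_contrast: float = 3.0
    contrast_jitter: float = 0.2  # lognormal sigma of per-tumor enhancement
    easy_texture_range: tuple[float, float] = (0.05, 0.3)
    challenging_texture_range: tuple[float, float] = (0.7, 1.0)
    challenging_rim_range: tuple[float, float] = (1.2, 1.8)
    noise_sigma: float = 0.15
    easy_boundary_sigma_mm: float = 1.6
    challenging_boundary_sigma_mm: float = 2.2
    easy_morph_range_mm: tuple[float, float] = (-0.4, 0.4)
    challenging_morph_range_mm: tuple[float, float] = (-1.5, 1.5)
    spicule_keep_prob: float = 0.6


def _radius_from_volume_cm3(volume_cm3: float) -> float:
    return float((3.0 * volume_cm3 * 1000.0 / (4.0 * np.pi)) ** (1.0 / 3.0))


def _draw_spec(difficulty: str, cfg: CohortConfig, rng, seed: int) -> PhantomSpec:
    easy = difficulty == "easy"
    base_vol = cfg.easy_volume_cm3 if easy else cfg.challenging_volume_cm3
    z = float(np.clip(rng.normal(), -2.0, 2.0))  # keep lesions inside the grid
    vol = base_vol * float(np.exp(z * cfg.volume_jitter))
    r = _radius_from_volume_cm3(vol)
    aniso = cfg.easy_anisotropy if easy else cfg.challenging_anisotropy
    scale = np.exp(rng.normal(0.0, aniso, size=3))
    scale /= scale.prod() ** (1.0 / 3.0)  # volume-preserving anisotropy
    radii = tuple(float(r * s) for s in scale)
    # per-tumor enhancement and texture amplitude: lesions differ from
    # patient to patient, which is what drives between-tumor feature
    # variance (the ICC numerator)
    contrast = cfg.intensity_contrast * float(
        np.exp(rng.normal(0.0, cfg.contrast_jitter))
    )
    tex_lo, tex_hi = (
        cfg.easy_texture_range if easy else cfg.challenging_texture_range
    )
    texture = float(rng.uniform(tex_lo, tex_hi))
    # rescale the rare extreme draw so lesion + spicules stay inside the grid
    half = min((n - 1) * s / 2.0 for n, s in zip(cfg.grid_shape, cfg.spacing_mm))
    allowed = half - 1.5 - (0.0 if easy else cfg.spicule_length_mm)
    if max(radii) > allowed:
        shrink = allowed / max(radii)
        radii = tuple(r * shrink for r in radii)
    rim = 0.0 if easy else float(rng.uniform(*cfg.challenging_rim_range))
    return PhantomSpec(
        grid_shape=cfg.grid_shape,
        spacing_mm=cfg.spacing_mm,
        difficulty=difficulty,
        radius_mm=radii,
        n_spicules=0 if easy else int(rng.integers(*cfg.spicule_count_range)),
        spicule_length_mm=cfg.spicule_length_mm,
        spicule_radius_mm=cfg.spicule_radius_mm,
        intensity_contrast=contrast,
        rim_enhancement=rim,
        texture_sigma=texture,
        noise_sigma=cfg.noise_sigma,
        seed=seed,
    )


def _perturbation_for(difficulty: str, cfg: CohortConfig, seed: int) -> PerturbationSpec:
    easy = difficulty == "easy"
    return PerturbationSpec(
        boundary_sigma_mm=(
            cfg.easy_boundary_sigma_mm if easy else cfg.challenging_boundary_sigma_mm
        ),
        morph_radius_range_mm=(
            cfg.easy_morph_range_mm if easy else cfg.challenging_morph_range_mm
        ),
        spicule_keep_prob=1.0 if easy else cfg.spicule_keep_prob,
        seed=seed,
    )


def _tumor_seeds(base_seed: int, index: int, n_observers: int) -> list[int]:
    """Deterministic per-tumor seed fan-out, independent of generation order."""
    ss = np.random.SeedSequence(entropy=base_seed, spawn_key=(index,))
    state = ss.generate_state(2 + n_observers)
    return [int(s % (2**31)) for s in state]


def make_cohort(
    n_easy: int,
    n_challenging: int,
    n_observers: int,
    base_seed: int,
    config: CohortConfig | None = None,
) -> list[ObserverSet]:
    """Generate the full synthetic study cohort.

    Challenging lesions are drawn with a larger mean volume and stronger
    observer perturbations than easy ones.  Per-tumor randomness is derived
    deterministically from ``base_seed`` and the tumor index.
    """
    if n_easy < 1 or n_challenging < 1:
        raise ValueError("n_easy and n_challenging must be >= 1")
    if n_observers < 2:
        raise ValueError("at least 2 observers are required")
    cfg = config or CohortConfig()
    difficulties = ["easy"] * n_easy + ["challenging"] * n_challenging
    cohort: list[ObserverSet] = []
    for idx, diff in enumerate(difficulties):
        seeds = _tumor_seeds(base_seed, idx, n_observers)
        rng = np.random.default_rng(seeds[0])
        spec = _draw_spec(diff, cfg, rng, seed=seeds[1])
        image, truth = make_phantom(spec)
        observers = {}
        for k in range(n_observers):
            pert = _perturbation_for(diff, cfg, seed=seeds[2 + k])
            observers[f"obs{k + 1}"] = simulate_observer(truth, pert)
        cohort.append(
            ObserverSet(
                tumor_id=f"tumor{idx:03d}",
                image=image,
                truth_mask=truth,
                observer_masks=observers,
                difficulty=diff,
            )
        )
    return cohort


def save_cohort(cohort: list[ObserverSet], out_dir: str | Path) -> Path:
    """Write a cohort as NIfTI volumes plus a JSON manifest; returns the manifest path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = []
    for oset in cohort:
        tid = oset.tumor_id
        write_volume(oset.image, out / f"image_{tid}.nii.gz")
        write_mask(oset.truth_mask, out / f"truth_{tid}.nii.gz")
        obs_files = {}
        for name, m in oset.observer_masks.items():
            fname = f"{name}_{tid}.nii.gz"
            write_mask(m, out / fname)
            obs_files[name] = fname
        manifest.append(
            {
                "tumor_id": tid,
                "difficulty": oset.difficulty,
                "image": f"image_{tid}.nii.gz",
                "truth": f"truth_{tid}.nii.gz",
                "observers": obs_files,
            }
        )
    mpath = out / "cohort_manifest.json"
    mpath.write_text(json.dumps(manifest, indent=2))
    return mpath


def load_cohort(in_dir: str | Path) -> list[ObserverSet]:
    """Read a cohort previously written by :func:`save_cohort`."""
    root = Path(in_dir)
    manifest = json.loads((root / "cohort_manifest.json").read_text())
    cohort = []
    for entry in manifest:
        cohort.append(
            ObserverSet(
                tumor_id=entry["tumor_id"],
                image=read_volume(root / entry["image"]),
                truth_mask=read_mask(root / entry["truth"]),
                observer_masks={
                    name: read_mask(root / fname)
                    for name, fname in entry["observers"].items()
                },
                difficulty=entry["difficulty"],
            )
        )
    return cohort
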