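# Methods

`radrobust` quantifies how robust radiomics features are to inter-observer
variability in manual 3D tumor segmentation. Because no patient imaging is
bundled, the package ships a synthetic phantom cohort whose generator is a
first-class, tested component: it encodes the population and observer
structure that the downstream statistics assume, and every pipeline result
in this repository is computed from it at run time.

## The statistical model

For each tumor *i* and observer *j* the pipeline produces a feature value
x<sub>ij</sub>. Feature robustness is the two-way random-effects,
absolute-agreement, single-rater intraclass correlation ICC(2,1), computed
from the two-way ANOVA mean squares (MSR between subjects, MSC between
raters, MSE residual) of the n x k matrix:

    ICC(2,1) = (MSR - MSE) / (MSR + (k-1) MSE + (k/n)(MSC - MSE))

A feature is *robust* when ICC > 0.9 (strict). A matrix with no variance
anywhere has no defined agreement and is reported as undefined (never
robust). Undefined feature values are handled by tumor-wise deletion before
the ICC; features whose modal value covers >= 95% of all tumor-observer
records are removed beforehand as near-zero-variance.

Spatial agreement between two segmentations A and B is the volumetric Dice
similarity coefficient DSC = 2|A∩B| / (|A|+|B|) over voxel sets, computed
for every unordered observer pair of every tumor. The easy-vs-challenging
comparison applies a two-sided Welch t-test to per-tumor mean DSC; Welch
rather than pooled-variance because the strata differ in size and spread.
The summary 95% CI on the mean ICC is the t-interval of the mean across
features (an across-feature summary, not a per-feature F-based interval;
per-feature intervals are deliberately not the headline quantity).

## Image processing chain

Order: normalize -> resample -> (wavelet filter) -> discretize per ROI ->
features.

* **Normalization**: z-score either over all voxels (`whole_image`) or over
  non-background voxels only (`foreground`), where background is the
  largest connected below-Otsu-threshold component (air). Both conventions
  exist in widely used extraction software; `whole_image` is the default.
* **Resampling**: trilinear interpolation of the image onto an isotropic
  1.0 mm grid covering the original extent; masks are resampled
  nearest-neighbor onto the same grid (linear interpolation of a binary
  mask would need an arbitrary re-threshold). Convention: world position =
  origin + index * spacing, axis-aligned only.
* **Discretization**: fixed bin width w = 0.1 in normalized-intensity
  units, with edges anchored at integer multiples of w:
  level(x) = floor(I(x)/w) - floor(min_ROI/w) + 1. The anchored-edge rule
  makes levels invariant under shifts by exact multiples of w and is the
  convention of the open-source extractor this package mirrors. The width
  can also be selected automatically: among candidate widths
  {0.01, 0.02, 0.05, 0.1, 0.2, 0.5, 1.0}, choose the one maximizing the
  number of ROIs whose bin count ceil(range/w) lies in [16, 128], ties to
  the smallest width.
* **Wavelets**: single-level 3D stationary (undecimated) Haar transform
  with `norm=True`, giving 8 sub-bands (LLL..HHH) on the original grid so
  the original mask applies unchanged; with an orthogonal wavelet the
  transform partitions energy exactly, which the tests verify. The family
  is configurable; Haar is the default because it makes the Parseval check
  exact.

## Feature families

Shape (11 mesh/axis descriptors; marching cubes at iso-level 0.5 on the
lightly Gaussian-smoothed binary mask — smoothing suppresses the staircase
surface-area bias of voxelized boundaries), first-order (18), and five
texture families on the discretized ROI: GLCM (24), GLRLM (16), GLSZM (16),
NGTDM (5), GLDM (14). Conventions: 26-neighborhoods at Chebyshev distance 1
(13 unique directions); GLCM symmetrized and, like GLRLM, computed per
direction then averaged, skipping directions with no valid pairs; GLSZM
zones 26-connected; GLDM tolerance alpha = 0 with dependence column
j = (number of dependent neighbors) + 1. Degenerate inputs yield the
defined subset of features, NaN otherwise (e.g. GLCM Correlation of a flat
ROI is reported as 1, the fully-degenerate convention of the reference
open-source implementation). Unfiltered set: 104 features; with the 8
wavelet sub-bands (93 intensity/texture features each): 848. Exact name
lists ship as a versioned manifest.

## The synthetic cohort

Default study: 30 "easy" + 10 "challenging" tumors, 4 simulated observers,
64^3 grids at 1 mm isotropic. Lesions are ellipsoids (volume-preserving
log-normal anisotropy) with per-tumor population spread: volume log-normal
around 5.3 cm^3 (easy) / 10.4 cm^3 (challenging) with sigma 0.3 (clipped at
2 sigma so lesions fit the grid), enhancement contrast log-normal (sigma
0.2) around 3 arbitrary units, intra-lesion texture amplitude uniform in
0.05-0.3 (easy) / 0.7-1.0 (challenging), additive noise sigma 0.15.
Challenging lesions additionally carry 3-6 thick protrusion lobes
(radius 2.2-3.2 mm, length ~7 mm) and rim enhancement (amplitude 1.2-1.8,
decaying over 2.5 mm from the surface): spatially heterogeneous enhancement
is what makes intensity features sensitive to where the boundary is drawn.

Observers perturb the ground-truth mask in three ways, mirroring manual
contouring: (1) a smooth random boundary-displacement field (Gaussian white
noise smoothed to a 3 mm correlation length, scaled to sigma 1.6 mm easy /
2.2 mm challenging), applied through the signed Euclidean distance
transform; (2) a systematic over-/under-segmentation offset uniform in
(-0.4, 0.4) mm easy / (-1.5, 1.5) mm challenging; (3) for challenging
lesions, independent dropout of each protruding lobe with keep probability
0.6 (protrusions are recovered from the mask itself as connected components
of the mask minus its morphological opening). The zero perturbation is the
exact identity. These settings were calibrated once so that pairwise DSC
sits at the level reported for human observers on breast DCE-MRI
(~0.83 easy, ~0.75 challenging, ~0.82 overall) while reproducing the
qualitative stratified structure (easy tumors yield a higher share of
robust features than challenging ones); they are the fixed study
conditions, not tuning knobs.

All randomness derives from a single base seed fanned out per tumor and
observer through `numpy.random.SeedSequence(entropy=base_seed,
spawn_key=(tumor_index,))`, so cohorts are bit-reproducible and independent
of generation order.

### What the generator does and does not emulate

It emulates: two difficulty classes with distinct morphology, size and
heterogeneity; controlled, class-dependent inter-observer disagreement with
both random and systematic components; disagreement about inclusion of
disputed subregions. It does not emulate: DCE kinetics or multi-timepoint
enhancement, breast-anatomy background (fat/fibroglandular tissue, skin,
lymph nodes), scanner- or sequence-dependent noise spectra, non-mass
enhancement as a distinct morphology, or per-observer skill differences
(a per-observer systematic bias exists implicitly only through the random
offset). Passing tests therefore demonstrate correctness of the statistics
and the direction and rough magnitude of the mechanism — not clinical-level
reproduction of any patient cohort.

## Numerical choices

* ICC denominators: exact all-equal matrices return NaN before any
  floating-point cancellation can fabricate a value; tiny negative residual
  sums of squares are clamped to 0.
* DSC uses integer voxel cardinalities; no tolerance is involved.
* Geometric alignment tolerance between image and mask: 1e-6 mm.
* Bin-width tie-break: smallest candidate width.
* Observer simulation retries a fresh draw up to 10 times if a perturbation
  annihilates the mask, then raises.
* Marching-cubes smoothing sigma: 1 voxel; single-voxel masks have no
  triangulatable surface and report mesh metrics as NaN.

## Problem sizes used by the test suite

Unit tests run on small grids (<= 44^3) and tiny ROIs (<= 8^3 for the
brute-force texture oracles). The study-level checks use the default
40-tumor, 4-observer, 64^3 cohort with wavelets enabled; the
perturbation-monotonicity check uses displacement levels 0.5/1.0/2.0 mm
with 30 seeds per level on 4-tumor, 3-observer, 40^3 all-easy cohorts
without wavelets — sizes chosen
to keep a full run at desk scale while leaving the Monte-Carlo conclusions
stable.

## Known limitations

* The phantom interior is smooth-field texture; real tumor texture has
  structure at multiple scales, so absolute ICC levels per feature group
  should not be read as predictions for clinical data.
* Protrusion recovery by morphological opening cannot distinguish a thin
  lobe from a narrow isthmus of the core lesion; with the default geometry
  this is rare and harmless, but exotic shapes could mislabel regions.
* ICC(2,1) assumes a complete tumor x observer grid; tumor-wise deletion
  discards information when values are undefined for only some observers.
* Only single-level wavelet decomposition is implemented, and only the
  feature families listed above (no fractal, local-intensity, GLDZM or
  standalone intensity-histogram groups).
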