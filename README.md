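# radrobust

Radiomics promises quantitative imaging biomarkers, but every feature is
computed inside a region of interest that somebody had to draw. When
several observers segment the same tumor, how many features survive the
disagreement? `radrobust` is a tested, reusable pipeline that answers this
for 3D MRI-style volumes: it measures inter-observer spatial agreement with
the Dice similarity coefficient (DSC), classifies each radiomics feature as
robust or not with the intraclass correlation ICC(2,1), and compares
easy-to-segment against challenging-to-segment tumors. Because patient
imaging cannot be redistributed, the package includes a synthetic
breast-lesion phantom cohort with simulated observers as a first-class,
seeded, tested component — the whole study runs from a single seed.

It is aimed at radiomics researchers who want a transparent, reproducible
robustness analysis they can point at their own NIfTI volumes and
segmentations, and at methodologists studying how segmentation variability
propagates into feature space.

## The statistics at the core

For masks A and B (voxel sets):

    DSC = 2 |A ∩ B| / (|A| + |B|)          1 = perfect overlap, 0 = disjoint

For a feature measured on n tumors by k observers, with two-way ANOVA mean
squares MSR (tumors), MSC (observers), MSE (residual):

    ICC(2,1) = (MSR − MSE) / (MSR + (k−1)·MSE + (k/n)·(MSC − MSE))

A feature is **robust** when ICC > 0.9 (strict). Features whose modal value
covers ≥ 95% of all observations are removed first (near-zero variance).
Strata are compared with a two-sided Welch t-test on per-tumor mean DSC.

Features are IBSI-style: shape, first-order, and five texture-matrix
families (GLCM, GLRLM, GLSZM, NGTDM, GLDM) on the unfiltered image and on
the 8 sub-bands of a single-level stationary 3D wavelet transform —
848 features per segmentation with the default manifest. Preprocessing:
z-score normalization, trilinear resampling to 1 mm³ isotropic voxels, and
fixed-bin-width (0.1) discretization with an automatic bin-width selection
rule targeting 16–128 bins per ROI. See `docs/methods.md` for the full model.

## Worked example

```python
from radrobust import RunConfig, run_pipeline

result = run_pipeline(RunConfig(seed=1), out_dir="out")
h = result.headline
print(f"mean DSC {h['mean_dsc']:.3f} "
      f"(easy {h['mean_dsc_easy']:.3f}, challenging {h['mean_dsc_challenging']:.3f})")
print(f"mean ICC {h['mean_icc']:.3f}; robust {result.report.formatted_percentage()}")
print(f"Welch p (easy vs challenging DSC): {h['welch_p']:.2e}")
```

prints, with the default cohort (30 easy + 10 challenging tumors, 4
observers, 64³ grids at 1 mm):

```
mean DSC 0.821 (easy 0.836, challenging 0.776)
mean ICC 0.809; robust 49.4% (419/848)
Welch p (easy vs challenging DSC): 6.43e-06
```

Read: observers of a homogeneous, sharp-margined lesion agree well
(DSC ≈ 0.84) and most of its features survive; spiculated, heterogeneous
lesions are segmented less consistently (DSC ≈ 0.78, significantly lower),
and a smaller share of their features is robust. About half of all
features clear the ICC > 0.9 bar under this level of disagreement — the
other half should not be trusted across observers. `out/` contains the
full report tables (`dsc_pairs.csv`, `icc_per_feature.csv`,
`group_summary.csv`, `stratified_summary.csv`, `comparison.json`, ...).

The same pipeline is scriptable from the shell:

```bash
radrobust simulate --n-easy 30 --n-challenging 10 --observers 4 --seed 1 --out cohort/
radrobust analyze  --cohort cohort/ --out report/
radrobust run      --seed 1 --out report/       # simulate + extract + analyze
```

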