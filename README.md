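# maskvar

Sensitivity of standardised radiomic features to polygon→binary-mask
conversion.

## The problem

Clinical contours (DICOM RTSTRUCT) store a region of interest as closed
planar polygon loops at sub-voxel patient coordinates.  Radiomic feature
extraction needs a binary voxel mask, so every imaging platform converts
polygons to masks — and they do it differently: some test whether each
voxel **centre** lies inside the polygon (the crossing-number / even-odd
rule), others **super-sample** each voxel into `2^split` sub-voxel
centres per axis and include the voxel when the interior percentage
reaches a threshold.  Strict thresholds erode the mask edge, lenient
ones dilate it.  Because a handful of edge voxels is a large fraction of
a small or low-resolution ROI (PET especially), the conversion choice
alone perturbs "standardised" feature values, patient rankings and
unsupervised patient clustering.

`maskvar` implements this whole analysis as a reusable pipeline for
researchers who study radiomics reproducibility:

- **geometry** — RTSTRUCT/JSON contour reading, patient↔voxel transforms;
- **rasterize** — centre-point and grid-super-sampled conversion
  (`RasterStrategy(method, split, threshold_pct)`);
- **mask_metrics** — difference maps and the voxel discrepancy
  `V_d = 100·Σ|d_map|/N_m` against a designated baseline mask of
  `N_m` voxels, with slice-extension vs edge classification;
- **features** — an IBSI-style registry of 45 features across all nine
  families (morph, stat, ih, cm, rlm, szm, dzm, ngt, ngl), computed on
  original voxels without resampling;
- **compare_stats** — symmetric percent difference
  `P_d = 100·|f_A−f_B|/|(f_A+f_B)/2|` with four severity bins
  ([0,0.5), [0.5,3), [3,10), [10,∞)%), Spearman ρ of patient rankings,
  and ICC(2,1) (two-way random effects, absolute agreement) with each
  conversion strategy as a rater;
- **clustering** — Z-scoring, complete-linkage dendrograms and the
  entanglement `Σ|pos₁(i)−pos₂(i)| / Σ|i−(n+1−i)|` between two leaf
  orders (0 = identical ordering, 1 = full reversal);
- **phantom** — a seeded synthetic cohort (ellipsoidal lesions with
  jittered per-slice contours on fine CT / intermediate MRI / coarse PET
  grids) so the full pipeline runs with no data download;
- **experiments** — three runners: strategy-vs-baseline comparison,
  super-sampling threshold sweep, and a mixed-import simulation of a
  multi-centre collection.

## Worked example

```python
from maskvar import (CohortConfig, ExtractionConfig, RasterStrategy,
                     difference_map, extract_features, generate_cohort,
                     rasterize, voxel_discrepancy)

cohort = generate_cohort(CohortConfig(seed=42))
pat = cohort.patients[0]
geom = pat.images["PET"].geometry

baseline = rasterize(pat.contours["PET"], geom, RasterStrategy(method="centre"))
strict = rasterize(pat.contours["PET"], geom,
                   RasterStrategy("supersampled", split=1, threshold_pct=90.0))
vd = voxel_discrepancy(difference_map(strict, baseline))
fb = extract_features(pat.images["PET"], baseline, ExtractionConfig())
fs = extract_features(pat.images["PET"], strict, ExtractionConfig())
print(f"PET ROI: {baseline.n_voxels} voxels, V_d = {vd:.1f}%")
print(f"volume {fb['morph_volume']:.0f} -> {fs['morph_volume']:.0f} mm^3")
```

prints

```
PET ROI: 95 voxels, V_d = 24.2%
volume 6080 -> 4608 mm^3
```

i.e. eroding the conversion threshold to 90% removes 23 of this
patient's 95 PET ROI voxels (V_d = 24.2% of the baseline ROI), and the
morphological volume drops accordingly — the small-ROI amplification the
pipeline is built to quantify.

The same study end-to-end from a shell:

```sh
maskvar simulate --seed 42 --out cohort/
maskvar exp1 --cohort cohort/ --strategy ss:1:90 --out exp1/
maskvar exp2 --cohort cohort/ --split 1 --out exp2/
maskvar exp3 --cohort cohort/ --out exp3/
```

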