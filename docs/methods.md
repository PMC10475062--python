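# Methods

## Coordinate model

A voxel grid is described by the patient-space position of the first
voxel centre (origin), the unit direction cosines of increasing row,
column and slice index, the (row, col, slice) spacing in mm and the grid
dims.  Integer index = voxel **centre**, 0-based; the grid is closed at
voxel centres.  `patient_to_voxel` and `voxel_to_patient` are exact
inverses (tested to 1e-9 mm over random orthonormal orientations).
Contour polygons are closed planar loops; an item counts as planar when
max |z − mean z| ≤ 1e-3 mm, which absorbs float serialisation of
nominally constant-z contours.  Only CLOSED_PLANAR RTSTRUCT items are
accepted; grid geometry is always taken from the image series, never
inferred from contours.

## Rasterisation

Point-in-polygon membership uses the crossing-number (even-odd) rule
with the half-open edge convention: an edge is counted iff exactly one
endpoint lies strictly above the horizontal ray.  This removes
vertex-on-ray double counting without any epsilon; points exactly on an
edge are classified by the same arithmetic.  Multiple polygons on one
slice combine by even-odd (XOR), so nested loops create holes.

A polygon is assigned to the slice plane whose continuous slice index is
within half a slice spacing of its vertices; anything further is a data
error.

The super-sampled strategy subdivides each voxel into `2^split` sub-voxel
centres per axis, placed symmetrically about the voxel centre at offsets
`(k + 1/2)/2^split − 1/2` voxel widths (split 1 → ±1/4; 8 sub-voxels per
voxel in 3D).  A voxel is included when the interior percentage of its
sub-voxel centres is **≥** the threshold (inclusive comparison: with 4
in-plane sub-voxels and a 25% threshold, one interior sub-voxel
suffices).  Split 0 reduces exactly to the centre method.  The default
`z_policy="parent_slice"` tests z-displaced sub-voxel centres against
the polygons of the parent voxel's slice — contours exist only on slice
planes, so interpolating between them is a separate modelling choice we
do not make silently; the z-split is then inert and the interior
fraction equals the in-plane fraction (the implementation uses this
shortcut).  `nearest_plane` instead resolves each sub-voxel layer to its
nearest contoured plane.  Commercial implementations do not document
their sub-voxel placement or z handling; this module fixes one explicit
convention rather than guessing any vendor's.

Threshold monotonicity (larger threshold ⇒ subset mask), the
erosion/dilation ordering around the centre mask for convex contours,
and area convergence for polygons large relative to a voxel are asserted
as property tests.

## Mask discrepancy

For masks `m_a` (test) and `m_n` (designated baseline) on one grid, the
difference map is the element-wise subtraction `m_a − m_n` ∈ {−1, 0, +1}
and the voxel discrepancy is `V_d = 100 · Σ|d_map| / N_m` with `N_m` the
baseline ROI voxel count.  The baseline must be designated explicitly —
`V_d` is not symmetric unless the two ROI sizes match.  Discrepant
voxels on slices occupied by exactly one mask are classified as
slice extensions (superior/inferior plane differences), the remainder as
edge disagreements; the two counts always sum to `Σ|d_map|`.

## Feature extraction

Features are computed from original voxels — no interpolation or
resampling — so that mask differences are the only source of variation.
Intensities are discretised per ROI, fixed bin number (FBN) by default:
`level = min(Ng, 1 + floor(Ng·(x − min)/(max − min)))`, constant regions
mapping to level 1; fixed bin size (FBS) is
`1 + floor((x − min_bound)/width)`.  Default FBN 32 for every modality,
overridable per modality.

The registry holds 45 features, at least three per family:

- **morph**: voxel-count volume, voxel-face surface area, maximum 3D
  diameter (max pairwise centre distance, convex-hull accelerated),
  sphericity `π^(1/3)(6V)^(2/3)/A`;
- **stat** (raw intensities): mean, population variance, skewness,
  excess kurtosis, median, min, max, range, energy;
- **ih** (levels): mean, variance, entropy (−Σp·log₂p), uniformity,
  mode (lowest level on ties);
- **cm**: joint maximum, joint entropy, contrast, dissimilarity, inverse
  difference, correlation — from co-occurrences over the 13 unique 3D
  directions at Chebyshev distance 1, symmetrised, merged into one
  matrix, then normalised;
- **rlm**: short/long run emphasis, grey-level non-uniformity, run
  percentage, run entropy — runs merged over the same 13 directions;
- **szm**: small/large zone emphasis, zone-size entropy, zone
  percentage — zones are 26-connected constant-level components;
- **dzm**: small/large distance emphasis, distance entropy — zone
  distance is the city-block distance to the nearest out-of-mask voxel,
  with the volume border counting as outside and minimum distance 1;
- **ngt**: coarseness, contrast, busyness, complexity, strength from
  occurrence probabilities `p_i` and summed absolute deviations `s_i`
  against valid 26-neighbourhood means;
- **ngl**: low/high dependence emphasis, dependence count entropy and
  non-uniformity; the dependence count k (identical-level 26-neighbours,
  α = 0) is stored at column j = k + 1 so the 1/j² and j² weights are
  defined at k = 0.

Numerical conventions: `log₂(0)` terms in entropies contribute 0;
`ε = 2⁻⁵²` guards the coarseness and busyness denominators; a constant
region yields co-occurrence correlation 1 by convention; kurtosis is
reported as excess kurtosis.  Every matrix builder is validated against
an exhaustive pure-Python enumeration oracle in the test suite.  Full
parity with any particular 158-feature platform registry is out of
scope; the registry above is the package's own documented list.

## Comparison statistics

`P_d = 100·|f_A − f_B| / |(f_A + f_B)/2|`; matching zeros are defined as
no variation (P_d = 0), and a zero mean with nonzero difference returns
a NaN sentinel reported in the worst category.  The denominator takes
the absolute value of the mean so P_d is sign-safe for negative-valued
features; note P_d can exceed 200% when the two values have opposite
signs.  Severity bins are half-open: [0, 0.5), [0.5, 3), [3, 10),
[10, ∞) percent, applied consistently (0.5 → G2, 3 → G3, 10 → G4).

Spearman ρ is the Pearson correlation of average ranks; zero rank
variance gives a NaN sentinel rather than a silent drop.  ICC(2,1) —
two-way random effects, absolute agreement, single rater — is computed
from the explicit ANOVA decomposition
`(MS_R − MS_E)/(MS_R + (k−1)MS_E + (k/n)(MS_C − MS_E))` with strategies
as raters and patients as subjects; an all-equal matrix returns 1 by
convention.  The implementation is cross-checked in tests against both a
literal ANOVA oracle and pingouin's absolute-agreement single-rater
estimate to 1e-10; neither is a runtime dependency.

## Clustering and entanglement

Feature columns are Z-scored to mean 0 / population sd 1 (constant
columns zeroed and flagged), then patients are clustered with
complete-linkage agglomeration on Euclidean distances.  The linkage is
implemented directly (O(n³); cohorts are tens of patients) to pin down
determinism: minimum-distance ties merge the pair with the smallest
patient-label ranks, and each merge places the subtree containing the
smaller rank on the left, making leaf orders independent of input row
order.  Merge heights are cross-checked against scipy's linkage and a
brute-force recomputation.

Entanglement between two dendrograms over the same labels is
`Σᵢ|pos₁(i) − pos₂(i)|^L / Σᵢ|i − (n+1−i)|^L` at L = 1, i.e. normalised
by the exact-reversal worst case: 0 iff the leaf orders match, 1 for a
full reversal.  It is computed on the raw leaf orders with no
untangling/rotation optimisation, since any rotation search would change
the values; this choice is deliberate and documented.

## Synthetic cohort

Each patient carries one randomly oriented ellipsoidal lesion (one
anatomy) imaged on three axis-aligned grids: CT 1×1×3 mm (64×64×24),
MRI 1×1×5 mm (48×48×16), PET 4×4×4 mm (32×32×16), each centred on the
lesion region.  Semi-axes are uniform in 6–12 mm, so the PET ROI holds
tens of voxels on average while the CT ROI holds hundreds to thousands —
the size regime in which a fixed edge discrepancy disturbs features most
on PET.  Contours are the analytic ellipsoid cross-sections at each
slice plane, sampled at 64 vertices, with smooth circularly-correlated
vertex jitter (sd 0.3 mm, capped at 15% of the local cross-section
radius so loops stay simple; self-intersecting draws are resampled).
Cross-sections with minimum radius under 0.5 mm are skipped, mirroring
the clinical practice of not contouring sub-voxel polar slivers.

Lesion intensities are a patient-specific mean (N(100, 20)) plus
spatially correlated texture (Gaussian-smoothed white noise, 3 mm
correlation length, contrast uniform in 10–25) over a white-noise
background (sd 5).  These values are chosen once to give non-degenerate
texture matrices in every family and clear between-patient variation;
FBN discretisation makes the texture features insensitive to the
absolute scale.  Everything derives from a single seed through spawned
per-patient substreams, so cohorts are bit-identical per seed.

What the phantom does **not** emulate: organ anatomy and heterogeneous
tissue, scanner physics (PET partial-volume blur, MRI bias fields),
inter-observer delineation behaviour, and oblique acquisitions.  Passing
the cohort-scale tests therefore demonstrates the pipeline's internal
consistency and the geometric size effect, not clinical effect sizes;
cohort-level numbers (mean V_d, entanglement values) are properties of
these study conditions, not estimates of any clinical dataset's values.

## Experiment runners and problem sizes

Experiment 1 compares arbitrary strategies against a designated baseline
(default: the centre-method mask standing in for a pre-computed
reference mask); Experiment 2 sweeps the super-sampling threshold 10–90%
in steps of 10 at fixed split; Experiment 3 splits the cohort into three
groups imported with (centre; split 1, threshold 90%; split 3, threshold
50%) and compares family-level clustering of the recombined table, with
mixed and baseline tables normalised separately.  The default cohort
size is 20 patients — large enough for stable rank statistics and
clustering while keeping a full three-experiment run in the
tens-of-seconds range on one CPU.  Reports are plain CSV; heatmaps are
emitted as category matrices rather than figures.

## Known limitations

- The centre-method baseline is a stand-in for an externally supplied
  reference mask (e.g. a curated NIfTI segmentation); `read_mask_nifti`
  accepts such a mask when one exists.
- GLCM features are computed at distance 1, merged-3D only; per-angle
  variants are out of scope.
- The feature registry is representative, not exhaustive; adding a
  feature means adding one function over the already-validated matrices.
- Contour z-interpolation between slice planes is deliberately not
  implemented.
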