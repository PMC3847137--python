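# Methods

This note documents the models, conventions, and design choices behind
`thoravol`, and what its synthetic-data experiments do and do not show
about real images.

## Coordinate and geometry conventions

Volumes are indexed `(slice, row, col)`, 0-based, with pixel centers at
integer coordinates.  A pixel belongs to a contoured region iff its center
is strictly inside the polygon; centers exactly on an edge are resolved by
an even-odd (ray crossing) test with the test row offset by 1e-9, which is
deterministic and independent of vertex orientation (reversing the vertex
order provably yields the same mask, and this is property-tested against a
point-in-polygon oracle).  Circular ROIs are defined by a physical
diameter; membership uses physical distance from the center computed with
the in-plane pixel spacing.

The effective slice spacing is thickness + gap (8 + 2 = 10 mm for the
sagittal survey).  It is stored as the NIfTI slice zoom and used for all
volume integration: each slice is treated as representative of its 10 mm
slab.  The acquisition protocol's wording ("multiplied by the total slice
thickness") is ambiguous between 8 and 10 mm; integrating over the
center-to-center spacing avoids a systematic 20% undercount from the
gaps, and `itfv(..., slice_integration="thickness")` exposes the
alternative.  In-plane pixel size is not fixed by a 256×155 matrix with a
400–450 mm FOV alone; phantoms default to 1.6 mm isotropic in-plane.

Modality (MR vs CT) is carried as metadata — embedded in the NIfTI header
description together with thickness and gap — never inferred from value
ranges.

## Fat volumetry

The reference population is the *pooled pixel set* of all muscle ROIs,
not the mean of per-ROI means: the protocol wording ("the mean signal and
SD of these regions") is ambiguous, and pooling uses all pixels in a
single deterministic estimate.  SDs use the n−1 denominator.  The
threshold is μ + k·σ with k = 10 by default; the comparison is inclusive
(≥), mirroring the "≥ 10 SD" operating point, and k is a parameter
everywhere (never hard-coded) so the calibration sweep can vary it.

Consequence of inclusivity worth knowing: with a literally zero-variance
reference (σ = 0), the threshold equals the reference mean and reference
tissue itself satisfies ≥.  "Noise-free" recovery experiments therefore
either pass an explicit threshold between the tissue means or use
near-degenerate SDs (tissue separation ≫ 10σ), where the full chain
recovers the voxel truth exactly.

## CT-anchored calibration

Visual matching of MR and CT fat segmentations is replaced by the Dice
coefficient (bounded, symmetric, standard for segmentation agreement),
averaged over the analysed slices; empty-vs-empty slices score 1.  Ties
select the smaller k — the more inclusive threshold, which errs toward
counting fat.  The default grid is the integers 4…16, bracketing the
10-SD operating point.  Registration is assumed done: phantom MR/CT pairs
are constructed congruent, as anatomically matched multiplanar
reconstructions would be.  Reference statistics are computed per
bundle (per patient), and Dice is averaged across that bundle's slices.

The calibration phantom encodes a known optimum: fat MR signal is uniform
on [μ+10.6σ, μ+14σ] and a bright non-fat tissue compartment (emulating
intermediate-intensity structures such as vessels and partial-volume
pixels) spans [μ+4σ, μ+9.4σ], while on CT only true fat falls in the
−190…−30 HU window.  Thresholds below 10 admit bright tissue, thresholds
above 10 cut into fat, so Dice peaks at k = 10.  The ±0.6σ guard bands
around the operating point absorb the sampling error of the estimated
threshold at the reference size used (8 ROIs of 9.6 mm per slice, ≈1300
pooled pixels, SE of μ̂+10σ̂ ≈ 1 signal unit).

## LV scar quantification

Myocardium is the per-slice set difference of the rasterized epicardial
and endocardial regions; the geometry constructor requires endo strictly
inside epi.  One explicit reference ROI in remote myocardium serves the
whole stack (the "largest contiguous normal region" is a manual choice in
practice, and a single whole-stack reference keeps the threshold
consistent across slices).  Scar % = 100 × (myocardial voxels ≥ μ_ref +
k·σ_ref) / (myocardial voxels), k = 5 by default; the voxel-count ratio
equals the mass ratio because tissue density cancels.

## Synthetic data

**Thoracic phantom.** Rectangular intra-thoracic contour per slice
(margin 8 px); compartments: background, muscle, fat ellipsoids, optional
bright non-fat ellipsoids.  MR signal is Gaussian per compartment,
clipped at 0 — Gaussian rather than Rician because the method consumes
only means and SDs of tissue classes, and Gaussian keeps every tail
probability analytic for testing.  Defaults are muscle N(100, 5) and fat
N(200, 10) in arbitrary units (a 20σ separation, far past the 10-SD
operating point) and dim background N(20, 10).  CT values are uniform per
tissue: fat in (−190, −30) HU, soft tissue in (35, 55) HU, background at
−1000 HU (air).  Reference ROIs are placed by the generator in the
posterior (paravertebral) muscle band, verified disjoint from fat truth.
The fat truth mask marks exactly the voxels whose centers fall inside a
fat ellipsoid, so truth volume is the voxel count times the voxel volume.

**LV phantom.** Concentric circular endo/epi contours (radii 18/30 px at
1.5 mm by default) over 4 slices; the scar is the contiguous angular
sector of annulus voxels whose size is chosen *by voxel count* to match
the requested fraction exactly up to rounding (sector-by-angle alone
would carry rasterization error).  Remote myocardium is N(μ_r, σ_r), scar
N(μ_s, σ_r) with μ_s required to exceed μ_r + 5σ_r so the truth is
recoverable; the blood pool is bright, the reference ROI sits mid-wall
diametrically opposite the scar sector.

**Cohort.** Four cells — MetS−/MI−, MetS+/MI−, MetS−/MI+, MetS+/MI+ —
with default sizes 16/32/30/32 and indexed-ITFV means ± SDs of
22.3 ± 10.6, 28.6 ± 12.6, 30.6 ± 12.3 and 35.2 ± 11.4 ml/kg/m².  BMI
group SDs are back-calculated from reported 95% CIs of the group means
(sd = half-width·√n/1.96 → 2.35/6.49/4.19/4.76).  ITFV in ml is indexed
ITFV × BMI by construction, so indexing inverts the generator exactly.
Scar % in the MI+ cells follows a linear coupling, scar = intercept_g +
0.8 × indexed ITFV + N(0, 11.5), with the per-group intercept set so the
group scar means hit their targets (21.1 / 21.0 % by default) and the
noise SD chosen so the implied group scar SDs (√(0.8²·σ_ITFV² + 11.5²) ≈
14.5–14.9) match the reported ≈15.  Waist circumference shares a
standardized component with indexed ITFV (r = 0.8 by default), which is
what the collinearity screen detects.  Non-negative quantities are
truncated at 0 by resampling, not clipping, preserving approximate
normality near the bulk.

Truncation has one measurable side effect: with the default MI+ scar
means, the 0-floor binds for ~8% of subjects, so the realized
scar–ITFV relation is no longer exactly linear and pooled OLS attenuates
the slope (≈0.68 instead of 0.8).  The regression-recovery experiment
therefore uses a variant cohort with a common, higher scar intercept
(MI+ scar means 40 / 43.7%) where truncation is inactive (<0.5% of
draws) and the stated linear generating model actually holds; there the
mean recovered slope is within 0.05 of 0.8 and 95% CI coverage is ≈95%.

## Statistics

Normality is Shapiro-Wilk at α = 0.05 per group (no criterion is
standard; this is the common default).  The two-group parametric test is
Welch's t (unequal variances) — the safer default when group variances
are not known equal; the pooled form is available via `equal_var=True`.
Fisher's exact test replaces chi-square for 2×2 tables with any expected
cell < 5.  The collinearity screen is sequential in the order predictors
are listed: a candidate whose |Pearson r| with an already-included
predictor exceeds 0.7 (configurable) is excluded and reported with its
partner; binary predictors are 0/1-coded (point-biserial), categorical
predictors are dummy-coded with the first level as reference.

Bland-Altman: differences are first-listed minus second; limits of
agreement are bias ± 1.96·SD(differences) with the n−1 denominator.
These are *limits of agreement*, not confidence intervals of the bias —
reported observer-agreement intervals of the kind "1.2 (−146.3 to
148.7)" at n = 10 are far too wide for a CI of a mean and are consistent
only with limits of agreement, so that is what is implemented, with the
labelling discrepancy noted here.  Pearson r is defined as 1.0 for
identical series (including constant ones) and undefined (NaN) against a
non-identical constant series.

## Reproducibility harness

Observer variability is emulated by perturbing contour vertices and
reference-ROI centers with zero-mean Gaussian jitter (magnitudes in
pixels per rater), then re-running the full volumetry.  Each phantom is
read twice at the intra-rater magnitude and once at the (larger)
inter-rater magnitude; Bland-Altman statistics summarize each pairing.
Zero jitter reproduces identical measurements (bias 0, r = 1).  For the
experiment to be informative the phantom's fat must reach near the traced
border — border tracing is the dominant real-world source of variability
— so the harness phantoms place fat within ~1 px of the contour;
with centrally located fat the measurement is (correctly) insensitive to
contour jitter.

## Problem sizes and determinism

Default experiment sizes: 30 calibration pairs on (6, 64, 64) grids;
noise-tail checks on ≥10⁴ fat voxels; 2000 null replicates for type-I
calibration; 500 cohort replicates for power; 200 for regression
recovery; 10 phantoms for the agreement experiment.  All generators and
experiments take explicit integer seeds and are bit-reproducible; the
pipeline report files are byte-identical across reruns of the same
config + seed.

## Limitations

* Phantoms are geometric (rectangular borders, ellipsoidal fat, circular
  myocardium) with independent Gaussian/uniform noise; they contain no
  anatomy, no bias fields, no Rician noise floor, no partial-volume
  gradients, and no registration error between MR and CT.  Passing tests
  demonstrate correctness of the computational chain and its statistical
  calibration, not segmentation accuracy on clinical images.
* Thoracic border detection, Dixon fat/water separation, MR–CT
  registration and DICOM handling are out of scope.
* The cohort generator reproduces first and second moments and one linear
  coupling; real covariate structure (e.g. age–BMI dependence) is not
  modelled.
* ANOVA p-values printed from rounded group summaries are not exactly
  recoverable without patient-level data; the power experiments
  characterize the test at the stated effect sizes instead.
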