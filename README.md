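# thoravol

Quantification of intra-thoracic fat volume (ITFV) on fat-bright sagittal
MR stacks, with CT-anchored calibration of the segmentation threshold,
signal-threshold scar quantification on late-gadolinium-enhancement (LGE)
stacks, and the cohort statistics used to relate fat burden to metabolic
syndrome and myocardial infarction — all exercised end to end on synthetic
phantoms with exact ground truth.

## Who this is for

Researchers in cardiovascular imaging who want a tested, scriptable
implementation of reference-tissue-normalized threshold volumetry (the
kind normally done interactively in clinical analysis software), and
anyone who needs a reproducible harness to study how threshold choice,
observer variability and cohort effect sizes propagate into the final
statistics.

## The method

**Fat volumetry.** On a fat-bright sequence (e.g. HASTE), adipose tissue
has the highest signal of any thoracic tissue.  Signal is normalized to
paravertebral muscle: five (or more) circular reference ROIs of 5–10 mm
are pooled into one pixel population with mean μ and standard deviation σ,
and the fat threshold is

    T = μ + k·σ,   k = 10 by default.

Inside the manually traced intra-thoracic border of each sagittal slice,
every pixel with signal ≥ T is fat.  The total volume is

    ITFV = Σ_slices (fat pixel count × pixel area) × Δz,

with Δz the center-to-center slice spacing (thickness + gap, 8 + 2 =
10 mm by default; an option restricts it to the acquired thickness).
ITFV is indexed to body mass index: indexed ITFV = ITFV / BMI (ml per
kg/m²).

**CT-anchored calibration.** Adipose tissue occupies a calibrated CT
attenuation window (−190 to −30 HU).  Given a co-registered MR/CT pair,
`calibrate_k` sweeps k, segments the MR stack at each μ + k·σ, and scores
slice-wise Dice overlap against the CT HU-window segmentation; the argmax
(ties to the smaller k) is the calibrated multiplier.  On phantoms
constructed with a known operating point the sweep recovers k = 10.

**Scar quantification (STRM).** The myocardium is the annulus between
endocardial and epicardial contours; a reference ROI in remote myocardium
supplies μ and σ; myocardial voxels with signal ≥ μ + 5σ are scar, and
scar burden is reported as % of LV mass (voxel-count ratio — density
cancels).

**Statistics.** Group comparisons pick their test from a Shapiro-Wilk
normality check per group (Welch t / one-way ANOVA when normal,
Mann-Whitney U / Kruskal-Wallis otherwise); contingency tables use
chi-square, or Fisher's exact test for 2×2 tables with an expected cell
below 5; scar burden is modelled by OLS with a pairwise collinearity
screen (|r| > 0.7 excludes a candidate and reports the offending pair);
repeated measurements are compared with Bland-Altman bias and limits of
agreement (bias ± 1.96·SD of the paired differences) plus Pearson r.

## Worked example

```python
import thoravol as tv

# a thoracic phantom with a known fat ellipsoid (~120 ml)
spec = tv.ThoracicPhantomSpec(
    fat_regions=(tv.Ellipsoid((35.0, 70.0, 76.8), (25.0, 30.0, 40.0)),),
    seed=1)
bundle = tv.make_thoracic_phantom(spec)
print(f"truth    {bundle.truth_volume_ml:.2f} ml")

res = tv.quantify_fat(bundle.mr, bundle.thoracic_contours,
                      bundle.muscle_rois, k=10, bmi=30.0)
print(f"measured {res.volume_ml:.2f} ml at threshold {res.threshold:.1f}")
print(f"indexed  {res.indexed_volume:.2f} ml per kg/m^2")

# a paired MR/CT phantom constructed so the best multiplier is 10
pair = tv.make_calibration_pair(seed=1)
cal = tv.calibrate_k(pair.mr, pair.ct, pair.thoracic_contours,
                     pair.muscle_rois)
print(f"calibrated k = {cal.selected_k:g} "
      f"(peak Dice {max(cal.mean_dice_per_k):.3f})")
```

prints

```
truth    120.47 ml
measured 120.47 ml at threshold 152.2
indexed  4.02 ml per kg/m^2
calibrated k = 10 (peak Dice 1.000)
```

The measured volume equals the voxelized truth because muscle
(N(100, 5)) and fat (N(200, 10)) are 20 muscle-SDs apart, so the 10-SD
threshold (here estimated at 152.2 from the pooled reference ROIs) misses
essentially no fat and admits essentially no muscle.  The calibration
pair additionally contains an intermediate-intensity tissue band, so the
Dice sweep against the CT fat window has a unique peak, at k = 10.

A configuration-driven end-to-end run (per-subject phantoms → volumetry →
scar → cohort table → statistics report):

```bash
thoravol run --config config.yaml     # or: python -m thoravol.cli ...
```

with a YAML like

```yaml
mode: synthetic
n_per_group: 50
seed: 3
output_dir: out/
```

which writes `subjects/*.json`, `cohort.csv`, `stats_report.json` and
`run.log` (byte-identical across reruns with the same config and seed).
Subcommands `itfv`, `calibrate`, `scar`, `compare`, `regress` and
`agreement` expose the individual stages on NIfTI/JSON/CSV inputs.

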