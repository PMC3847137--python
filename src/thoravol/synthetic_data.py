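"""Synthetic phantoms and cohorts with known ground truth.

Three generators make every downstream stage testable without patient data:

* :func:`make_thoracic_phantom` — a sagittal fat-bright MR stack with a
  co-registered CT, a rectangular intra-thoracic contour per slice,
  paravertebral-muscle reference ROIs, and an exact voxel-level fat truth
  mask.  Tissue compartments are muscle, fat (ellipsoids), optional bright
  non-fat tissue, and background; MR signal is Gaussian per compartment
  (clipped at 0), CT attenuation uniform within per-tissue HU ranges with
  adipose tissue inside the conventional -190..-30 HU window.
* :func:`make_lv_phantom` — a short-axis LGE stack whose myocardium is an
  annulus between concentric endo/epi contours, with a contiguous
  subendocardial scar sector of an exact voxel fraction and a reference ROI
  in remote myocardium.
* :func:`simulate_cohort` — a four-cell cohort (MetS-/MI-, MetS+/MI-,
  MetS-/MI+, MetS+/MI+) whose indexed-ITFV, BMI, scar and covariate
  distributions default to the study's group summaries; scar in the MI+
  cells is linearly coupled to indexed ITFV so regression recovery is
  testable.

All generators are deterministic for a fixed spec + seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .imaging_core import (
    MODALITY_CT,
    MODALITY_MR,
    BinaryMask,
    CircularROI,
    PlanarContour,
    VoxelGrid,
    rasterize_contour,
    roi_disc_pixels,
)

# the four study cells, in the order used everywhere downstream
GROUPS = ("MetS-/MI-", "MetS+/MI-", "MetS-/MI+", "MetS+/MI+")
MI_POSITIVE_GROUPS = ("MetS-/MI+", "MetS+/MI+")


# ---------------------------------------------------------------------------
# Thoracic MR/CT phantom
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Ellipsoid:
    """Axis-aligned ellipsoid in physical coordinates.

    ``center_mm`` and ``semi_axes_mm`` are ordered (slice-axis, row-axis,
    col-axis); the voxel at index (s, r, c) sits at physical position
    (s*dz, r*dr, c*dc).
    """

    center_mm: tuple[float, float, float]
    semi_axes_mm: tuple[float, float, float]

    def __post_init__(self) -> None:
        if any(a <= 0 for a in self.semi_axes_mm):
            raise ValueError("semi-axes must be > 0")

    def volume_ml(self) -> float:
        a, b, c = self.semi_axes_mm
        return 4.0 / 3.0 * math.pi * a * b * c / 1000.0


@dataclass
class ThoracicPhantomSpec:
    """Parameters of the paired MR/CT thoracic phantom.

    MR signal statistics default to muscle N(100, 5) and fat N(200, 10) —
    a 20-sigma separation in muscle units, comfortably past the 10-SD
    operating point — with dim background.  Geometry defaults to the
    sagittal survey: 8 mm slices with a 2 mm gap and 1.6 mm in-plane
    pixels.  ``fat_signal_range`` / ``bright_signal_range``, when set,
    replace the Gaussian draw of that compartment with a uniform draw over
    an absolute signal interval (used to construct calibration phantoms
    whose optimal multiplier is known).
    """

    grid_shape: tuple[int, int, int] = (8, 96, 96)
    pixel_spacing_mm: tuple[float, float] = (1.6, 1.6)
    slice_thickness_mm: float = 8.0
    slice_gap_mm: float = 2.0
    muscle_mean: float = 100.0
    muscle_sd: float = 5.0
    fat_mean: float = 200.0
    fat_sd: float = 10.0
    background_mean: float = 20.0
    background_sd: float = 10.0
    fat_regions: tuple[Ellipsoid, ...] = ()
    bright_regions: tuple[Ellipsoid, ...] = ()
    fat_signal_range: tuple[float, float] | None = None
    bright_signal_range: tuple[float, float] | None = None
    thoracic_contour_margin_px: int = 8
    ct_fat_hu_range: tuple[float, float] = (-190.0, -30.0)
    ct_muscle_hu_range: tuple[float, float] = (35.0, 55.0)
    ct_air_hu: float = -1000.0
    n_muscle_rois: int = 5
    roi_diameter_mm: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fat_mean <= self.muscle_mean:
            raise ValueError("fat_mean must exceed muscle_mean (fat is bright)")
        for sd in (self.muscle_sd, self.fat_sd, self.background_sd):
            if sd < 0:
                raise ValueError("SDs must be >= 0")
        if self.ct_fat_hu_range[0] >= self.ct_fat_hu_range[1]:
            raise ValueError("ct_fat_hu_range must be (low, high) with low < high")


@dataclass
class PhantomBundle:
    """A generated phantom with its analysis inputs and ground truth."""

    mr: VoxelGrid
    ct: VoxelGrid
    thoracic_contours: list[PlanarContour]
    muscle_rois: list[CircularROI]
    fat_truth: BinaryMask

    @property
    def truth_volume_ml(self) -> float:
        return self.fat_truth.count() * self.mr.voxel_volume_mm3 / 1000.0


def _rect_contour(slice_index: int, rows: int, cols: int, margin: int) -> PlanarContour:
    m = margin
    return PlanarContour(slice_index, np.array([
        [m - 0.5, m - 0.5],
        [m - 0.5, cols - m - 0.5],
        [rows - m - 0.5, cols - m - 0.5],
        [rows - m - 0.5, m - 0.5],
    ]))


def _ellipsoid_mask(regions: Sequence[Ellipsoid],
                    shape: tuple[int, int, int],
                    dz: float, dr: float, dc: float) -> np.ndarray:
    n_s, n_r, n_c = shape
    zz = np.arange(n_s)[:, None, None] * dz
    yy = np.arange(n_r)[None, :, None] * dr
    xx = np.arange(n_c)[None, None, :] * dc
    mask = np.zeros(shape, dtype=bool)
    for ell in regions:
        cz, cy, cx = ell.center_mm
        az, ay, ax = ell.semi_axes_mm
        mask |= (((zz - cz) / az) ** 2
                 + ((yy - cy) / ay) ** 2
                 + ((xx - cx) / ax) ** 2) <= 1.0
    return mask


def make_thoracic_phantom(spec: ThoracicPhantomSpec) -> PhantomBundle:
    """Generate a paired MR/CT thoracic phantom with exact fat truth.

    Raises if a fat or bright-tissue ellipsoid extends outside the traced
    thoracic region, or if a reference ROI cannot be placed on pure muscle.
    """
    rng = np.random.default_rng(spec.seed)
    n_s, n_r, n_c = spec.grid_shape
    dr, dc = spec.pixel_spacing_mm
    dz = spec.slice_thickness_mm + spec.slice_gap_mm
    m = spec.thoracic_contour_margin_px

    contours = [_rect_contour(s, n_r, n_c, m) for s in range(n_s)]
    interior = np.zeros(spec.grid_shape, dtype=bool)
    interior[:, m:n_r - m, m:n_c - m] = True

    fat = _ellipsoid_mask(spec.fat_regions, spec.grid_shape, dz, dr, dc)
    bright = _ellipsoid_mask(spec.bright_regions, spec.grid_shape, dz, dr, dc)
    if np.any(fat & ~interior) or np.any(bright & ~interior):
        raise ValueError("ellipsoid outside thoracic contour")
    if np.any(fat & bright):
        raise ValueError("fat and bright-tissue regions overlap")
    muscle = interior & ~fat & ~bright

    # MR: Gaussian per compartment (clipped at 0), or uniform over an
    # absolute signal range when the spec pins a compartment's range.
    mr_vals = rng.normal(spec.background_mean, spec.background_sd, spec.grid_shape)
    mr_vals[muscle] = rng.normal(spec.muscle_mean, spec.muscle_sd, int(muscle.sum()))
    if spec.fat_signal_range is not None:
        lo, hi = spec.fat_signal_range
        mr_vals[fat] = rng.uniform(lo, hi, int(fat.sum()))
    else:
        mr_vals[fat] = rng.normal(spec.fat_mean, spec.fat_sd, int(fat.sum()))
    if bright.any():
        if spec.bright_signal_range is None:
            raise ValueError("bright_regions given without bright_signal_range")
        lo, hi = spec.bright_signal_range
        mr_vals[bright] = rng.uniform(lo, hi, int(bright.sum()))
    mr_vals = np.clip(mr_vals, 0.0, None)

    # CT: uniform HU per tissue; background is air.
    ct_vals = np.full(spec.grid_shape, spec.ct_air_hu, dtype=float)
    soft = muscle | bright
    ct_vals[soft] = rng.uniform(*spec.ct_muscle_hu_range, int(soft.sum()))
    ct_vals[fat] = rng.uniform(*spec.ct_fat_hu_range, int(fat.sum()))

    mr = VoxelGrid(mr_vals, (dr, dc), spec.slice_thickness_mm,
                   spec.slice_gap_mm, MODALITY_MR)
    ct = VoxelGrid(ct_vals, (dr, dc), spec.slice_thickness_mm,
                   spec.slice_gap_mm, MODALITY_CT)
    truth = BinaryMask(fat, provenance="phantom fat truth")

    rois = _place_muscle_rois(spec, mr, muscle)
    return PhantomBundle(mr=mr, ct=ct, thoracic_contours=contours,
                         muscle_rois=rois, fat_truth=truth)


def _place_muscle_rois(spec: ThoracicPhantomSpec, mr: VoxelGrid,
                       muscle: np.ndarray) -> list[CircularROI]:
    """Reference ROIs in the posterior muscle band, disjoint from fat.

    ROI discs are placed on each slice near the posterior contour edge
    (the paravertebral band) at evenly spaced columns, backing anteriorly
    row by row until the disc covers pure muscle.
    """
    n_s, n_r, n_c = spec.grid_shape
    dr, dc = spec.pixel_spacing_mm
    m = spec.thoracic_contour_margin_px
    rad_r = spec.roi_diameter_mm / 2.0 / dr
    rad_c = spec.roi_diameter_mm / 2.0 / dc
    cols = np.linspace(m + rad_c + 1, n_c - 1 - m - rad_c - 1,
                       spec.n_muscle_rois)
    rois: list[CircularROI] = []
    for s in range(n_s):
        for col in cols:
            placed = False
            row = n_r - 1 - m - rad_r - 1
            while row > m + rad_r:
                roi = CircularROI(s, (float(row), float(col)), spec.roi_diameter_mm)
                disc = roi_disc_pixels(roi, mr)
                if np.all(muscle[s][disc]):
                    rois.append(roi)
                    placed = True
                    break
                row -= 1
            if not placed:
                raise ValueError(
                    f"cannot place a pure-muscle reference ROI on slice {s}")
    return rois


def make_calibration_pair(seed: int = 0,
                          grid_shape: tuple[int, int, int] = (6, 64, 64),
                          muscle_mean: float = 100.0,
                          muscle_sd: float = 5.0) -> PhantomBundle:
    """Paired MR/CT phantom whose best MR threshold multiplier is 10.

    Fat MR signal is drawn uniformly on [mu + 10.6 sigma, mu + 14 sigma],
    so thresholds at k <= 10 capture all fat while k = 11, 12, ... start
    cutting into it.  A bright non-fat tissue region (emulating
    intermediate-intensity structures such as vessels and partial-volume
    pixels) spans [mu + 4 sigma, mu + 9.4 sigma], so thresholds below 10
    admit false-positive tissue.  On CT only the true fat falls inside the
    -190..-30 HU window, hence Dice agreement against the CT segmentation
    peaks at the construction multiplier k = 10.  The +/- 0.6 sigma guard
    bands around the operating point absorb the sampling error of the
    estimated threshold given the reference pixel count used here
    (8 ROIs of 9.6 mm per slice, ~1300 pooled pixels).
    """
    n_s, n_r, n_c = grid_shape
    dr = dc = 1.6
    dz = 10.0
    cy = (n_r - 1) / 2 * dr
    cx = (n_c - 1) / 2 * dc
    cz = (n_s - 1) / 2 * dz
    extent_r = (n_r - 2 * 8) * dr / 2  # interior half-extent at margin 8
    fat = (Ellipsoid((cz, cy - extent_r * 0.35, cx), (dz * n_s / 2.2,
                                                      extent_r * 0.42,
                                                      extent_r * 0.62)),)
    bright = (Ellipsoid((cz, cy + extent_r * 0.35, cx - extent_r * 0.3),
                        (dz * n_s / 2.4, extent_r * 0.30, extent_r * 0.45)),)
    spec = ThoracicPhantomSpec(
        grid_shape=grid_shape,
        pixel_spacing_mm=(dr, dc),
        slice_thickness_mm=8.0,
        slice_gap_mm=2.0,
        muscle_mean=muscle_mean,
        muscle_sd=muscle_sd,
        fat_regions=fat,
        bright_regions=bright,
        fat_signal_range=(muscle_mean + 10.6 * muscle_sd,
                          muscle_mean + 14.0 * muscle_sd),
        bright_signal_range=(muscle_mean + 4.0 * muscle_sd,
                             muscle_mean + 9.4 * muscle_sd),
        n_muscle_rois=8,
        roi_diameter_mm=9.6,
        seed=seed,
    )
    return make_thoracic_phantom(spec)


# ---------------------------------------------------------------------------
# LV LGE phantom
# ---------------------------------------------------------------------------

@dataclass
class LVPhantom:
    lge: VoxelGrid
    endo_contours: list[PlanarContour]
    epi_contours: list[PlanarContour]
    reference_region: CircularROI
    scar_truth: BinaryMask
    myocardium_truth: BinaryMask

    @property
    def true_scar_fraction(self) -> float:
        n_myo = self.myocardium_truth.count()
        return self.scar_truth.count() / n_myo if n_myo else 0.0


def _circle_contour(slice_index: int, center_rc: tuple[float, float],
                    radius_px: float, n_vertices: int = 96) -> PlanarContour:
    theta = np.linspace(0.0, 2.0 * np.pi, n_vertices, endpoint=False)
    verts = np.stack([center_rc[0] + radius_px * np.sin(theta),
                      center_rc[1] + radius_px * np.cos(theta)], axis=1)
    return PlanarContour(slice_index, verts)


def make_lv_phantom(scar_fraction: float,
                    remote_mean: float = 100.0,
                    remote_sd: float = 5.0,
                    scar_mean: float = 160.0,
                    seed: int = 0,
                    n_slices: int = 4,
                    plane_shape: tuple[int, int] = (128, 128),
                    pixel_spacing_mm: tuple[float, float] = (1.5, 1.5),
                    slice_thickness_mm: float = 6.0,
                    slice_gap_mm: float = 4.0,
                    endo_radius_px: float = 18.0,
                    epi_radius_px: float = 30.0,
                    scar_start_angle: float = 0.3,
                    reference_diameter_mm: float = 6.0) -> LVPhantom:
    """Short-axis LGE stack with a scar sector of an exact voxel fraction.

    The myocardium is the annulus between concentric circular endo/epi
    contours on each slice.  Scar voxels are the annulus voxels falling in
    a contiguous angular sector starting subendocardially at
    ``scar_start_angle``; the sector is sized by voxel count so the true
    scar fraction matches ``scar_fraction`` up to rounding.  Remote
    myocardium is N(remote_mean, remote_sd); scar is N(scar_mean,
    remote_sd); blood pool is bright (near scar intensity).
    """
    if not 0.0 <= scar_fraction <= 1.0:
        raise ValueError("scar_fraction must be in [0, 1]")
    if scar_fraction > 0 and not scar_mean > remote_mean + 5.0 * remote_sd:
        raise ValueError("scar_mean must exceed remote_mean + 5*remote_sd")
    if epi_radius_px <= endo_radius_px:
        raise ValueError("degenerate annulus: epi radius must exceed endo radius")
    rng = np.random.default_rng(seed)
    n_r, n_c = plane_shape
    shape = (n_slices, n_r, n_c)
    center = ((n_r - 1) / 2.0, (n_c - 1) / 2.0)

    endo = [_circle_contour(s, center, endo_radius_px) for s in range(n_slices)]
    epi = [_circle_contour(s, center, epi_radius_px) for s in range(n_slices)]

    myo = np.zeros(shape, dtype=bool)
    scar = np.zeros(shape, dtype=bool)
    for s in range(n_slices):
        epi_m = rasterize_contour(epi[s], shape).values[s]
        endo_m = rasterize_contour(endo[s], shape).values[s]
        annulus = epi_m & ~endo_m
        myo[s] = annulus
        if scar_fraction > 0:
            rr, cc = np.nonzero(annulus)
            ang = np.mod(np.arctan2(rr - center[0], cc - center[1])
                         - scar_start_angle, 2.0 * np.pi)
            order = np.argsort(ang, kind="stable")
            n_scar = int(round(scar_fraction * len(rr)))
            sel = order[:n_scar]
            scar[s, rr[sel], cc[sel]] = True

    blood = np.zeros(shape, dtype=bool)
    for s in range(n_slices):
        blood[s] = rasterize_contour(endo[s], shape).values[s]

    vals = np.abs(rng.normal(5.0, 2.0, shape))
    vals[blood] = rng.normal(scar_mean * 0.9, remote_sd + 1.0, int(blood.sum()))
    vals[myo] = rng.normal(remote_mean, remote_sd, int(myo.sum()))
    vals[scar] = rng.normal(scar_mean, remote_sd, int(scar.sum()))
    vals = np.clip(vals, 0.0, None)

    lge = VoxelGrid(vals, pixel_spacing_mm, slice_thickness_mm,
                    slice_gap_mm, MODALITY_MR)

    # remote reference ROI at mid-wall, diametrically opposite the scar
    # sector's center
    sector_center = scar_start_angle + math.pi * scar_fraction
    ref_angle = sector_center + math.pi
    mid_r = (endo_radius_px + epi_radius_px) / 2.0
    ref_center = (center[0] + mid_r * math.sin(ref_angle),
                  center[1] + mid_r * math.cos(ref_angle))
    ref = CircularROI(0, ref_center, reference_diameter_mm)
    disc = roi_disc_pixels(ref, lge)
    if not np.all(myo[0][disc]):
        raise ValueError("reference ROI falls outside the myocardial annulus")
    if scar_fraction <= 0.75 and np.any(scar[0][disc]):
        raise ValueError("reference ROI overlaps scar")

    return LVPhantom(lge=lge, endo_contours=endo, epi_contours=epi,
                     reference_region=ref,
                     scar_truth=BinaryMask(scar, "phantom scar truth"),
                     myocardium_truth=BinaryMask(myo, "phantom myocardium"))


# ---------------------------------------------------------------------------
# Cohort simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GroupParams:
    """Per-cell distributional parameters of the synthetic cohort.

    BMI SDs are back-calculated from the reported 95% confidence intervals
    of the group means (sd = half-width * sqrt(n) / 1.96).
    """

    n: int
    indexed_itfv_mean: float
    indexed_itfv_sd: float
    bmi_mean: float
    bmi_sd: float
    age_mean: float
    age_sd: float
    female_prop: float
    caucasian_prop: float
    diabetes_prop: float
    hypertension_prop: float
    gfr_mean: float
    gfr_sd: float
    waist_mean: float
    waist_sd: float
    scar_mean: float | None = None  # % LV mass; None for MI- cells

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("each group needs n >= 2")
        for sd in (self.indexed_itfv_sd, self.bmi_sd, self.age_sd,
                   self.gfr_sd, self.waist_sd):
            if sd < 0:
                raise ValueError("SDs must be >= 0")


DEFAULT_GROUP_PARAMS: dict[str, GroupParams] = {
    "MetS-/MI-": GroupParams(n=16, indexed_itfv_mean=22.3, indexed_itfv_sd=10.6,
                             bmi_mean=22.9, bmi_sd=2.35, age_mean=42.3,
                             age_sd=16.9, female_prop=0.44, caucasian_prop=0.62,
                             diabetes_prop=0.0, hypertension_prop=0.0,
                             gfr_mean=94.0, gfr_sd=18.0,
                             waist_mean=88.7, waist_sd=25.0),
    "MetS+/MI-": GroupParams(n=32, indexed_itfv_mean=28.6, indexed_itfv_sd=12.6,
                             bmi_mean=32.5, bmi_sd=6.49, age_mean=62.0,
                             age_sd=10.2, female_prop=0.23, caucasian_prop=0.81,
                             diabetes_prop=0.45, hypertension_prop=0.77,
                             gfr_mean=81.0, gfr_sd=23.0,
                             waist_mean=119.9, waist_sd=9.0),
    "MetS-/MI+": GroupParams(n=30, indexed_itfv_mean=30.6, indexed_itfv_sd=12.3,
                             bmi_mean=26.0, bmi_sd=4.19, age_mean=60.1,
                             age_sd=11.4, female_prop=0.14, caucasian_prop=0.79,
                             diabetes_prop=0.07, hypertension_prop=0.45,
                             gfr_mean=78.0, gfr_sd=20.0,
                             waist_mean=106.4, waist_sd=14.3,
                             scar_mean=21.1),
    "MetS+/MI+": GroupParams(n=32, indexed_itfv_mean=35.2, indexed_itfv_sd=11.4,
                             bmi_mean=30.4, bmi_sd=4.76, age_mean=58.7,
                             age_sd=14.8, female_prop=0.09, caucasian_prop=0.79,
                             diabetes_prop=0.42, hypertension_prop=0.70,
                             gfr_mean=76.0, gfr_sd=21.0,
                             waist_mean=116.0, waist_sd=11.0,
                             scar_mean=21.0),
}


@dataclass
class CohortSpec:
    """Four-cell cohort specification.

    ``scar_slope`` couples scar %LV to indexed ITFV among MI+ subjects:
    scar = intercept_g + scar_slope * indexed_itfv + N(0, noise_sd_scar),
    with intercept_g chosen per group so the group scar mean matches its
    ``scar_mean``.  ``waist_itfv_corr`` induces the waist-circumference
    collinearity with indexed ITFV.  Non-negative quantities (indexed ITFV,
    scar %) are truncated at 0 by resampling, which preserves approximate
    normality near the bulk.
    """

    groups: dict[str, GroupParams] = field(
        default_factory=lambda: dict(DEFAULT_GROUP_PARAMS))
    scar_slope: float = 0.8
    noise_sd_scar: float = 11.5
    waist_itfv_corr: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        unknown = set(self.groups) - set(GROUPS)
        if unknown:
            raise ValueError(f"unknown group label(s): {sorted(unknown)}")
        if set(self.groups) != set(GROUPS):
            raise ValueError("spec must define exactly the four study cells")
        if self.noise_sd_scar < 0:
            raise ValueError("noise_sd_scar must be >= 0")
        if not -1.0 <= self.waist_itfv_corr <= 1.0:
            raise ValueError("waist_itfv_corr must be in [-1, 1]")


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      n: int, low: float = 0.0) -> np.ndarray:
    """Normal draws resampled (not clipped) until all >= low."""
    if sd == 0:
        if mean < low:
            raise ValueError("degenerate truncated normal: mean below bound")
        return np.full(n, mean)
    out = rng.normal(mean, sd, n)
    for _ in range(1000):
        bad = out < low
        if not bad.any():
            return out
        out[bad] = rng.normal(mean, sd, int(bad.sum()))
    raise RuntimeError("truncation resampling failed to converge")


def simulate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Draw a synthetic cohort table; deterministic for a fixed spec+seed.

    Columns: id, group, bmi, itfv_ml, indexed_itfv, scar_pct (NaN for
    MI- cells), age, sex, race, diabetes, gfr, waist_cm, hypertension.
    """
    rng = np.random.default_rng(spec.seed)
    rows = []
    subj = 0
    for label in GROUPS:
        gp = spec.groups[label]
        idx_itfv = _truncated_normal(rng, gp.indexed_itfv_mean,
                                     gp.indexed_itfv_sd, gp.n)
        bmi = _truncated_normal(rng, gp.bmi_mean, gp.bmi_sd, gp.n, low=12.0)
        age = _truncated_normal(rng, gp.age_mean, gp.age_sd, gp.n, low=18.0)
        gfr = _truncated_normal(rng, gp.gfr_mean, gp.gfr_sd, gp.n, low=5.0)
        female = rng.random(gp.n) < gp.female_prop
        caucasian = rng.random(gp.n) < gp.caucasian_prop
        diabetes = rng.random(gp.n) < gp.diabetes_prop
        hypertension = rng.random(gp.n) < gp.hypertension_prop

        # waist shares a standardized component with indexed ITFV
        rho = spec.waist_itfv_corr
        z_itfv = ((idx_itfv - gp.indexed_itfv_mean) / gp.indexed_itfv_sd
                  if gp.indexed_itfv_sd > 0 else np.zeros(gp.n))
        z_new = rng.standard_normal(gp.n)
        waist = (gp.waist_mean
                 + gp.waist_sd * (rho * z_itfv + math.sqrt(1 - rho ** 2) * z_new))

        if gp.scar_mean is not None:
            intercept = gp.scar_mean - spec.scar_slope * gp.indexed_itfv_mean
            raw = (intercept + spec.scar_slope * idx_itfv
                   + rng.normal(0.0, spec.noise_sd_scar, gp.n))
            # resample only the noise term for negative draws
            for _ in range(1000):
                bad = raw < 0
                if not bad.any():
                    break
                raw[bad] = (intercept + spec.scar_slope * idx_itfv[bad]
                            + rng.normal(0.0, spec.noise_sd_scar, int(bad.sum())))
            scar = np.minimum(raw, 100.0)
        else:
            scar = np.full(gp.n, np.nan)

        for i in range(gp.n):
            rows.append({
                "id": f"S{subj:04d}",
                "group": label,
                "bmi": bmi[i],
                "itfv_ml": idx_itfv[i] * bmi[i],
                "indexed_itfv": idx_itfv[i],
                "scar_pct": scar[i],
                "age": age[i],
                "sex": "F" if female[i] else "M",
                "race": "Caucasian" if caucasian[i] else "Other",
                "diabetes": bool(diabetes[i]),
                "gfr": gfr[i],
                "waist_cm": waist[i],
                "hypertension": bool(hypertension[i]),
            })
            subj += 1
    return pd.DataFrame(rows)
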