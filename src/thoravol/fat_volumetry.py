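"""Reference-normalized threshold volumetry of intra-thoracic fat.

The measurement chain mirrors how intra-thoracic fat volume (ITFV) is
quantified on fat-bright sagittal MR stacks:

1. :func:`reference_stats` pools the pixels of several paravertebral-muscle
   ROIs into one reference population with mean ``mu_ref`` and SD
   ``sigma_ref``.
2. :func:`fat_threshold` forms the signal threshold ``mu_ref + k * sigma_ref``
   (default multiplier ``k = 10``).
3. :func:`segment_fat` marks, inside the manually traced intra-thoracic
   contour of each slice, every pixel whose signal is ``>=`` the threshold.
4. :func:`itfv` sums fat areas over slices and multiplies by the slice
   spacing to give a volume in ml; :func:`index_itfv` divides by BMI.

Reference pooling treats the pixels of all ROIs as a single population
(rather than averaging per-ROI means): it uses all information and is
deterministic.  SDs use the n-1 denominator throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .imaging_core import (
    MODALITY_MR,
    BinaryMask,
    CircularROI,
    PlanarContour,
    VoxelGrid,
    rasterize_contour,
    roi_pixels,
)

logger = logging.getLogger("thoravol")

#: default SD multiplier for fat segmentation on fat-bright MR
DEFAULT_K_FAT = 10.0

SliceIntegration = Literal["spacing", "thickness"]


@dataclass
class ReferenceStats:
    """Pooled mean/SD of the reference-tissue pixel population."""

    mean: float
    sd: float
    n_pixels: int
    n_rois: int

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("sd must be >= 0")
        if not (self.n_pixels >= self.n_rois >= 1):
            raise ValueError("need n_pixels >= n_rois >= 1")


@dataclass
class FatSegmentationResult:
    """Output bundle of a full fat-volumetry run on one subject/stack."""

    mask: BinaryMask
    threshold: float
    k: float
    per_slice_area_mm2: list[float]
    volume_ml: float
    indexed_volume: float | None = None  # ml per kg/m^2, set when BMI known


def reference_stats(grid: VoxelGrid, rois: Sequence[CircularROI]) -> ReferenceStats:
    """Pooled mean and SD over the pixels of all reference ROIs.

    All ROI pixel values are concatenated into one population; the SD uses
    the n-1 denominator.
    """
    if len(rois) == 0:
        raise ValueError("empty ROI list")
    pooled = np.concatenate([roi_pixels(roi, grid) for roi in rois]).astype(float)
    if pooled.size < 2:
        raise ValueError("reference ROIs cover fewer than 2 pixels")
    return ReferenceStats(mean=float(pooled.mean()),
                          sd=float(pooled.std(ddof=1)),
                          n_pixels=int(pooled.size),
                          n_rois=len(rois))


def fat_threshold(stats: ReferenceStats, k: float = DEFAULT_K_FAT) -> float:
    """Signal threshold ``mean + k * sd`` above the reference tissue."""
    if k <= 0:
        raise ValueError("k must be > 0")
    return stats.mean + k * stats.sd


def segment_fat(grid: VoxelGrid,
                contours: Sequence[PlanarContour],
                threshold: float) -> BinaryMask:
    """Threshold segmentation restricted to the traced thoracic region.

    A pixel is fat iff its center lies inside its slice's contour AND its
    signal is ``>= threshold`` (inclusive).  Slices without a contour are
    skipped with a logged warning, matching an incompletely traced stack.
    """
    if grid.modality != MODALITY_MR:
        raise ValueError("segment_fat expects an MR grid")
    by_slice: dict[int, PlanarContour] = {}
    for ct in contours:
        if ct.slice_index in by_slice:
            raise ValueError(f"multiple contours for slice {ct.slice_index}")
        by_slice[ct.slice_index] = ct
    mask = np.zeros(grid.shape, dtype=bool)
    for s in range(grid.shape[0]):
        ct = by_slice.get(s)
        if ct is None:
            logger.warning("slice %d has no contour; skipped", s)
            continue
        region = rasterize_contour(ct, grid.shape).values[s]
        mask[s] = region & (grid.values[s] >= threshold)
    return BinaryMask(mask, provenance=f"fat>= {threshold:g}")


def itfv(mask: BinaryMask,
         grid: VoxelGrid,
         slice_integration: SliceIntegration = "spacing") -> float:
    """Total fat volume in ml from a fat mask.

    The fat area of each slice (true-pixel count x in-plane pixel area) is
    summed over slices and multiplied by the slice extent.  With
    ``slice_integration="spacing"`` (default) each slice represents a slab
    of thickness+gap; ``"thickness"`` uses the acquired thickness only and
    ignores the gap.
    """
    if mask.shape != grid.shape:
        raise ValueError(f"shape mismatch: mask {mask.shape} vs grid {grid.shape}")
    sr, sc = grid.pixel_spacing_mm
    if slice_integration == "spacing":
        dz = grid.effective_slice_spacing_mm
    elif slice_integration == "thickness":
        dz = grid.slice_thickness_mm
    else:
        raise ValueError(f"unknown slice_integration {slice_integration!r}")
    per_slice_counts = mask.values.reshape(mask.shape[0], -1).sum(axis=1)
    return float(per_slice_counts.sum() * sr * sc * dz / 1000.0)


def per_slice_areas_mm2(mask: BinaryMask, grid: VoxelGrid) -> list[float]:
    sr, sc = grid.pixel_spacing_mm
    counts = mask.values.reshape(mask.shape[0], -1).sum(axis=1)
    return [float(n * sr * sc) for n in counts]


def index_itfv(volume_ml: float, bmi: float) -> float:
    """ITFV indexed to body mass index, in ml per kg/m^2."""
    if bmi <= 0:
        raise ValueError("BMI must be > 0")
    return volume_ml / bmi


def quantify_fat(grid: VoxelGrid,
                 contours: Sequence[PlanarContour],
                 rois: Sequence[CircularROI],
                 k: float = DEFAULT_K_FAT,
                 bmi: float | None = None,
                 slice_integration: SliceIntegration = "spacing",
                 ) -> FatSegmentationResult:
    """Run the full chain: reference stats -> threshold -> mask -> volume."""
    stats = reference_stats(grid, rois)
    thr = fat_threshold(stats, k)
    mask = segment_fat(grid, contours, thr)
    volume = itfv(mask, grid, slice_integration)
    return FatSegmentationResult(
        mask=mask,
        threshold=thr,
        k=k,
        per_slice_area_mm2=per_slice_areas_mm2(mask, grid),
        volume_ml=volume,
        indexed_volume=None if bmi is None else index_itfv(volume, bmi),
    )
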