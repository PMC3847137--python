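"""STRM late-enhancement scar quantification.

Signal-Threshold-versus-Reference-Myocardium (STRM): the myocardium is the
annulus between manually traced endocardial and epicardial contours; a
reference ROI in the largest contiguous region of normal (remote)
myocardium provides mean and SD; every myocardial voxel with signal
``>= mean + k*SD`` (default k = 5) is scar; scar burden is reported as a
percentage of LV mass.  Because tissue density is uniform, the voxel-count
ratio equals the mass ratio, so no absolute mass is needed.

One reference region parameterizes the whole stack.  The reference ROI is
supplied explicitly (mirroring the manual tracing step), not auto-detected.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import shapely

from .imaging_core import (
    BinaryMask,
    CircularROI,
    PlanarContour,
    VoxelGrid,
    rasterize_contour,
    roi_disc_pixels,
)
from .fat_volumetry import ReferenceStats, fat_threshold

#: default SD multiplier for scar detection
DEFAULT_K_SCAR = 5.0


@dataclass
class MyocardialGeometry:
    """Per-slice endo/epi contours plus one remote-myocardium reference ROI."""

    endo_contours: list[PlanarContour]
    epi_contours: list[PlanarContour]
    reference_region: CircularROI

    def __post_init__(self) -> None:
        if len(self.endo_contours) != len(self.epi_contours):
            raise ValueError("need one endo and one epi contour per slice")
        for endo, epi in zip(self.endo_contours, self.epi_contours):
            if endo.slice_index != epi.slice_index:
                raise ValueError("endo/epi contour slice indices must match")
            if not shapely.contains_properly(epi.polygon, endo.polygon):
                raise ValueError(
                    f"endo contour not strictly inside epi on slice {endo.slice_index}")

    @property
    def slice_indices(self) -> list[int]:
        return [c.slice_index for c in self.endo_contours]


def myocardium_mask(geom: MyocardialGeometry,
                    grid_shape: tuple[int, int, int]) -> BinaryMask:
    """Annular myocardial mask: epi region minus endo region per slice."""
    mask = np.zeros(grid_shape, dtype=bool)
    for endo, epi in zip(geom.endo_contours, geom.epi_contours):
        s = endo.slice_index
        epi_m = rasterize_contour(epi, grid_shape).values[s]
        endo_m = rasterize_contour(endo, grid_shape).values[s]
        annulus = epi_m & ~endo_m
        if not annulus.any():
            raise ValueError(f"degenerate (empty) annulus on slice {s}")
        mask[s] = annulus
    return BinaryMask(mask, provenance="myocardium (epi - endo)")


def reference_myocardium_stats(lge: VoxelGrid,
                               geom: MyocardialGeometry) -> ReferenceStats:
    """Mean/SD of the remote-myocardium reference region (one ROI, whole stack)."""
    roi = geom.reference_region
    annulus = myocardium_mask(geom, lge.shape)
    disc = roi_disc_pixels(roi, lge)
    if not np.all(annulus.values[roi.slice_index][disc]):
        raise ValueError("reference region extends outside the myocardial annulus")
    vals = lge.values[roi.slice_index][disc].astype(float)
    if vals.size < 2:
        raise ValueError("reference region covers fewer than 2 pixels")
    return ReferenceStats(mean=float(vals.mean()), sd=float(vals.std(ddof=1)),
                          n_pixels=int(vals.size), n_rois=1)


def scar_percent(lge: VoxelGrid,
                 geom: MyocardialGeometry,
                 k: float = DEFAULT_K_SCAR) -> float:
    """Scar burden as % of LV mass at threshold ``reference mean + k*SD``."""
    if k <= 0:
        raise ValueError("k must be > 0")
    annulus = myocardium_mask(geom, lge.shape)
    n_myo = annulus.count()
    if n_myo == 0:
        raise ValueError("empty myocardial annulus")
    stats = reference_myocardium_stats(lge, geom)
    threshold = fat_threshold(stats, k)
    n_scar = int((annulus.values & (lge.values >= threshold)).sum())
    return 100.0 * n_scar / n_myo
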