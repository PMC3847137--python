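"""CT-anchored calibration of the MR fat-threshold multiplier.

Adipose tissue has a calibrated CT attenuation window (conventionally
-190 to -30 HU), so a co-registered CT segmentation serves as the anchor
for choosing the MR multiplier ``k`` in the ``mu + k*sigma`` threshold:
the MR segmentation is swept over a grid of multipliers and the one whose
per-slice Dice agreement with the CT segmentation is highest is selected
(ties resolved toward the smaller, more inclusive multiplier).  The Dice
coefficient is the objective surrogate for visually matching the two
segmentations side by side.

MR and CT volumes are assumed congruent (pre-registered, anatomically
matched slices); no registration is performed here.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .imaging_core import (
    MODALITY_CT,
    BinaryMask,
    CircularROI,
    PlanarContour,
    VoxelGrid,
    rasterize_contour,
)
from .fat_volumetry import fat_threshold, reference_stats, segment_fat

#: default HU window for adipose tissue on CT
DEFAULT_HU_WINDOW = (-190.0, -30.0)

#: default multiplier grid: integers bracketing the 10-SD operating point
DEFAULT_K_GRID = tuple(range(4, 17))


@dataclass
class CalibrationResult:
    k_grid: list[float]
    mean_dice_per_k: list[float]
    selected_k: float
    n_slices: int

    def __post_init__(self) -> None:
        if self.selected_k not in self.k_grid:
            raise ValueError("selected_k must be an element of k_grid")
        if any(not 0.0 <= d <= 1.0 for d in self.mean_dice_per_k):
            raise ValueError("Dice scores must lie in [0, 1]")


def segment_fat_ct(ct: VoxelGrid,
                   contours: Sequence[PlanarContour],
                   window: tuple[float, float] = DEFAULT_HU_WINDOW) -> BinaryMask:
    """HU-window fat segmentation restricted to the traced region.

    A pixel is fat iff its center is inside its slice's contour and
    ``low <= HU <= high`` (both bounds inclusive).
    """
    if ct.modality != MODALITY_CT:
        raise ValueError("segment_fat_ct expects a CT grid")
    low, high = window
    if low >= high:
        raise ValueError("window must be (low, high) with low < high")
    mask = np.zeros(ct.shape, dtype=bool)
    for contour in contours:
        region = rasterize_contour(contour, ct.shape).values[contour.slice_index]
        hu = ct.values[contour.slice_index]
        mask[contour.slice_index] = region & (hu >= low) & (hu <= high)
    return BinaryMask(mask, provenance=f"ct fat in [{low}, {high}] HU")


def dice(a: BinaryMask, b: BinaryMask) -> float:
    """Dice overlap 2|A∩B| / (|A|+|B|); 1.0 when both masks are empty."""
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    na, nb = a.count(), b.count()
    if na + nb == 0:
        return 1.0
    inter = int((a.values & b.values).sum())
    return 2.0 * inter / (na + nb)


def _dice_2d(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = int(a.sum()), int(b.sum())
    if na + nb == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / (na + nb)


def calibrate_k(mr: VoxelGrid,
                ct: VoxelGrid,
                contours: Sequence[PlanarContour],
                rois: Sequence[CircularROI],
                k_grid: Sequence[float] = DEFAULT_K_GRID,
                window: tuple[float, float] = DEFAULT_HU_WINDOW,
                ) -> CalibrationResult:
    """Sweep the MR threshold multiplier against the CT fat segmentation.

    For each ``k`` the MR stack is segmented at ``mu_ref + k*sigma_ref``
    and compared slice-by-slice with the CT HU-window segmentation; the
    Dice score is averaged over the analysed slices and the ``k`` with the
    highest mean Dice is selected (ties go to the smaller ``k``, the more
    inclusive and hence conservative choice for fat volume).
    """
    if len(k_grid) == 0:
        raise ValueError("empty k_grid")
    if mr.shape != ct.shape:
        raise ValueError("MR and CT volumes must be congruent")
    stats = reference_stats(mr, rois)
    ct_mask = segment_fat_ct(ct, contours, window)
    slices = sorted({c.slice_index for c in contours})

    ks = sorted(float(k) for k in k_grid)
    mean_dice = []
    for k in ks:
        mr_mask = segment_fat(mr, contours, fat_threshold(stats, k))
        per_slice = [_dice_2d(mr_mask.values[s], ct_mask.values[s])
                     for s in slices]
        mean_dice.append(float(np.mean(per_slice)))
    best = int(np.argmax(mean_dice))  # argmax takes the first (smallest) k on ties
    return CalibrationResult(k_grid=ks, mean_dice_per_k=mean_dice,
                             selected_k=ks[best], n_slices=len(slices))
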