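"""Core image data model, contour geometry, mask arithmetic and NIfTI I/O.

Conventions used throughout the package:

* Volumes are indexed ``(slice, row, col)``, 0-based.
* Contour and ROI coordinates are in pixel units with pixel centers at
  integer coordinates, i.e. pixel ``(r, c)`` has its center at ``(r, c)``
  and physically occupies ``[r - 0.5, r + 0.5] x [c - 0.5, c + 0.5]``.
* The effective slice spacing is ``slice_thickness_mm + slice_gap_mm``
  (center-to-center distance of adjacent slices); it is what gets stored
  as the slice zoom in NIfTI headers and used for all volume integration.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field
from typing import Iterable

import nibabel as nib
import numpy as np
from shapely.geometry import LinearRing, Polygon

logger = logging.getLogger("thoravol")

#: row offset applied to pixel centers before the even-odd test so that
#: centers lying exactly on a horizontal polygon edge are resolved
#: deterministically, independent of vertex orientation.
EDGE_EPS = 1e-9

MODALITY_MR = "MR"
MODALITY_CT = "CT"


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class VoxelGrid:
    """A 3-D scalar image with physical spacing metadata.

    Parameters
    ----------
    values
        3-D array indexed ``(slice, row, col)``.  MR signal in arbitrary
        units (non-negative) or CT attenuation in Hounsfield units.
    pixel_spacing_mm
        In-plane ``(row, col)`` spacing in millimetres.
    slice_thickness_mm
        Acquired slice thickness in millimetres.
    slice_gap_mm
        Inter-slice gap in millimetres (0 for contiguous slices).
    modality
        ``"MR"`` or ``"CT"``.  Carried as metadata, never inferred from
        the value range.
    """

    values: np.ndarray
    pixel_spacing_mm: tuple[float, float]
    slice_thickness_mm: float
    slice_gap_mm: float = 0.0
    modality: str = MODALITY_MR

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError(f"non-3-D image: got {self.values.ndim} dimensions")
        if self.values.size == 0:
            raise ValueError("empty 0-voxel grid")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("grid contains non-finite values")
        sr, sc = self.pixel_spacing_mm
        if sr <= 0 or sc <= 0 or self.slice_thickness_mm <= 0:
            raise ValueError("all spacings must be > 0")
        if self.slice_gap_mm < 0:
            raise ValueError("slice_gap_mm must be >= 0")
        if self.modality not in (MODALITY_MR, MODALITY_CT):
            raise ValueError(f"unknown modality {self.modality!r}")
        if self.modality == MODALITY_MR and self.values.min() < 0:
            raise ValueError("MR volumes must be non-negative")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def effective_slice_spacing_mm(self) -> float:
        """Center-to-center slice distance: thickness + gap."""
        return self.slice_thickness_mm + self.slice_gap_mm

    @property
    def voxel_volume_mm3(self) -> float:
        sr, sc = self.pixel_spacing_mm
        return sr * sc * self.effective_slice_spacing_mm


@dataclass
class PlanarContour:
    """A closed simple polygon delimiting an analysis region on one slice.

    Vertices are ``(row, col)`` pixel coordinates (fractional allowed) and
    the polygon is implicitly closed (last vertex connects to the first).
    """

    slice_index: int
    vertices: np.ndarray

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 2:
            raise ValueError("vertices must be an (n, 2) array of (row, col)")
        if len(self.vertices) < 3:
            raise ValueError("contour needs at least 3 vertices")
        ring = LinearRing([(c, r) for r, c in self.vertices])
        if not ring.is_simple:
            raise ValueError("self-intersecting polygon")
        if self.polygon.area <= 0:
            raise ValueError("contour encloses zero area")

    @property
    def polygon(self) -> Polygon:
        """Shapely polygon in (x=col, y=row) axes."""
        return Polygon([(c, r) for r, c in self.vertices])

    def reversed(self) -> "PlanarContour":
        return PlanarContour(self.slice_index, self.vertices[::-1].copy())


@dataclass
class BinaryMask:
    """Boolean volume congruent with a :class:`VoxelGrid`."""

    values: np.ndarray
    provenance: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=bool)
        if self.values.ndim != 3:
            raise ValueError("mask must be 3-D")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def count(self) -> int:
        return int(self.values.sum())

    def __and__(self, other: "BinaryMask") -> "BinaryMask":
        _check_congruent(self, other)
        return BinaryMask(self.values & other.values,
                          f"({self.provenance}) & ({other.provenance})")

    def __or__(self, other: "BinaryMask") -> "BinaryMask":
        _check_congruent(self, other)
        return BinaryMask(self.values | other.values,
                          f"({self.provenance}) | ({other.provenance})")

    def __sub__(self, other: "BinaryMask") -> "BinaryMask":
        _check_congruent(self, other)
        return BinaryMask(self.values & ~other.values,
                          f"({self.provenance}) - ({other.provenance})")


def _check_congruent(a: BinaryMask, b: BinaryMask) -> None:
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")


@dataclass
class CircularROI:
    """A circular region of interest with a physical diameter.

    Used for the paravertebral-muscle signal reference on MR (5-10 mm
    diameter discs) and for the remote-myocardium reference on LGE.
    """

    slice_index: int
    center: tuple[float, float]
    diameter_mm: float
    diameter_bounds_mm: tuple[float, float] = (5.0, 10.0)

    def __post_init__(self) -> None:
        lo, hi = self.diameter_bounds_mm
        if not (lo <= self.diameter_mm <= hi):
            raise ValueError(
                f"diameter {self.diameter_mm} mm outside bounds [{lo}, {hi}] mm")


# ---------------------------------------------------------------------------
# NIfTI I/O
# ---------------------------------------------------------------------------

def write_volume(grid: VoxelGrid, path: str | os.PathLike) -> None:
    """Write a :class:`VoxelGrid` to a NIfTI-1 file.

    The zooms encode ``(effective slice spacing, row spacing, col spacing)``
    and the header description carries modality / thickness / gap so a
    round-trip through :func:`read_volume` is lossless for the metadata as
    well as for the stored numeric type.
    """
    affine = np.diag([grid.effective_slice_spacing_mm,
                      grid.pixel_spacing_mm[0],
                      grid.pixel_spacing_mm[1],
                      1.0])
    img = nib.Nifti1Image(grid.values, affine)
    img.header.set_zooms((grid.effective_slice_spacing_mm,
                          grid.pixel_spacing_mm[0],
                          grid.pixel_spacing_mm[1]))
    descrip = (f"modality={grid.modality};thk={grid.slice_thickness_mm:g};"
               f"gap={grid.slice_gap_mm:g}")
    img.header["descrip"] = descrip.encode()
    nib.save(img, os.fspath(path))


def read_volume(path: str | os.PathLike, modality: str | None = None) -> VoxelGrid:
    """Read a NIfTI file into a :class:`VoxelGrid`.

    Modality, thickness and gap are recovered from the header description
    written by :func:`write_volume`; an explicit ``modality`` argument
    overrides the stored tag.  For files from other sources the first zoom
    is taken as the slice thickness with zero gap.
    """
    img = nib.load(os.fspath(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"non-3-D image: got {data.ndim} dimensions")
    # zooms are float32 in the header; round away representation noise
    zooms = [round(float(z), 6) for z in img.header.get_zooms()[:3]]
    if any(z <= 0 for z in zooms):
        raise ValueError(f"non-positive zooms {zooms}")
    meta = _parse_descrip(bytes(img.header["descrip"]).decode(errors="replace"))
    thickness = meta.get("thk", float(zooms[0]))
    gap = meta.get("gap", 0.0)
    if abs((thickness + gap) - zooms[0]) > 1e-4:
        # foreign file whose descrip does not match the zooms
        thickness, gap = float(zooms[0]), 0.0
    mod = modality or meta.get("modality") or MODALITY_MR
    return VoxelGrid(values=data,
                     pixel_spacing_mm=(float(zooms[1]), float(zooms[2])),
                     slice_thickness_mm=float(thickness),
                     slice_gap_mm=float(gap),
                     modality=str(mod))


def _parse_descrip(descrip: str) -> dict:
    out: dict = {}
    descrip = descrip.split("\x00", 1)[0]  # drop header NUL padding
    for part in descrip.split(";"):
        if "=" not in part:
            continue
        key, val = part.split("=", 1)
        key = key.strip()
        if key == "modality":
            out[key] = val.strip()
        else:
            try:
                out[key] = float(val)
            except ValueError:
                pass
    return out


# ---------------------------------------------------------------------------
# Contour rasterization and ROI sampling
# ---------------------------------------------------------------------------

def _even_odd_inside(vertices: np.ndarray, rows: int, cols: int) -> np.ndarray:
    """Even-odd (ray crossing) point-in-polygon test for all pixel centers.

    A pixel belongs to the region iff its center is strictly inside the
    polygon; centers exactly on an edge are resolved by offsetting the test
    row by ``EDGE_EPS``, which makes the result deterministic and
    independent of vertex orientation.
    """
    ys = np.arange(rows, dtype=float)[:, None] + EDGE_EPS
    xs = np.arange(cols, dtype=float)[None, :]
    inside = np.zeros((rows, cols), dtype=bool)
    v = np.asarray(vertices, dtype=float)
    nxt = np.roll(v, -1, axis=0)
    for (y1, x1), (y2, x2) in zip(v, nxt):
        crosses = (y1 > ys) != (y2 > ys)  # (rows, 1)
        if not crosses.any():
            continue
        denom = y2 - y1  # nonzero wherever crosses is true
        x_int = x1 + (ys - y1) * (x2 - x1) / np.where(denom == 0, 1.0, denom)
        inside ^= crosses & (xs < x_int)
    return inside


def rasterize_contour(contour: PlanarContour,
                      grid_shape: tuple[int, int, int]) -> BinaryMask:
    """Rasterize a closed contour into a 3-D boolean mask.

    Only the plane ``contour.slice_index`` may contain true pixels.  A
    pixel is marked iff its center lies inside the polygon under the
    even-odd rule (see :func:`_even_odd_inside`).
    """
    n_slices, rows, cols = grid_shape
    if not (0 <= contour.slice_index < n_slices):
        raise ValueError(f"slice index {contour.slice_index} outside grid")
    r, c = contour.vertices[:, 0], contour.vertices[:, 1]
    if (r.min() < -0.5 or r.max() > rows - 0.5
            or c.min() < -0.5 or c.max() > cols - 0.5):
        raise ValueError("contour vertices outside the image extent")
    mask = np.zeros(grid_shape, dtype=bool)
    mask[contour.slice_index] = _even_odd_inside(contour.vertices, rows, cols)
    return BinaryMask(mask, provenance=f"contour[slice={contour.slice_index}]")


def roi_disc_pixels(roi: CircularROI, grid: VoxelGrid) -> np.ndarray:
    """Boolean in-plane footprint (rows x cols) of the ROI disc.

    Membership uses the physical distance from the ROI center computed
    with the in-plane pixel spacing: a pixel is in the disc iff its center
    lies within ``diameter_mm / 2``.
    """
    _, rows, cols = grid.shape
    sr, sc = grid.pixel_spacing_mm
    radius = roi.diameter_mm / 2.0
    cr, cc = roi.center
    rr = (np.arange(rows)[:, None] - cr) * sr
    cc_mm = (np.arange(cols)[None, :] - cc) * sc
    disc = rr ** 2 + cc_mm ** 2 <= radius ** 2
    # disc must lie fully inside the image extent
    if (cr - radius / sr < -0.5 or cr + radius / sr > rows - 0.5
            or cc - radius / sc < -0.5 or cc + radius / sc > cols - 0.5):
        raise ValueError("ROI extends beyond image")
    return disc


def roi_pixels(roi: CircularROI, grid: VoxelGrid) -> np.ndarray:
    """Values of all pixels whose centers fall inside the ROI disc."""
    n_slices = grid.shape[0]
    if not (0 <= roi.slice_index < n_slices):
        raise ValueError(f"ROI slice index {roi.slice_index} outside grid")
    disc = roi_disc_pixels(roi, grid)
    return grid.values[roi.slice_index][disc]


# ---------------------------------------------------------------------------
# JSON serialization of contours and ROIs
# ---------------------------------------------------------------------------

def contours_to_json(contours: Iterable[PlanarContour], path: str | os.PathLike) -> None:
    payload = [{"slice": int(ct.slice_index),
                "vertices": [[float(r), float(c)] for r, c in ct.vertices]}
               for ct in contours]
    with open(path, "w") as fh:
        json.dump(payload, fh)


def contours_from_json(path: str | os.PathLike) -> list[PlanarContour]:
    with open(path) as fh:
        payload = json.load(fh)
    return [PlanarContour(int(item["slice"]), np.asarray(item["vertices"], float))
            for item in payload]


def rois_to_json(rois: Iterable[CircularROI], path: str | os.PathLike) -> None:
    payload = [{"slice": int(roi.slice_index),
                "center": [float(roi.center[0]), float(roi.center[1])],
                "diameter_mm": float(roi.diameter_mm)}
               for roi in rois]
    with open(path, "w") as fh:
        json.dump(payload, fh)


def rois_from_json(path: str | os.PathLike) -> list[CircularROI]:
    with open(path) as fh:
        payload = json.load(fh)
    return [CircularROI(int(item["slice"]),
                        (float(item["center"][0]), float(item["center"][1])),
                        float(item["diameter_mm"]))
            for item in payload]
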