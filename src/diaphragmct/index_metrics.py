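"""Diaphragm index from a voxel surface, plus emphysema densitometry.

The diaphragm index is the ratio of the diaphragm's surface area to its
axially projected surface area: 1 for a perfectly flat diaphragm, 2 for
a hemispherical dome. The voxel sheet is first reduced to a height map
(mean z per (x, y) column, in mm), the surface area is estimated by
triangulating the height map over unit cells, and the projected area is
the footprint of the same cells — so a flat sheet scores exactly 1 and
SA >= PA always holds (a 3D triangle's area is never smaller than its
axial projection).

The emphysema score (%LAA-950) is the percentage of lung voxels with
attenuation below -950 HU, the standard CT densitometric measure of
emphysema used as a covariate alongside the diaphragm index.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import (
    AlignmentError,
    DegenerateSurfaceError,
    EmptySegmentationError,
    EmptySurfaceError,
)
from .extraction import DiaphragmSurface
from .volume_io import BinaryMask, CTVolume


@dataclass
class HeightMap:
    """Per-(x, y)-column surface height in mm; NaN marks absent columns."""

    heights: np.ndarray                 # 2D float, indexed [x, y]
    spacing: tuple[float, float]        # (sx, sy) mm

    @property
    def footprint(self) -> np.ndarray:
        return np.isfinite(self.heights)


@dataclass
class SideMetrics:
    surface_area: float        # mm^2
    projected_area: float      # mm^2
    index: float               # dimensionless


@dataclass
class IndexResult:
    """Per-lung and combined diaphragm index.

    The combined index pools areas across sides,
    ``(SA_L + SA_R) / (PA_L + PA_R)``, rather than averaging the
    per-side indices.
    """

    left: SideMetrics | None
    right: SideMetrics | None
    combined: SideMetrics
    params: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        def side(m):
            if m is None:
                return None
            return {"surface_area_mm2": m.surface_area,
                    "projected_area_mm2": m.projected_area,
                    "diaphragm_index": m.index}
        return {"left": side(self.left), "right": side(self.right),
                "combined": side(self.combined), "params": self.params}


@dataclass
class EmphysemaResult:
    percent_below_threshold: float
    threshold_hu: float


def to_height_map(surface: DiaphragmSurface) -> HeightMap:
    """Reduce the voxel sheet to a per-column height map.

    Each occupied (x, y) column maps to the mean z (in mm) of its
    surface voxels; the mean is robust to the local sheet thickness the
    stitching fill introduces.
    """
    grid = surface.grid
    if not grid.any():
        raise EmptySurfaceError("cannot build a height map from an empty surface")
    counts = grid.sum(axis=2)
    z_idx = np.arange(grid.shape[2], dtype=float)
    z_sum = (grid * z_idx[None, None, :]).sum(axis=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        heights = np.where(counts > 0, z_sum / np.maximum(counts, 1), np.nan)
    heights = heights * surface.spacing[2]
    heights[counts == 0] = np.nan
    return HeightMap(heights=heights,
                     spacing=(surface.spacing[0], surface.spacing[1]))


def _complete_cells(hm: HeightMap) -> np.ndarray:
    h = hm.heights
    return (np.isfinite(h[:-1, :-1]) & np.isfinite(h[1:, :-1])
            & np.isfinite(h[:-1, 1:]) & np.isfinite(h[1:, 1:]))


def surface_area(hm: HeightMap) -> float:
    """Triangulated 3D area of the height map, in mm².

    Every complete unit cell (2x2 block of occupied columns) is split
    into two triangles and the 3D triangle areas are summed; a cell's
    area is the mean over the two possible diagonal splits, which makes
    the estimate exactly symmetric under axis flips (neither diagonal is
    privileged). Cells with any absent corner contribute nothing, so the
    footprint matches :func:`projected_area` exactly. Cell contributions
    are accumulated in sorted order so the total is bit-identical under
    translation and mirroring of the surface.
    """
    cells = _complete_cells(hm)
    if not cells.any():
        raise DegenerateSurfaceError("no complete 2x2 cell in the height map")
    h = hm.heights
    sx, sy = hm.spacing
    h00, h10 = h[:-1, :-1], h[1:, :-1]
    h01, h11 = h[:-1, 1:], h[1:, 1:]
    # cell corners: P00=(0,0,h00) P10=(sx,0,h10) P01=(0,sy,h01) P11=(sx,sy,h11)
    # main-diagonal split: (P00, P10, P11) + (P00, P11, P01)
    a_main = (_tri_area(sx, 0.0, h10 - h00, sx, sy, h11 - h00)
              + _tri_area(sx, sy, h11 - h00, 0.0, sy, h01 - h00))
    # anti-diagonal split: (P00, P10, P01) + (P10, P11, P01)
    a_anti = (_tri_area(sx, 0.0, h10 - h00, 0.0, sy, h01 - h00)
              + _tri_area(0.0, sy, h11 - h10, -sx, sy, h01 - h10))
    cell_areas = 0.5 * (a_main + a_anti)
    return float(np.sort(cell_areas[cells]).sum())


def _tri_area(ux, uy, uz, vx, vy, vz):
    cx = uy * vz - uz * vy
    cy = uz * vx - ux * vz
    cz = ux * vy - uy * vx
    return 0.5 * np.sqrt(cx * cx + cy * cy + cz * cz)


def projected_area(hm: HeightMap) -> float:
    """Axially projected area: complete-cell count times cell area, mm²."""
    cells = _complete_cells(hm)
    if not cells.any():
        raise DegenerateSurfaceError("no complete 2x2 cell in the height map")
    return float(cells.sum()) * hm.spacing[0] * hm.spacing[1]


def _side_metrics(surface: DiaphragmSurface) -> SideMetrics:
    hm = to_height_map(surface)
    sa = surface_area(hm)
    pa = projected_area(hm)
    if pa <= 0:
        raise DegenerateSurfaceError("projected area is zero")
    return SideMetrics(surface_area=sa, projected_area=pa, index=sa / pa)


def diaphragm_index(left: DiaphragmSurface | None,
                    right: DiaphragmSurface | None,
                    params: dict | None = None) -> IndexResult:
    """Compute per-side and combined diaphragm indices.

    At least one side must be present; the combined index pools surface
    and projected areas over the present sides.
    """
    if left is None and right is None:
        raise EmptySurfaceError("at least one diaphragm surface is required")
    lm = _side_metrics(left) if left is not None else None
    rm = _side_metrics(right) if right is not None else None
    sa = sum(m.surface_area for m in (lm, rm) if m is not None)
    pa = sum(m.projected_area for m in (lm, rm) if m is not None)
    combined = SideMetrics(surface_area=sa, projected_area=pa, index=sa / pa)
    return IndexResult(left=lm, right=rm, combined=combined,
                       params=dict(params or {}))


def emphysema_score(ct: CTVolume, lung: BinaryMask,
                    threshold: float = -950.0) -> EmphysemaResult:
    """%LAA: percentage of lung voxels with attenuation below ``threshold`` HU."""
    if ct.grid.shape != lung.grid.shape:
        raise AlignmentError(
            f"CT shape {ct.grid.shape} != lung mask shape {lung.grid.shape}"
        )
    n = lung.count()
    if n == 0:
        raise EmptySegmentationError("lung mask is empty")
    below = int((ct.grid[lung.grid] < threshold).sum())
    return EmphysemaResult(percent_below_threshold=100.0 * below / n,
                           threshold_hu=float(threshold))
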