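"""Per-coronal-slice extraction of the lung-diaphragm intersection.

The diaphragm itself is hard to segment directly on CT (its density
matches the liver and other abdominal organs), so the caudal surface of
the lung segmentation — the lung-diaphragm intersection — is used as a
proxy. The extraction runs per lung:

1. keep the lower third of the lung mask (the diaphragm dome lives
   there);
2. iterate over coronal slices, keeping per slice the largest
   8-connected component;
3. outline the component (morphological dilation minus the original);
4. cut the closed outline at the two costophrenic points: within search
   bands spanning the first and last 25% of the outline's width, remove
   the most caudal voxel (outermost on ties). If the cut yields two
   8-connected components the smaller one is the lung-diaphragm
   intersection arc;
5. when the cut fails to split the outline, fall back to tracing the
   outline from the most caudal midpoint outward on both sides, ending
   each side at its most caudal voxel if the outline ascends beyond it,
   else at the outermost voxel;
6. filter out arcs that cannot be diaphragm: arcs sagging caudally at
   their midpoint (filter 1) and arcs whose midpoint lies too close to
   their most caudal voxel, indicating an inward-curving contour
   (filter 2);
7. stitch each kept arc to the previously kept one by connecting
   endpoints and filling the enclosed region, so consecutive slices form
   a connected sheet;
8. keep the largest 26-connected 3D component of the stitched result.

Coordinates follow the canonical frame of :mod:`.volume_io`: a coronal
slice is the boolean plane ``mask[:, y, :]`` indexed ``(x, z)`` with z
increasing cranially, so "most caudal" means smallest z.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from skimage.measure import label as _cc_label

from .errors import EmptySegmentationError, ExtractionFailureError, ParameterError
from .volume_io import BinaryMask

#: structuring element for the outline dilation: the 4-connected cross.
#: A 3x3 square makes the outline two voxels thick across diagonal
#: boundary steps, and removing a single voxel per search band then
#: almost never disconnects the ring; with the cross the outline is a
#: one-voxel 8-connected ring and the costophrenic cut behaves as
#: intended (failing only on rare degenerate slices).
_CROSS = ndimage.generate_binary_structure(2, 1)


@dataclass
class ExtractionParams:
    """Tunable parameters of the per-slice extraction.

    search_band_fraction
        Fraction of the outline width covered by each costophrenic
        search band (default 0.25: first and last quarter).
    ascent_check_length
        Number of voxels over which the fallback trace requires a net
        cranial ascent beyond a candidate caudal edge (default 5).
    filter2_min_distance_fraction
        Minimum allowed distance between an arc's midpoint and its most
        caudal voxel, as a fraction of the arc's x-extent (default 0.25).
    lower_fraction
        Fraction of the lung's occupied z-range retained as the "lower
        third" (default 1/3).
    """

    search_band_fraction: float = 0.25
    ascent_check_length: int = 5
    filter2_min_distance_fraction: float = 0.25
    lower_fraction: float = 1.0 / 3.0

    def __post_init__(self):
        for name in ("search_band_fraction", "filter2_min_distance_fraction",
                     "lower_fraction"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ParameterError(f"{name} must be in (0, 1), got {v}")
        if self.ascent_check_length < 1:
            raise ParameterError("ascent_check_length must be >= 1")


@dataclass
class DiaphragmArc:
    """Ordered open path of (x, z) voxels in one coronal slice."""

    path: list[tuple[int, int]]
    y_index: int
    provenance: str = "cut"            # "cut" | "fallback"
    status: str = "pending"            # "kept" | "discarded_filter1" | ...
    #: full voxel set of the retained component; a superset of ``path``
    #: in the rare case the component is not traceable as a single path
    pixels: frozenset = field(default_factory=frozenset)

    def __post_init__(self):
        if not self.pixels:
            self.pixels = frozenset(self.path)

    @property
    def endpoints(self) -> tuple[tuple[int, int], tuple[int, int]]:
        return self.path[0], self.path[-1]


@dataclass
class DiaphragmSurface:
    """Stitched 3D lung-diaphragm intersection for one lung."""

    grid: np.ndarray                    # bool, indexed [x, y, z]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float]
    side: str
    slice_log: dict[int, str] = field(default_factory=dict)

    def count(self) -> int:
        return int(self.grid.sum())


class NeedsFallback(Exception):
    """Raised when the costophrenic cut cannot split the outline."""


# ---------------------------------------------------------------------------
# Per-slice primitives
# ---------------------------------------------------------------------------

def lower_third(mask: BinaryMask, lower_fraction: float = 1.0 / 3.0) -> BinaryMask:
    """Retain the caudal fraction of the mask's occupied z-range.

    Keeps voxels with ``z < z_min + round(lower_fraction * height)``
    where height is the occupied z-extent in slices; at least one slice
    is always kept.
    """
    occupied_z = np.flatnonzero(mask.grid.any(axis=(0, 1)))
    if occupied_z.size == 0:
        raise EmptySegmentationError("cannot take lower third of an empty mask")
    z_min, z_max = int(occupied_z[0]), int(occupied_z[-1])
    n_keep = max(1, round(lower_fraction * (z_max - z_min + 1)))
    grid = mask.grid.copy()
    grid[:, :, z_min + n_keep:] = False
    return BinaryMask(grid=grid, spacing=mask.spacing, origin=mask.origin,
                      side=mask.side)


def largest_component_2d(slice_grid: np.ndarray) -> np.ndarray:
    """Keep only the largest 8-connected component of a boolean slice.

    Ties are broken deterministically: the component whose first voxel
    in (z, x) scan order comes first wins.
    """
    slice_grid = np.asarray(slice_grid, dtype=bool)
    if not slice_grid.any():
        return np.zeros_like(slice_grid)
    lab = _cc_label(slice_grid, connectivity=2)
    sizes = np.bincount(lab.ravel())
    sizes[0] = 0
    best = sizes.max()
    candidates = np.flatnonzero(sizes == best)
    if candidates.size == 1:
        keep = candidates[0]
    else:
        nx = slice_grid.shape[0]
        best_key, keep = None, None
        for c in candidates:
            xs, zs = np.nonzero(lab == c)
            key = (zs * nx + xs).min()
            if best_key is None or key < best_key:
                best_key, keep = key, c
    return lab == keep


def outline_2d(slice_grid: np.ndarray) -> np.ndarray:
    """One-voxel outline: morphological dilation minus the region.

    Dilation uses the 4-connected cross, so the outline is a one-voxel
    8-connected closed ring (thin across diagonal boundary steps); it is
    disjoint from the region and every outline voxel is 8-adjacent to it.
    """
    slice_grid = np.asarray(slice_grid, dtype=bool)
    if not slice_grid.any():
        return np.zeros_like(slice_grid)
    dil = ndimage.binary_dilation(slice_grid, structure=_CROSS)
    return dil & ~slice_grid


def _band_caudal_voxel(pts: np.ndarray, x_lo: int, x_hi: int,
                       outer: str) -> tuple[int, int] | None:
    """Most caudal outline voxel with x in [x_lo, x_hi]; at equal z the
    outermost x (min for the left band, max for the right) is chosen."""
    sel = pts[(pts[:, 0] >= x_lo) & (pts[:, 0] <= x_hi)]
    if sel.size == 0:
        return None
    z_min = sel[:, 1].min()
    at_z = sel[sel[:, 1] == z_min]
    x = at_z[:, 0].min() if outer == "min" else at_z[:, 0].max()
    return int(x), int(z_min)


def cut_costophrenic(outline: np.ndarray, params: ExtractionParams,
                     y_index: int = 0) -> DiaphragmArc:
    """Cut the outline at the two costophrenic points and keep the arc.

    Removes the most caudal voxel within each lateral search band. If
    the removal splits the outline into exactly two 8-connected
    components, the smaller one (on ties, the one containing the most
    caudal voxel) is returned as the lung-diaphragm intersection arc;
    otherwise :class:`NeedsFallback` is raised.
    """
    outline = np.asarray(outline, dtype=bool)
    pts = np.argwhere(outline)
    if pts.size == 0:
        raise NeedsFallback("empty outline")
    x_min, x_max = int(pts[:, 0].min()), int(pts[:, 0].max())
    width = x_max - x_min + 1
    if width < 4:
        raise NeedsFallback(f"outline width {width} too small for search bands")
    band_w = max(1, round(params.search_band_fraction * width))
    left_pt = _band_caudal_voxel(pts, x_min, x_min + band_w - 1, "min")
    right_pt = _band_caudal_voxel(pts, x_max - band_w + 1, x_max, "max")
    if left_pt is None or right_pt is None or left_pt == right_pt:
        raise NeedsFallback("could not find two distinct cut points")

    remaining = outline.copy()
    remaining[left_pt] = False
    remaining[right_pt] = False
    lab = _cc_label(remaining, connectivity=2)
    n = lab.max()
    if n != 2:
        raise NeedsFallback(f"cut produced {n} components instead of 2")
    sizes = np.bincount(lab.ravel())
    if sizes[1] != sizes[2]:
        keep = 1 if sizes[1] < sizes[2] else 2
    else:
        # equal halves: the diaphragm is the one holding the caudal extreme
        rp = np.argwhere(remaining)
        order = np.lexsort((rp[:, 0], rp[:, 1]))
        cx, cz = rp[order[0]]
        keep = int(lab[cx, cz])
    comp = np.argwhere(lab == keep)
    pixels = frozenset((int(x), int(z)) for x, z in comp)
    path = _order_open_path(pixels)
    return DiaphragmArc(path=path, y_index=y_index, provenance="cut",
                        pixels=pixels)


# -- path ordering -----------------------------------------------------------

_ORTHO = ((0, 1), (0, -1), (1, 0), (-1, 0))
_DIAG = ((1, 1), (1, -1), (-1, 1), (-1, -1))


def _neighbours(p):
    x, z = p
    for dx, dz in _ORTHO + _DIAG:
        yield (x + dx, z + dz)


def _order_open_path(pixels: frozenset) -> list[tuple[int, int]]:
    """Order the pixels of a thin open curve from one endpoint to the other.

    Walks the curve preferring orthogonal steps (so staircase corners are
    not short-circuited diagonally), backtracking where the curve locally
    thickens. Falls back to a greedy partial order on pathological
    inputs; the full pixel set is preserved separately on the arc.
    """
    if not pixels:
        return []
    adj = {p: [q for q in _neighbours(p) if q in pixels] for p in pixels}
    endpoints = sorted(p for p, nb in adj.items() if len(nb) == 1)
    starts = endpoints if endpoints else [min(pixels)]
    best: list[tuple[int, int]] = []
    for start in starts:
        path = _dfs_cover(start, adj, len(pixels), budget=60 * len(pixels))
        if len(path) > len(best):
            best = path
        if len(best) == len(pixels):
            break
    return best


def _dfs_cover(start, adj, n_total, budget):
    """Depth-first search for a path covering all pixels; orthogonal
    steps are tried first. Returns the longest path found within the
    expansion budget (the full cover in non-degenerate cases)."""

    def step_order(p):
        x, z = p
        # deterministic: orthogonal neighbours first, then diagonal
        return sorted(adj[p],
                      key=lambda q: (abs(q[0] - x) + abs(q[1] - z) != 1, q))

    best = [start]
    stack = [(start, [start], {start})]
    expansions = 0
    while stack and expansions < budget:
        p, path, seen = stack.pop()
        expansions += 1
        if len(path) > len(best):
            best = path
            if len(best) == n_total:
                return best
        nxt = [q for q in step_order(p) if q not in seen]
        # LIFO stack: push in reverse so the preferred neighbour pops first
        for q in reversed(nxt):
            stack.append((q, path + [q], seen | {q}))
    return best


def _order_closed_ring(pixels: frozenset) -> list[tuple[int, int]]:
    """Order the pixels of a thin closed ring into a cyclic sequence."""
    if not pixels:
        return []
    adj = {p: [q for q in _neighbours(p) if q in pixels] for p in pixels}
    start = min(pixels)
    ring = _dfs_cover(start, adj, len(pixels), budget=40 * len(pixels))
    return ring


# -- fallback trace ----------------------------------------------------------

def fallback_trace(outline: np.ndarray, params: ExtractionParams,
                   y_index: int = 0) -> DiaphragmArc | None:
    """Trace the outline outward from its most caudal midpoint.

    On each side of the start the edge of the diaphragm is the most
    caudal voxel of that side, provided the outline ascends (net z
    increase) over the next ``ascent_check_length`` voxels beyond it;
    otherwise the outermost voxel of the side is used. Returns the
    caudal portion spanning the two edges, or None when the outline is
    too small to trace (the slice is then skipped).
    """
    outline = np.asarray(outline, dtype=bool)
    pts = np.argwhere(outline)
    if pts.shape[0] < 2 * params.ascent_check_length:
        return None
    pixels = frozenset((int(x), int(z)) for x, z in pts)
    ring = _order_closed_ring(pixels)
    if len(ring) < 2 * params.ascent_check_length:
        return None

    x_min, x_max = int(pts[:, 0].min()), int(pts[:, 0].max())
    x_mid = (x_min + x_max) / 2.0
    z_min = int(pts[:, 1].min())
    caudal = [p for p in ring if p[1] == z_min]
    start = min(caudal, key=lambda p: (abs(p[0] - x_mid), p))
    i0 = ring.index(start)
    n = len(ring)
    half = n // 2
    side_a = [ring[(i0 + k) % n] for k in range(1, half + 1)]
    side_b = [ring[(i0 - k) % n] for k in range(1, n - half)]

    def choose_edge(side):
        if not side:
            return None
        zs = np.array([p[1] for p in side])
        # last occurrence of the side's caudal extreme: the outer end of a
        # flat caudal stretch, i.e. the costophrenic-corner candidate
        i_caudal = int(np.flatnonzero(zs == zs.min())[-1])
        L = params.ascent_check_length
        if i_caudal + L < len(side) and side[i_caudal + L][1] > side[i_caudal][1]:
            return i_caudal
        # no ascent beyond the caudal point: take the outermost voxel
        dx = np.abs(np.array([p[0] for p in side]) - start[0])
        return int(np.argmax(dx))

    ia, ib = choose_edge(side_a), choose_edge(side_b)
    if ia is None or ib is None:
        return None
    path = list(reversed(side_b[: ib + 1])) + [start] + side_a[: ia + 1]
    return DiaphragmArc(path=path, y_index=y_index, provenance="fallback")


# -- arc filters -------------------------------------------------------------

def filter_arc(arc: DiaphragmArc, params: ExtractionParams) -> str:
    """Classify an arc as diaphragm or spurious.

    Filter 1 removes arcs that sag caudally at their midpoint (a
    diaphragm dome is flat or cranially convex). Filter 2 removes arcs
    whose midpoint sits too close to their most caudal voxel — the
    signature of an inward-curving contour rather than a dome.

    The midpoint is the average of the path's two central voxels for
    even path lengths. When several voxels tie for most caudal (a flat
    caudal stretch), the distance is taken to the nearer of the
    stretch's two extremal (leftmost/rightmost) voxels, so a perfectly
    flat arc keeps its half-extent distance and the decision is exactly
    mirror-symmetric and independent of path direction.
    """
    n = len(arc.path)
    if n < 3:
        return "discarded_filter2"
    a, b = arc.path[(n - 1) // 2], arc.path[n // 2]
    mid = ((a[0] + b[0]) / 2.0, (a[1] + b[1]) / 2.0)
    e1, e2 = arc.endpoints
    if mid[1] < min(e1[1], e2[1]):
        return "discarded_filter1"
    z_min = min(p[1] for p in arc.path)
    caudal = [p for p in arc.path if p[1] == z_min]
    reps = (min(caudal), max(caudal))
    dist = min(float(np.hypot(mid[0] - p[0], mid[1] - p[1])) for p in reps)
    xs = [p[0] for p in arc.path]
    x_extent = max(xs) - min(xs) + 1
    if dist < params.filter2_min_distance_fraction * x_extent:
        return "discarded_filter2"
    return "kept"


# -- inter-slice stitching ---------------------------------------------------

def _digital_segment(a: tuple[int, int], b: tuple[int, int]) -> set:
    """Digital straight segment between two voxels.

    DDA sampling along the major axis with round-half-to-both ties (at
    an exact half-integer both candidate voxels are included), so the
    segment is a pure function of the endpoint geometry: symmetric
    under endpoint swap, integer translation and axis mirroring.
    """
    (x0, z0), (x1, z1) = a, b
    dx, dz = x1 - x0, z1 - z0
    n = max(abs(dx), abs(dz))
    if n == 0:
        return {a}
    pts = {a, b}
    for k in range(1, n):
        # exact rational coordinates: (x0 + k*dx/n, z0 + k*dz/n)
        xm_num, zm_num = x0 * n + k * dx, z0 * n + k * dz
        cells = []
        for num in (xm_num, zm_num):
            q, r = divmod(num, n)
            if 2 * r == n:
                cells.append((q, q + 1))
            elif 2 * r < n:
                cells.append((q, q))
            else:
                cells.append((q + 1, q + 1))
        for xx in cells[0]:
            for zz in cells[1]:
                pts.add((xx, zz))
    return pts

def stitch_slices(prev: DiaphragmArc | None, cur: DiaphragmArc,
                  plane_shape: tuple[int, int]) -> np.ndarray:
    """Connect the current arc to the previous slice's arc and fill.

    The previous arc is overlaid into the current (x, z) plane, each of
    its endpoints is joined to the nearer endpoint of the current arc by
    a digital straight segment, and the interior of the resulting closed
    curve is filled. This guarantees consecutive slice regions overlap
    in (x, z), making their 3D union 26-connected.
    """
    canvas = np.zeros(plane_shape, dtype=bool)
    for x, z in cur.pixels:
        canvas[x, z] = True
    if prev is None:
        return canvas
    for x, z in prev.pixels:
        canvas[x, z] = True
    (p1, p2), (c1, c2) = prev.endpoints, cur.endpoints

    def d(a, b):
        return (a[0] - b[0]) ** 2 + (a[1] - b[1]) ** 2

    # pair each prev endpoint with the nearer cur endpoint, keeping the
    # pairing one-to-one (minimum total distance)
    if d(p1, c1) + d(p2, c2) <= d(p1, c2) + d(p2, c1):
        pairs = ((p1, c1), (p2, c2))
    else:
        pairs = ((p1, c2), (p2, c1))
    for a, b in pairs:
        for x, z in _digital_segment(a, b):
            canvas[x, z] = True
    return ndimage.binary_fill_holes(canvas)


# ---------------------------------------------------------------------------
# Orchestrator
# ---------------------------------------------------------------------------

def extract_diaphragm(lung: BinaryMask,
                      params: ExtractionParams | None = None) -> DiaphragmSurface:
    """Extract the lung-diaphragm intersection surface for one lung.

    Runs the full per-slice pipeline over the lower third of the lung
    and keeps the largest 26-connected component of the stitched result.
    The per-slice status log records, for every coronal slice, whether
    its arc was kept, filtered out, or skipped and why.
    """
    params = params or ExtractionParams()
    if not lung.grid.any():
        raise EmptySegmentationError("lung mask is empty")
    low = lower_third(lung, params.lower_fraction)
    nx, ny, nz = low.grid.shape
    out = np.zeros((nx, ny, nz), dtype=bool)
    log: dict[int, str] = {}
    prev_arc: DiaphragmArc | None = None
    for y in range(ny):
        plane = low.grid[:, y, :]
        if not plane.any():
            log[y] = "empty"
            continue
        comp = largest_component_2d(plane)
        outline = outline_2d(comp)
        if not outline.any():
            log[y] = "empty_outline"
            continue
        try:
            arc = cut_costophrenic(outline, params, y_index=y)
        except NeedsFallback:
            arc = fallback_trace(outline, params, y_index=y)
            if arc is None:
                log[y] = "skipped_untraceable"
                continue
        status = filter_arc(arc, params)
        arc.status = status
        log[y] = status
        if status != "kept":
            continue
        region = stitch_slices(prev_arc, arc, (nx, nz))
        out[:, y, :] |= region
        prev_arc = arc
    if not out.any():
        raise ExtractionFailureError(
            f"no coronal slice of the {lung.side} lung yielded a kept arc",
            slice_log=log,
        )
    lab = _cc_label(out, connectivity=3)
    sizes = np.bincount(lab.ravel())
    sizes[0] = 0
    out = lab == int(sizes.argmax())
    return DiaphragmSurface(grid=out, spacing=low.spacing, origin=low.origin,
                            side=lung.side, slice_log=log)
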