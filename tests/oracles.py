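"""Independent brute-force reference implementations used as test oracles.

Everything here is written with plain Python loops, sets and BFS —
deliberately avoiding scipy/scikit-image morphology — so the package's
vectorised implementations are checked against an independent route.
The one shared primitive is line rasterisation in the stitch oracle
(digital straight segments have convention-dependent tie-breaking, so
both routes must use the same segment; the fill logic being checked is
independent).
"""

from __future__ import annotations

from collections import deque

import numpy as np
from diaphragmct.extraction import _digital_segment as _shared_segment

ORTHO = ((0, 1), (0, -1), (1, 0), (-1, 0))
DIAG = ((1, 1), (1, -1), (-1, 1), (-1, -1))
NEIGH8 = ORTHO + DIAG


def brute_outline(region: np.ndarray) -> set[tuple[int, int]]:
    """Outline = background pixels 4-adjacent to the region (cross dilation)."""
    fg = {(int(x), int(z)) for x, z in np.argwhere(region)}
    out = set()
    for x, z in fg:
        for dx, dz in ORTHO:
            q = (x + dx, z + dz)
            if q not in fg:
                out.add(q)
    return {(x, z) for x, z in out
            if 0 <= x < region.shape[0] and 0 <= z < region.shape[1]}


def brute_components(pixels: set[tuple[int, int]]) -> list[set]:
    """8-connected components by BFS."""
    pixels = set(pixels)
    comps = []
    while pixels:
        seed = pixels.pop()
        comp = {seed}
        q = deque([seed])
        while q:
            x, z = q.popleft()
            for dx, dz in NEIGH8:
                p = (x + dx, z + dz)
                if p in pixels:
                    pixels.remove(p)
                    comp.add(p)
                    q.append(p)
        comps.append(comp)
    return comps


def brute_largest_component(region: np.ndarray) -> set[tuple[int, int]]:
    """Largest 8-connected component; ties -> first voxel in (z, x) scan order."""
    pixels = {(int(x), int(z)) for x, z in np.argwhere(region)}
    if not pixels:
        return set()
    comps = brute_components(pixels)
    best = max(len(c) for c in comps)
    tied = [c for c in comps if len(c) == best]
    return min(tied, key=lambda c: min((z, x) for x, z in c))


def brute_cut(outline: np.ndarray,
              band_fraction: float = 0.25) -> set[tuple[int, int]] | None:
    """Costophrenic cut re-implemented with loops; None = needs fallback."""
    pixels = {(int(x), int(z)) for x, z in np.argwhere(outline)}
    if not pixels:
        return None
    xs = [x for x, _ in pixels]
    x_min, x_max = min(xs), max(xs)
    width = x_max - x_min + 1
    if width < 4:
        return None
    band_w = max(1, round(band_fraction * width))

    def pick(lo, hi, outermost_min):
        cand = [(x, z) for x, z in pixels if lo <= x <= hi]
        if not cand:
            return None
        z_min = min(z for _, z in cand)
        at = [x for x, z in cand if z == z_min]
        return (min(at) if outermost_min else max(at), z_min)

    left = pick(x_min, x_min + band_w - 1, True)
    right = pick(x_max - band_w + 1, x_max, False)
    if left is None or right is None or left == right:
        return None
    remaining = pixels - {left, right}
    comps = brute_components(remaining)
    if len(comps) != 2:
        return None
    a, b = comps
    if len(a) != len(b):
        return a if len(a) < len(b) else b
    caudal = min(remaining, key=lambda p: (p[1], p[0]))
    return a if caudal in a else b


def brute_stitch(prev_pixels, prev_endpoints, cur_pixels, cur_endpoints,
                 shape) -> set[tuple[int, int]]:
    """Stitch oracle: same segments, independent border flood fill.

    Closed curve = both arcs plus the minimum-total-distance endpoint
    joins; the filled region is everything not reachable from the canvas
    border through 4-connected background.
    """
    curve = set(prev_pixels) | set(cur_pixels)
    (p1, p2), (c1, c2) = prev_endpoints, cur_endpoints

    def d(a, b):
        return (a[0] - b[0]) ** 2 + (a[1] - b[1]) ** 2

    if d(p1, c1) + d(p2, c2) <= d(p1, c2) + d(p2, c1):
        pairs = ((p1, c1), (p2, c2))
    else:
        pairs = ((p1, c2), (p2, c1))
    for a, b in pairs:
        curve |= _shared_segment(a, b)

    nx, nz = shape
    outside = set()
    q = deque()
    for x in range(nx):
        for z in (0, nz - 1):
            if (x, z) not in curve:
                outside.add((x, z))
                q.append((x, z))
    for z in range(nz):
        for x in (0, nx - 1):
            if (x, z) not in curve:
                outside.add((x, z))
                q.append((x, z))
    while q:
        x, z = q.popleft()
        for dx, dz in ORTHO:
            p = (x + dx, z + dz)
            if (0 <= p[0] < nx and 0 <= p[1] < nz
                    and p not in curve and p not in outside):
                outside.add(p)
                q.append(p)
    return {(x, z) for x in range(nx) for z in range(nz)
            if (x, z) not in outside}


def brute_iqr_flags(values) -> list[bool]:
    """1.5*IQR rule with hand-computed linear-interpolation quartiles."""
    v = sorted(float(x) for x in values)
    n = len(v)

    def quantile(q):
        pos = q * (n - 1)
        lo = int(pos)
        frac = pos - lo
        return v[lo] if lo + 1 >= n else v[lo] + frac * (v[lo + 1] - v[lo])

    q1, q3 = quantile(0.25), quantile(0.75)
    iqr = q3 - q1
    lower, upper = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    return [bool(x < lower or x > upper) for x in values]


# -- random fixtures ---------------------------------------------------------

def random_region(rng: np.random.Generator, shape=(64, 64)) -> np.ndarray:
    """Random union of 1-3 filled ellipses (plausible slice-like blobs)."""
    nx, nz = shape
    region = np.zeros(shape, dtype=bool)
    for _ in range(rng.integers(1, 4)):
        cx = rng.uniform(8, nx - 8)
        cz = rng.uniform(8, nz - 8)
        ax = rng.uniform(3, nx / 4)
        az = rng.uniform(3, nz / 4)
        x = np.arange(nx)[:, None]
        z = np.arange(nz)[None, :]
        region |= ((x - cx) / ax) ** 2 + ((z - cz) / az) ** 2 <= 1.0
    return region


def random_arc(rng: np.random.Generator, shape=(64, 64)):
    """Random dome-like open arc (ordered 8-connected path) for stitching."""
    nx, nz = shape
    x0 = int(rng.integers(4, 12))
    x1 = int(rng.integers(nx - 12, nx - 4))
    base = int(rng.integers(6, nz // 2))
    amp = float(rng.uniform(0, nz // 3))
    path = []
    span = x1 - x0
    prev_z = None
    for x in range(x0, x1 + 1):
        t = (x - x0) / span
        z = base + int(round(amp * np.sin(np.pi * t)))
        z = min(max(z, 0), nz - 1)
        if prev_z is not None and abs(z - prev_z) > 1:
            step = 1 if z > prev_z else -1
            for zz in range(prev_z + step, z, step):
                path.append((x, zz))
        path.append((x, z))
        prev_z = z
    return path
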