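import numpy as np
import pytest
from skimage.draw import circle_perimeter

from diaphragmct import (
    BinaryMask,
    DiaphragmArc,
    EmptySegmentationError,
    ExtractionFailureError,
    ExtractionParams,
    NeedsFallback,
    cut_costophrenic,
    extract_diaphragm,
    fallback_trace,
    filter_arc,
    largest_component_2d,
    lower_third,
    outline_2d,
    split_lungs,
    stitch_slices,
)
from diaphragmct.phantom import dome_height

from oracles import brute_largest_component, brute_outline


def _mask(grid):
    return BinaryMask(grid=grid, spacing=(1.0, 1.0, 1.0))


# -- lower_third -------------------------------------------------------------

def test_lower_third_keeps_caudal_slab():
    grid = np.zeros((4, 4, 40), dtype=bool)
    grid[1:3, 1:3, 0:30] = True            # occupied z in [0, 29]
    out = lower_third(_mask(grid))
    kept_z = np.flatnonzero(out.grid.any(axis=(0, 1)))
    assert kept_z.min() == 0 and kept_z.max() == 9


def test_lower_third_offset_range():
    grid = np.zeros((4, 4, 40), dtype=bool)
    grid[1:3, 1:3, 7:27] = True            # height 20 -> keep 7..13
    out = lower_third(_mask(grid))
    kept_z = np.flatnonzero(out.grid.any(axis=(0, 1)))
    assert kept_z.min() == 7 and kept_z.max() == 13


def test_lower_third_degenerate_single_slice():
    grid = np.zeros((4, 4, 10), dtype=bool)
    grid[1:3, 1:3, 5] = True
    out = lower_third(_mask(grid))
    assert np.array_equal(out.grid, grid)


def test_lower_third_empty_mask_raises():
    with pytest.raises(EmptySegmentationError):
        lower_third(_mask(np.zeros((3, 3, 3), dtype=bool)))


# -- largest_component_2d ----------------------------------------------------

def test_largest_component_keeps_biggest_and_matches_brute(rng):
    plane = np.zeros((20, 20), dtype=bool)
    plane[2:7, 2:4] = True                 # 10 voxels
    plane[12:17, 12:13] = True             # 5 voxels
    out = largest_component_2d(plane)
    assert out.sum() == 10
    assert set(map(tuple, np.argwhere(out))) == brute_largest_component(plane)


def test_largest_component_tie_breaks_by_scan_order():
    plane = np.zeros((10, 10), dtype=bool)
    plane[1:3, 5:7] = True                 # 4 voxels, first in (z, x) order? z=5
    plane[6:8, 2:4] = True                 # 4 voxels at z=2 -> wins scan order
    out = largest_component_2d(plane)
    assert out[6, 2] and not out[1, 5]


def test_largest_component_empty_in_empty_out():
    plane = np.zeros((5, 5), dtype=bool)
    assert not largest_component_2d(plane).any()


# -- outline_2d --------------------------------------------------------------

def test_outline_of_single_voxel_is_cross():
    plane = np.zeros((5, 5), dtype=bool)
    plane[2, 2] = True
    out = outline_2d(plane)
    assert set(map(tuple, np.argwhere(out))) == {(1, 2), (3, 2), (2, 1), (2, 3)}


def test_outline_of_3x3_square_is_12_ring():
    plane = np.zeros((7, 7), dtype=bool)
    plane[2:5, 2:5] = True
    out = outline_2d(plane)
    assert out.sum() == 12
    assert set(map(tuple, np.argwhere(out))) == brute_outline(plane)


def test_outline_disjoint_from_region(rng):
    from oracles import random_region
    for _ in range(10):
        region = random_region(rng, (32, 32))
        out = outline_2d(region)
        assert not (out & region).any()
        if region.any():
            assert set(map(tuple, np.argwhere(out))) == brute_outline(region)


# -- cut_costophrenic --------------------------------------------------------

def test_cut_on_digital_circle_keeps_caudal_arc(params):
    outline = np.zeros((32, 32), dtype=bool)
    rr, cc = circle_perimeter(15, 15, 10)
    outline[rr, cc] = True
    n_circle = int(outline.sum())
    arc = cut_costophrenic(outline, params)
    assert len(arc.pixels) < n_circle / 2
    # arc is the caudal portion: every voxel in the lower half of the circle
    assert max(z for _, z in arc.pixels) <= 15


def test_cut_on_phantom_mid_slice_recovers_dome(small_phantom, params):
    spec, vol = small_phantom
    left, _ = split_lungs(vol)
    low = lower_third(left)
    cy = int(round(spec.lungs[0].center[1]))
    comp = largest_component_2d(low.grid[:, cy, :])
    arc = cut_costophrenic(outline_2d(comp), params)
    cx = spec.lungs[0].center[0]
    for x, z in arc.pixels:
        rho = min(abs(x - cx), spec.a)
        z_dome = spec.z_base + dome_height(spec.a, spec.h, np.array(rho))
        assert abs(z - z_dome) <= 2.0


def test_cut_needs_fallback_on_narrow_outline(params):
    outline = np.zeros((10, 10), dtype=bool)
    outline[3:6, 2] = True                 # width 3 < 4
    with pytest.raises(NeedsFallback):
        cut_costophrenic(outline, params)


def test_cut_needs_fallback_when_removal_cannot_split(params):
    # square ring: caudal row is flat; each band's caudal voxel is the ring
    # corner, whose removal leaves a diagonal bridge -> no split
    outline = np.zeros((12, 12), dtype=bool)
    outline[2:9, 2] = True
    outline[2:9, 8] = True
    outline[2, 2:9] = True
    outline[8, 2:9] = True
    with pytest.raises(NeedsFallback):
        cut_costophrenic(outline, params)


# -- fallback_trace ----------------------------------------------------------

def test_fallback_agrees_with_cut_on_dome_slices(small_phantom, params):
    spec, vol = small_phantom
    left, _ = split_lungs(vol)
    low = lower_third(left)
    cy = int(round(spec.lungs[0].center[1]))
    for y in (cy - 8, cy, cy + 8):
        comp = largest_component_2d(low.grid[:, y, :])
        outline = outline_2d(comp)
        arc_cut = cut_costophrenic(outline, params, y)
        arc_fb = fallback_trace(outline, params, y)
        sym = set(arc_cut.path) ^ set(arc_fb.path)
        ends = [arc_cut.path[0], arc_cut.path[-1],
                arc_fb.path[0], arc_fb.path[-1]]
        for p in sym:
            assert min(max(abs(p[0] - e[0]), abs(p[1] - e[1]))
                       for e in ends) <= 3


def test_fallback_flat_ring_edges_at_outermost_x(params):
    outline = np.zeros((30, 12), dtype=bool)
    outline[4:25, 2] = True
    outline[4:25, 7] = True
    outline[4, 2:8] = True
    outline[24, 2:8] = True
    arc = fallback_trace(outline, params)
    xs = sorted(p[0] for p in (arc.path[0], arc.path[-1]))
    assert xs == [4, 24]
    assert all(z == 2 for _, z in arc.path)


def test_fallback_tiny_outline_is_skipped(params):
    outline = np.zeros((8, 8), dtype=bool)
    for x, z in [(2, 2), (3, 2), (4, 3), (5, 2), (5, 3), (3, 3)]:
        outline[x, z] = True
    assert fallback_trace(outline, params) is None


# -- filter_arc --------------------------------------------------------------

def _arc_from_path(path):
    return DiaphragmArc(path=path, y_index=0)


def test_filter_keeps_dome_arc(params):
    # dome: endpoints caudal, midpoint cranial, caudal extreme at an end
    path = [(x, 5 + min(x - 2, 10, 22 - x)) for x in range(2, 23)]
    assert filter_arc(_arc_from_path(path), params) == "kept"


def test_filter1_discards_valley_arc(params):
    # V shape: midpoint 5 voxels caudal of both endpoints
    path = [(x, 10 - min(x - 2, 5, 12 - x)) for x in range(2, 13)]
    arc = _arc_from_path(path)
    mid = path[len(path) // 2]
    assert mid[1] == 5 and path[0][1] == 10 and path[-1][1] == 10
    assert filter_arc(arc, params) == "discarded_filter1"


def test_filter2_discards_inward_hooking_arc(params):
    # C-shape: the right end hooks down and folds back inward, putting
    # the caudal stretch right under the midpoint; x-extent 20 so the
    # midpoint-to-caudal distance (~2) is below the 0.25 * 20 threshold
    path = ([(x, 8) for x in range(1, 21)]
            + [(20, 7), (20, 6)]
            + [(x, 6) for x in range(19, 14, -1)])
    arc = _arc_from_path(path)
    xs = [p[0] for p in path]
    assert max(xs) - min(xs) + 1 == 20
    assert filter_arc(arc, params) == "discarded_filter2"


def test_filter_keeps_flat_arc(params):
    # a perfectly flat diaphragm line is the anticipated healthy-lung
    # shape and must pass both filters
    path = [(x, 5) for x in range(2, 23)]
    assert filter_arc(_arc_from_path(path), params) == "kept"


def test_filter_degenerate_two_voxel_arc(params):
    assert filter_arc(_arc_from_path([(0, 0), (1, 0)]), params) == "discarded_filter2"


# -- stitch_slices -----------------------------------------------------------

def test_stitch_first_slice_is_arc_itself():
    arc = _arc_from_path([(x, 5) for x in range(3, 12)])
    region = stitch_slices(None, arc, (20, 20))
    assert set(map(tuple, np.argwhere(region))) == set(arc.path)


def test_stitch_identical_arcs_adds_nothing():
    arc = _arc_from_path([(x, 5 + (x % 3 == 0)) for x in range(3, 12)])
    region = stitch_slices(arc, arc, (20, 20))
    assert set(map(tuple, np.argwhere(region))) == set(arc.path)


def test_stitch_shifted_arc_fills_band_of_thickness_two():
    prev = _arc_from_path([(x, 5) for x in range(3, 15)])
    cur = _arc_from_path([(x, 6) for x in range(3, 15)])
    region = stitch_slices(prev, cur, (20, 20))
    expect = {(x, 5) for x in range(3, 15)} | {(x, 6) for x in range(3, 15)}
    assert set(map(tuple, np.argwhere(region))) == expect


def test_stitch_fills_enclosed_interior():
    prev = _arc_from_path([(x, 4) for x in range(3, 15)])
    cur = _arc_from_path([(x, 9) for x in range(3, 15)])
    region = stitch_slices(prev, cur, (20, 20))
    assert region[8, 6]                    # interior voxel filled
    assert region.sum() == 12 * 6


# -- extract_diaphragm -------------------------------------------------------

def test_extract_surface_is_single_26_connected_component(small_surface):
    from skimage.measure import label
    _, surf = small_surface
    lab = label(surf.grid, connectivity=3)
    assert lab.max() == 1


def test_extract_surface_tracks_analytic_dome(small_surface):
    spec, surf = small_surface
    from diaphragmct import to_height_map
    hm = to_height_map(surf)
    cx, cy = spec.lungs[0].center
    nx, ny = hm.heights.shape
    rho = np.hypot(np.arange(nx)[:, None] - cx, np.arange(ny)[None, :] - cy)
    dome = spec.z_base + dome_height(spec.a, spec.h, np.minimum(rho, spec.a))
    occ = np.isfinite(hm.heights)
    err = np.abs(hm.heights - dome)[occ]
    assert np.mean(err <= 1.5) >= 0.95


def test_extract_filter_discard_fraction_is_low(small_surface):
    _, surf = small_surface
    statuses = [s for s in surf.slice_log.values() if s != "empty"]
    discarded = [s for s in statuses if s.startswith("discarded")]
    assert len(discarded) / len(statuses) <= 0.10


def test_extract_speck_raises_extraction_failure():
    grid = np.zeros((10, 10, 10), dtype=bool)
    grid[4, 4, 4] = True
    grid[4, 4, 5] = True
    with pytest.raises((ExtractionFailureError, EmptySegmentationError)):
        extract_diaphragm(_mask(grid))


def test_extract_empty_mask_raises():
    with pytest.raises(EmptySegmentationError):
        extract_diaphragm(_mask(np.zeros((5, 5, 5), dtype=bool)))


def test_extract_translation_equivariance(small_phantom):
    spec, vol = small_phantom
    left, _ = split_lungs(vol)
    surf = extract_diaphragm(left)
    shifted = BinaryMask(grid=np.roll(np.roll(left.grid, 2, axis=0), 3, axis=2),
                         spacing=left.spacing, side="left")
    surf_s = extract_diaphragm(shifted)
    assert np.array_equal(np.roll(np.roll(surf.grid, 2, axis=0), 3, axis=2),
                          surf_s.grid)


def test_extract_mirror_equivariance(small_phantom):
    spec, vol = small_phantom
    left, _ = split_lungs(vol)
    surf = extract_diaphragm(left)
    mirrored = BinaryMask(grid=left.grid[::-1].copy(),
                          spacing=left.spacing, side="left")
    surf_m = extract_diaphragm(mirrored)
    assert np.array_equal(surf.grid[::-1], surf_m.grid)
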