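# Methods

## The measurement model

The diaphragm index DI = S/P summarises diaphragm doming: S is the 3D
area of the lung–diaphragm intersection sheet, P its axial projection.
The lung–diaphragm intersection is a *proxy* for the diaphragm: it
covers only the dome region apposed to the lung base, not the zone of
apposition against the rib cage, and it carries no information about
muscle thickness. For a spherical cap of base radius a and height h the
lateral area is π(a² + h²) over a base of πa², so DI = 1 + (h/a)²
exactly — the closed form the phantom validation is built on.

## Extraction pipeline: conventions and parameters

All volumes are reoriented at load time to x: left→right, y:
posterior→anterior, z: caudal→cranial (a coronal slice is the (x, z)
plane at fixed y; "most caudal" = smallest z). Label volumes are
resampled to isotropic grids (default 1 mm) by nearest neighbour — a
segmentation must never be intensity-interpolated — with output shape
ceil(extent/target) per axis so anatomy is never cropped. Lobe labels
merge to lungs via a configurable map (default {1,2}→left,
{3,4,5}→right).

Tunable parameters (`ExtractionParams`), all dimensionless or in
voxels:

| parameter | default | meaning |
|---|---|---|
| `lower_fraction` | 1/3 | caudal fraction of the lung's z-extent processed |
| `search_band_fraction` | 0.25 | width fraction of each costophrenic search band |
| `ascent_check_length` | 5 | voxels over which the fallback trace must net-ascend beyond a candidate edge |
| `filter2_min_distance_fraction` | 0.25 | minimum midpoint-to-caudal-point distance as a fraction of arc x-extent |

The ascent length and filter-2 threshold are judgement calls (the
operation definitions bound them only qualitatively: "several pixels",
"too short"); both are exposed rather than hard-coded.

Notable design choices, made where the design was genuinely open:

- **Outline structuring element: 4-connected cross.** Dilation minus
  region with a 3×3 square leaves the outline two voxels thick across
  every diagonal boundary step; removing one voxel per search band then
  essentially never disconnects the ring, and the costophrenic cut —
  the primary path of the method — would always fail over to the trace
  fallback. With the cross, the outline is a one-voxel 8-connected ring
  and the cut succeeds on all but rare degenerate slices (2 of 121 on
  the h=30 reference phantom), which is the intended behaviour.
- **Fallback edge rule.** The "most caudal voxel of a side" is the
  *last* voxel of the side's caudal stretch along the trace (the
  costophrenic corner of a flat-bottomed slice); taking the first tied
  voxel makes flat rim slices fail the ascent check and derail the
  edge search onto the cranial part of the ring.
- **One voxel removed per search band** (two in total): a single
  removal cannot split a closed ring into two components.
- **Tie-breaks** are fixed for determinism: equal caudal z within a
  band → outermost x; equal-size 2D components → first in (z, x) scan
  order; equal halves after the cut → the half holding the caudal
  extreme.
- **Stitching** joins each endpoint of the previous kept arc to the
  nearer endpoint of the current arc (one-to-one, minimum total
  distance) with a digital straight segment and fills the enclosed
  region (4-connected background cannot cross an 8-connected closed
  curve, so a hole fill is exact). Filtered-out slices leave gaps;
  stitching continues from the last kept arc and the final largest
  26-connected-component step removes stray fragments — no bridging is
  attempted.
- **Exact symmetry.** The segment rasteriser includes both voxels at
  exact half-integer ties and the filters use direction-independent
  midpoints, so on thin-curve inputs the pipeline is exactly
  equivariant under integer translation and left–right mirroring, and
  the index is bit-identical under both (verified including the
  asymmetric two-lung phantom, where mirroring swaps the lungs).

## Area estimation

The sheet is reduced to a height map: each occupied (x, y) column maps
to the mean z of its voxels (robust to the local thickening the stitch
fill introduces; max/min were examined and are worse overall). S sums
3D triangle areas over every complete 2×2 cell, averaging the two
diagonal splits (flip-symmetric); P counts the same complete cells
times the cell area. Sharing the footprint makes the flat limit exactly
DI = 1 and guarantees DI ≥ 1 (a triangle's area is never smaller than
its axial projection). Cell contributions are summed in sorted order so
the total does not depend on traversal direction. The combined index
pools areas, (S_L + S_R)/(P_L + P_R), rather than averaging per-side
ratios.

## The phantom generator

`make_cap_phantom` voxelises a cylindrical lung body whose caudal end
is a spherical cap: voxel centres with lateral distance ρ ≤ a and
dome(ρ) ≤ z ≤ z_base + lung_height belong to the lung, where
dome(ρ) = √(R² − ρ²) − (R − h) and R = (a² + h²)/(2h). Only the lower
third matters to the algorithm, so the cylinder body is a deliberate
simplification; its height is kept ≥ 3.2 h so the dome lies entirely
inside the lower third, mirroring real anatomy (dome height ≪ lung
height) and keeping coronal cross-sections simply connected. Lobe
labels are painted in z-bands so the lobe→lung merge is exercised.
Generation is fully deterministic; an optional seeded roughening
perturbs the dome by ±1 voxel per column for robustness tests.

What the phantom does *not* emulate: real lung-base anatomy (cardiac
notch, mediastinal contact, costophrenic recess geometry), segmentation
noise beyond the ±1-voxel roughening, anisotropic acquisition, and
pathology such as pleural effusion. Passing the phantom ladder shows
the geometry pipeline recovers known dome shapes; it does not certify
accuracy on clinical segmentations, whose failure modes (missing
hemidiaphragm halves, spurious inclusions) are what the cohort-level
IQR flagging and visual-inspection defect labels are for.

## Accuracy on the phantom ladder

At a = 60 mm and 1 mm voxels the measured index recovers 1 + (h/a)²
within 5% for h ≤ 48 mm (+4.6% at h = 12 down to −2.4% at h = 48), is
exactly 1.000 in the flat limit, and increases strictly with h. The
hemisphere extreme h = a under-reads by ≈ 12%: a height field sampled
on a unit grid cannot represent the near-vertical rim annulus (an ideal
voxelised hemisphere sheet already under-reads by ≈ 8%), and the
per-slice cut removes the costophrenic corner voxels, trimming the
outermost column ring which at h = a carries a large share of the cap
area. Interior columns track the analytic dome to within 1.5 voxels
for > 99% of the footprint. Clinically reported indices (≈ 1.5–1.9)
lie well inside the accurately recovered range.

Small-h phantoms read slightly high because the extracted sheet is the
outline (one voxel caudal of the lung boundary) and staircase
discretisation adds spurious area; the effect shrinks as real doming
dominates.

## Cohort QC

Group quartiles use linear interpolation between order statistics
(numpy's default); values outside [Q1 − 1.5·IQR, Q3 + 1.5·IQR] are
flagged per group. Groups with fewer than 4 records are skipped with a
warning — quartiles are not meaningful there. Summaries report n,
mean, sample SD (n−1), min and max per group; SD is absent for
singleton groups. Defect labels (none / minor / major — minor: less
than half of one or both hemidiaphragm domes missing and/or a small
spurious inclusion; major: more than half missing and/or a significant
inclusion) are a recording vocabulary for human inspection; the
package tabulates their rates but does not assign them.

## Known limitations

- The method measures the lung–diaphragm intersection, not the
  diaphragm; the zone of apposition and muscle thickness are out of
  reach by construction.
- Bit-exact mirror equivariance holds for thin-curve outlines; on
  degenerate clumpy outlines (e.g. heavily roughened phantoms) arc
  components are not simple curves, best-effort path ordering is
  orientation-dependent, and repeat runs — though still deterministic —
  are not guaranteed bit-identical to their mirror image.
- Very small masks (outline shorter than twice the ascent-check
  length) are skipped per slice; a lung whose every slice is skipped
  raises an extraction failure with the per-slice log attached.
- Surface roughening aside, no CT intensity simulation is provided;
  emphysema scoring expects a real co-registered HU volume.
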