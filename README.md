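# diaphragmct

Automated quantification of diaphragm configuration from chest-CT lung
segmentations.

In severe COPD, hyperinflation flattens the diaphragm dome and impairs
its function. Because the diaphragm's soft-tissue density matches the
liver and other abdominal organs, segmenting the muscle itself on CT is
unreliable; instead, this package extracts the **lung–diaphragm
intersection** — the caudal surface of the lung segmentation resting on
the diaphragm — and summarises its shape as the **diaphragm index**

```
DI = S / P
```

where *S* is the surface area of the extracted sheet and *P* is its
area projected onto a single axial plane. A perfectly flat diaphragm
scores DI = 1; a hemispherical dome scores DI = 2. Lower values indicate
a flatter, more hyperinflated configuration. The package is aimed at
thoracic-imaging researchers who already have lobe or lung segmentations
(NIfTI or MetaImage) and want a reproducible, fully automatic shape
biomarker per scan, per lung, and pooled across lungs.

## Method

Per lung (after resampling the input label volume to 1 mm isotropic and
merging lobe labels):

1. keep the lower third of the lung's cranio-caudal extent;
2. per coronal slice: keep the largest connected component, outline it
   (morphological dilation minus the region), and cut the outline at the
   two costophrenic points — the most caudal outline voxels within
   search bands covering the first and last 25% of the outline width.
   The smaller of the two resulting pieces is the lung–diaphragm
   intersection arc; when the cut cannot split the outline, the arc is
   traced from the most caudal midpoint outward instead;
3. two shape filters drop arcs that cannot be diaphragm (caudally
   sagging at the midpoint, or curving inward);
4. consecutive arcs are stitched (endpoints joined, enclosed space
   filled) into a single 26-connected 3D sheet, and the largest
   component is kept;
5. the sheet is reduced to a height map z(x, y); *S* is its triangulated
   3D area and *P* the area of the same complete-cell footprint, so a
   flat sheet gives exactly DI = 1 and DI ≥ 1 always.

Validation is built in: a synthetic **spherical-cap phantom** generator
produces lungs whose diaphragm is a cap of base radius *a* and height
*h*, with closed-form index `DI = 1 + (h/a)²`. The whole pipeline is
tested against that analytic truth across a ladder of dome heights.

The package also computes the standard emphysema score (%LAA-950: the
percentage of lung voxels below −950 HU) and cohort-level QC: per-group
mean ± SD summaries and the 1.5 × IQR outlier rule used to select scans
for visual inspection, with a minor/major defect label vocabulary.

## Worked example

Generate a two-lung phantom (a = 30 mm; dome heights 15 mm left, 24 mm
right), extract both diaphragm surfaces and compute the index:

```
$ diaphragmct phantom --a 30 --h 15 --two-lungs --h-right 24 --out phantom.nii.gz
phantom written to phantom.nii.gz (sidecar phantom.json)
$ diaphragmct extract --in phantom.nii.gz --out-dir out
left: 3889 voxels -> out/diaphragm_left.nii.gz
right: 5047 voxels -> out/diaphragm_right.nii.gz
$ diaphragmct index --surface-left out/diaphragm_left.nii.gz \
                    --surface-right out/diaphragm_right.nii.gz --out report.json
combined diaphragm index: 1.400
```

The analytic per-side indices are 1 + (15/30)² = 1.25 and
1 + (24/30)² = 1.64; the combined index pools areas across sides,
(S_L + S_R)/(P_L + P_R), and lands between them. `report.json` carries
the per-side and combined surface areas (mm²), projected areas (mm²)
and indices.

Cohort QC from a CSV with columns `subject_id, group, diaphragm_index`:

```
$ diaphragmct cohort --csv cohort.csv --out-prefix qc
1 groups summarised; 1 outliers flagged
```

The same functionality is available as a library
(`diaphragmct.extract_diaphragm`, `diaphragmct.diaphragm_index`,
`diaphragmct.flag_outliers`, ...).

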