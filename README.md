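# vesel

Automated registration, 3D segmentation and quantitative morphometry of
synaptic-vesicle-like objects in electron tomogram stacks — plus a
synthetic phantom generator and a precision/recall evaluation harness so
every pipeline stage is testable without real tomograms.

The pipeline mirrors a two-macro workflow:

1. **register** — preprocessing (rescale to 1 nm/px in x/y, global
   contrast stretch with 0.4% saturation, per-slice mean filter of
   radius 3.45 px, per-slice bilateral filter), per-slice mean
   thresholding, cell-region masking via two hand-traced boundary
   polygons interpolated across slices, bounded hole filling (0–575 px),
   2D watershed splitting, erosion + removal of 2D components above
   6000 px, anisotropic 3D Euclidean distance map, Gaussian smoothing
   (sigma 3.45), seeded 3D watershed (map threshold 2, seed radius
   2.3 px), and removal of candidates failing the organism exclusion
   criteria (volume / sphericity / elongation).
2. **measure** — optional scripted proof-reading edits
   (`delete <id>` / `merge <a> <b>`), re-measurement, nearest-neighbor
   distances and the membrane-corrected mean diameter
   (default offset 8.9 nm).

All volumes are (z, y, x); x = column, y = row, 0-based; lengths in nm.

## CLI

```sh
# generate a synthetic phantom with ground truth
vesel simulate --config phantom.yaml --seed 1 --out-dir sim/

# stage I: detect vesicle candidates
vesel register --stack sim/phantom.mrc \
    --roi-first sim/roi_first.txt --roi-last sim/roi_last.txt \
    --preset celegans --out-dir run/

# stage II: (optional) edits, neighbors, corrected diameters
vesel measure --labels run/labels.tif --edits edits.txt \
    --neighbors 3 --membrane-offset 8.9 --out-dir run/

# compare against ground truth
vesel evaluate --truth sim/ground_truth.csv --pred run/vesicles.csv \
    --max-dist 20 --out metrics.csv
```

Presets fix the exclusion criteria: `zebrafish_30k` (min volume 6500
voxels), `zebrafish_20k` (5000), `celegans` (3000); all use minimum
sphericity 0.5 and maximum elongation 2.0. Explicit flags and config
file values override preset values. `register` writes `labels.tif`,
`candidates.csv`, a contour-overlay `composite.tif` and a
`manifest.json` that records every parameter, the seed and library
versions; reruns with the same inputs are byte-identical.

ROI files are plain text: a `slice <index>` line followed by one
`x y` vertex pair per line (≥ 3 vertices, positive area).

Result CSVs have columns `label, center_x_nm, center_y_nm, center_z_nm,
volume_nm3, feret_nm, diam1_nm, diam2_nm, diam3_nm, mean_diam_nm,
corrected_diam_nm, sphericity, elongation, dist_nn1_nm …
dist_nnN_nm` (13 + n columns for n neighbors).

## Thresholding polarity

The detector registers the membrane-bounded **lumina**: vesicle
interiors are brighter than the granular cytoplasmic field, the dark
membrane mesh interconnects and is eliminated by the 6000 px
large-component filter, and the reported `mean_diam_nm` therefore
tracks the *inner* vesicle diameter (add the membrane offset for the
outer convention). `threshold_mean` also supports the dark polarity
(`--polarity dark`) for electron-dense foreground extraction.

## Acceptance

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

runs the end-to-end phantom recovery and prints precision, recall,
error rate and diameter bias; the quantitative acceptance contract
itself is property-based and lives in `tests/test_acceptance.py`
(end-to-end recovery, diameter fidelity, confounder rejection, doublet
splitting, oracle-equivalence suites, worked-example arithmetic,
determinism).
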