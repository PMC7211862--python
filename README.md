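# nmjmorph

Automated neuromuscular-junction (NMJ) morphometry: a scriptable library and
batch CLI that computes **19 pre-/post-synaptic morphological variables** per
NMJ from two-channel fluorescence images (nerve-terminal stain + acetylcholine
receptor/AChR stain) and writes a curated CSV results table.

The analysis runs as a seven-stage flow per image:

1. per-channel maximum-intensity projection of the z-stack
2. AChR thresholding
3. nerve thresholding
4. axon measure/erase (from user-supplied annotations)
5. post-synaptic measures + endplate footprint construction
6. segmentation check + AChR cluster counting
7. record assembly

The 19 variables:

| pre-synaptic | post-synaptic | associated |
|---|---|---|
| nerve terminal area (µm²) | AChR area (µm²) | axon diameter (µm) |
| nerve terminal perimeter (µm) | AChR perimeter (µm) | |
| number of terminal branches | endplate area (µm²) | |
| number of branch points | endplate perimeter (µm) | |
| total branch length (µm) | endplate diameter (µm, max caliper/Feret) | |
| average branch length (µm) | number of AChR clusters | |
| complexity | average AChR cluster area (µm²) | |
| | fragmentation | |
| | compactness (%) | |
| | overlap (%) | |
| | synaptic contact area (µm²) | |

Notable automation behaviours:

- **Footprint-restricted cluster counting**: watershed-segmented AChR
  particles are hole-filled individually and recombined onto the endplate
  footprint; a cluster fully enclosed inside a hole of another is absorbed by
  its host, and extraneous particles outside the endplate are excluded.
- **Feret endplate diameter**: maximum caliper distance over the convex hull
  of foreground pixel corners (unit-square pixel model).
- **Aberrant-segmentation QC** ("spider web"/"broken window" images):
  flagged automatically by particle-count and median-area heuristics;
  cluster-dependent fields are recorded as missing while every other
  variable is still measured.

## Input formats

TIFF / OME-TIFF only (2-D images are accepted as depth-1 stacks). Proprietary
microscope formats (.lsm, .nd2, ...) must be converted to TIFF first.
Spatial calibration is taken from OME `PhysicalSize` metadata, then TIFF
resolution tags, then a config override — a missing calibration is an error,
never a silent default. Channel assignment is explicit in the config.

## CLI

```bash
# list the pipeline stages
nmjmorph analyze --dry-run .

# single image or folder (batch runs cycle through images in sorted order;
# per-image failures are logged and skipped)
nmjmorph analyze images/ --config cfg.yaml \
    --axon-sidecar axon.csv --thresholds thresholds.csv -o results.csv

# synthetic fixtures with ground-truth sidecars
nmjmorph simulate --preset nominal --seed 1 -o fixtures/
nmjmorph simulate --preset batch40 --seed 1 -o fixtures/

# per-variable Pearson/Spearman concordance between two result tables
nmjmorph validate results_a.csv results_b.csv
```

Example `cfg.yaml`:

```yaml
channel_map: {nerve: 0, achr: 1}
calibration_um_per_px: 0.1      # fallback when files carry no metadata
threshold:
  method: manual                # or otsu
  value: {nerve: 100, achr: 100}
footprint:
  method: convex_hull           # or close_fill
  close_radius_px: 10
qc:
  max_clusters: 50
  min_cluster_area_um2: 0.25
```

Axon annotations (line endpoints for the diameter, polygon to erase the axon
after measurement) come from a sidecar CSV with columns
`image_id,role,order,row,col` where `role` is `line` (2 rows) or `erase`
(≥3 polygon vertices), coordinates 0-based (row, col) pixels.

Interactive confirmations (threshold preview, segmentation check) are behind
`--interactive`; the default is fully headless.

## Synthetic fixtures

`nmjmorph.synthetic` generates two-channel stacks with exhaustively known
ground truth (cluster geometry, branch topology, analytic metric record):
presets `nominal`, `enclosed` (a cluster inside another's hole), `extraneous`,
`spiderweb`, `low_quality`, `batch40`. Fixtures ship as generator code;
rasterization uses a fixed pixel-centre-in-shape rule so analytic-vs-measured
tolerances are computable.

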