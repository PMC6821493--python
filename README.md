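# synapsequant

Quantifying cSMAC formation at the T cell:antigen-presenting-cell interface.

When a T cell recognizes antigen on an APC, signaling proteins such as LAT
organize into µm-scale structures at the cell couple's contact interface —
most prominently the central supramolecular activation cluster (cSMAC).
`synapsequant` is a reusable Python implementation of the image-analysis and
statistics stack used to quantify this organization from 3D time-lapse
fluorescence microscopy, super-resolution (STED) imaging and correlative
electron microscopy:

* **Interface-pattern classification** — each cell couple at each 20-s frame
  is assigned to one of six mutually exclusive patterns (central,
  invagination, diffuse, lamellal, peripheral, asymmetric) or "none". An
  accumulation region is any connected set of voxels whose fluorescence
  exceeds the cellular background (median over the segmented cell) by more
  than 40%; the region's geometric features — fraction of the interface
  covered, radial location within the interface disc, and extension away
  from the interface — decide the label.
* **Shape standardization and interface enrichment** — the T cell is
  segmented, reoriented interface-up by a two-point synapse annotation, and
  radially resampled onto a half-spheroid template that contains exactly
  **6628 voxels** on the native grid (0.34 µm lateral, 1 µm axial). Each
  cell-frame becomes a probability vector **p** (fractions of total
  intensity); enrichment is

  E = mean(p over R) / mean(p over all 6628 voxels),

  where R is the fixed region holding the 10% most fluorescent voxels
  (663) of the average distribution over all cells, time points and sensors.
* **Calibrated 3D puncta sizing** — puncta in deconvolved STED-like volumes
  are thresholded at 3.5 × the Otsu threshold, split by a 3D watershed
  seeded at distance-transform maxima (≥ 0.1 µm apart), and sized in µm³. A
  detection floor is calibrated as the 95th percentile of punctum sizes in
  control cells that do not express the protein; everything smaller is
  excluded.
* **Membrane-undulation morphometrics** — from a traced EM-section membrane
  polyline, the undulation ratio = arc length / straight-line chord per
  interface region; the interface diameter is cut into four equal sections,
  the central two forming the cSMAC.
* **Time-course statistics** — pairwise pooled two-proportion z-tests on
  pattern frequencies over −40…420 s, analytic/simulated power, Chauvenet
  outlier rejection, log-transform ANOVA (Tukey or Sidak post-hoc), and
  hierarchical clustering of sensor × (pattern, time) frequency matrices on
  1 − Pearson correlation with average linkage.
* **Synthetic-data generator** — ground-truthed cell-couple movies (spherical
  T cell truncated by a planar contact disc, Poisson + Gaussian noise),
  cohorts following a pattern-frequency schedule, STED-like puncta fields of
  known volumes, and sinusoidal membrane traces with quadrature-exact arc
  lengths. Every analysis step can therefore be validated against known
  truth.

## Worked example

Simulate a cell couple with central accumulation, classify its frames,
standardize its shape, and test a frequency difference:

```python
from synapsequant import (SimConfig, PatternScript, make_cell_couple,
                          build_template, segment_t_cell, standardize_shape,
                          compute_enrichment_region, enrichment,
                          proportion_z_test)
from synapsequant.pipeline import classify_series, find_cell_seed

cfg = SimConfig(seed=1, n_frames=5)
series, truth = make_cell_couple(cfg, PatternScript.uniform("central", 5))
calls = classify_series(series, coupling_frame=0, cell_id="demo")
print(calls[["time_s", "label", "coverage", "radial_fraction", "depth_um"]])
```

```
 time_s   label  coverage  radial_fraction  depth_um
    0.0 central     0.106            0.000       0.5
   20.0 central     0.109            0.009       0.5
   ...
```

Every frame is called `central`: the detected region covers ~11% of the
interface disc, sits on the axis (radial fraction ≈ 0) and extends only
0.5 µm into the cell — a cSMAC, not an invagination.

```python
template = build_template()                      # 6628 voxels exactly
vol = series.data[0]
mask = segment_t_cell(vol, find_cell_seed(vol, series.spacing), series.spacing)
cell = standardize_shape(vol, mask, template, series.spacing)
region = compute_enrichment_region([cell])
print(f"interface enrichment: {enrichment(cell, region):.2f}")
# interface enrichment: 1.29

r = proportion_z_test(29, 60, 15, 60)            # e.g. 48% vs 25% central
print(f"z = {r.z:.3f}, p = {r.p:.4f}")
# z = 2.652, p = 0.0080
```

An enrichment of 1.29 means the interface region holds 29% more probability
mass than a uniform cell would place there; the z-test says a 48% vs 25%
difference in central-pattern occurrence at n = 60 per condition is highly
significant.

A command-line interface mirrors the library:

```bash
synapsequant simulate couple --seed 1 --label central --out data/
synapsequant classify --volumes data/ --out calls.tsv
synapsequant tabulate --calls calls.tsv --out freq.tsv
synapsequant stats power --p1 0.35 --p2 0.65 --n 50
```

## Layout

```
src/synapsequant/
  synthgen.py     ground-truthed synthetic movies, puncta fields, traces
  standardize.py  segmentation, reorientation, 6628-voxel template, enrichment
  patterns.py     accumulation detection, six-pattern classifier, frequencies
  puncta.py       Otsu x 3.5 thresholding, watershed, size calibration
  membrane.py     arc-length/chord undulation ratios, interface quartering
  stats.py        z-tests, power, Chauvenet, log-ANOVA, sensor clustering
  pipeline.py     end-to-end glue (seed finding, per-movie classification)
  io.py           OME-TIFF / CSV / TSV / JSON readers and writers
  cli.py          `synapsequant` command-line interface
docs/methods.md   models, assumptions, parameter choices, limitations
```
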