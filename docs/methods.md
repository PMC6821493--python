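# Methods

This note documents the models, parameter choices and numerical conventions
behind `synapsequant`, and what the synthetic-data validation does and does
not establish about real imaging data.

## Imaging model and coordinate conventions

All volumes are indexed `(z, y, x)` with `spacing` triples in the same order;
the default acquisition grid is 1 µm axial × 0.34 µm lateral, one 3D stack
every 20 s for 46 frames. "Up" — toward the T cell:APC interface — is the
direction of decreasing z index. Physical positions are `index × spacing`,
so voxel centers lie on integer multiples of the spacing.

## Tight cell coupling (time zero)

The time course is aligned to tight couple formation: the earlier of (a) the
first frame where the interface reaches full width and (b) 40 s (two frames)
after first contact. "Full width" is not a visual judgment here but
≥ 90% of the steady-state width, with steady state taken as the median width
over the final 25% of frames. Both the 0.9 fraction and the two-frame lag
are parameters of `detect_tight_coupling`.

## Segmentation and reorientation

The T cell is segmented by Otsu thresholding restricted to a neighborhood of
twice the nominal cell radius around a seed point, followed by connected-
component selection (26-connectivity) containing the seed. A cell whose
surface touches the volume border over more than 25% of its boundary raises
a truncation warning rather than an error, since partial cells can still be
classified.

Reorientation uses the two-point synapse annotation: point 1 is the
interface center, point 2 the cell's rear pole; the rear→center axis is
rotated onto the vertical. The rotation is performed in physical
coordinates (so the anisotropic grid is handled exactly), about the volume's
physical center. Before resampling, voxels outside the mask are filled with
their nearest masked intensity so that interpolation at the cell edge does
not dilute the cell with background; intensities are resampled with cubic
splines (the mask trilinearly, thresholded at 0.5). Masked intensity is
conserved to well within 1%. Note the returned volume carries fill values
outside the mask; downstream consumers use the mask.

## The half-spheroid template

Cells are compared voxel-by-voxel after mapping onto a standardized half
spheroid whose interior holds exactly 6628 voxels on the native grid. The
count, not the semi-axes, is the defining constraint, so the semi-axes are
calibrated by a grid search (lateral and axial semi-axes 2–8 µm in 0.01-µm
steps) for pairs whose interior voxel-center count is exactly 6628; among
the 11 solutions the pair with lateral/axial aspect ratio closest to 1.5 is
kept. Within these search bounds all exact solutions are near-spherical;
the selected pair is a = 6.99 µm lateral, c = 7.51 µm axial (aspect 0.93).
A flatter template of equal count would require a lateral semi-axis beyond
8 µm — larger than a primary T cell — so the bounded search is retained.
The template's voxel order is the C-order scan of the (layer, y, x) grid
with the interface-adjacent layer first; this fixed order is the tie-break
wherever one is needed (most visibly in the enrichment region for perfectly
uniform inputs).

Shape standardization is a radial mapping: for every template voxel, a ray
is cast from the interface center through the voxel's direction; the cell's
radial extent along that ray (first exit of the segmentation mask, marched
at half the smallest voxel pitch) is linearly rescaled to the template's
extent, and intensity is sampled at the rescaled point by trilinear
interpolation after nearest-inside filling. The resulting 6628-vector is
clipped at zero and normalized to sum to 1, making it a probability
distribution (fractions of total intensity). Because the mapping is
ray-based, a star-shaped cell (with respect to the interface center) is
assumed; strongly concave cells would alias.

The enrichment region is computed once per dataset as the 663 (= 10% of
6628) voxels with the highest average probability across all supplied cells,
time points and sensors, and is stored as an artifact; per-cell enrichment
always uses this global region. Enrichment is bounded by [0, 6628/663].

## Pattern detection and classification

Cellular background is the median intensity over the cell mask — robust to
the accumulation itself occupying a minority of the cell. An accumulation
region is the largest 26-connected component of voxels strictly above
1.4 × background inside the mask; regions below 0.2 µm³ (< 2 voxels) are
treated as noise. For noisy movies the per-frame pipeline pre-smooths with a
small Gaussian (σ = 0.3 µm, per axis in voxel units) before thresholding;
with Poisson shot noise at ~50 photons per background voxel this suppresses
single-voxel excursions above the 1.4× line without shifting µm-scale region
boundaries appreciably.

Feature extraction measures, relative to the interface disc estimated from
the top mask layer: coverage (projected region area within the disc / disc
area), radial centroid fraction (in-plane centroid distance from the axis /
disc radius), depth (maximum distance of region voxels from the interface
plane, measured beneath the disc), central depth (the same beneath the
central half of the disc), the number of connected rim components
(projected, at radial fraction ≥ 0.7 within a 1.5-µm interface shell), an
annularity flag (rim signal occupies all 16 angular bins), and the fraction
of region voxels laterally beyond the disc rim.

The classifier is an exhaustive decision list; with the default thresholds
(all configurable via `PatternThresholds`):

1. no region → **none**;
2. central depth ≥ 1.5 µm → **invagination**;
3. coverage > 0.6 → **diffuse** if > 5% of the region lies laterally beyond
   the rim (signal running along the cortex), else **lamellal**;
4. annular or ≥ 2 rim components → **peripheral**;
5. radial centroid fraction ≤ 0.5 → **central**;
6. otherwise → **asymmetric**.

Two ordering choices deserve comment. Depth is measured beneath the
interface disc (centrally for the invagination test) because an invagination
is a central intrusion of the interface; cortical signal running down the
cell's sides also extends far from the interface plane but is lateral to the
disc and must not be mistaken for one. The annularity test precedes the
centrality test because a symmetric peripheral ring has its centroid on the
axis; judged by centroid location alone it would read as central. The
"central half" convention (radial fraction ≤ 0.5) deliberately matches the
EM quartering, where the central two of four sections are the cSMAC.

Frequencies are tabulated per condition, time point and label over the
−40…420 s grid; a cell not observed at a time point (e.g. coupled at movie
start) is excluded from that time point's denominator. The conventional
"periphery" series is reported as asymmetric + peripheral.

## Puncta analysis

Puncta are binarized at 3.5 × the Otsu threshold (256-bin histogram); "3.5
A.U." is interpreted as a multiplier on the Otsu value, the convention of
the common 3D-spot plugins, and is exposed as a parameter. Touching
particles are split by a watershed on the negated Euclidean distance
transform (anisotropy-aware), seeded at distance maxima thinned greedily to
a minimum physical separation of 0.1 µm — the closest distance at which
adjacent puncta are considered resolvable. Volumes are voxel count × voxel
volume.

The detection floor is the 95th percentile (linear interpolation between
order statistics) of punctum volumes measured in control cells that do not
express the protein; a punctum is retained iff its volume is at least this
cutoff. Group summaries report mean volume ± SEM and puncta count per cell
for cSMAC-positive versus cSMAC-negative cells (the grouping is an input
label, not computed here) and compare groups with a two-sample Student's
t-test (equal variances).

## Membrane undulation

Undulation is measured per 2D EM section: the ratio of the traced membrane
arc length to the straight-line chord of the same region, so 1.0 is a flat
membrane. The interface diameter is divided into four equal sections by
orthogonal projection onto the chord; polyline segments are split by linear
interpolation exactly where their projection crosses a quarter boundary, so
section arc lengths add up to the whole-trace length exactly. The central
two sections form the cSMAC (a conservative convention — real cSMACs are
usually smaller than half the diameter), the outer two the left and right
pSMAC; each section's "diameter" is its chord portion (L/4 or L/2), keeping
ratios comparable across regions. Control couples without a cSMAC are
analyzed across the entire interface as a single region. Projections falling
outside the chord (membrane overhang) are clamped and flagged. Ratios are
computed on the raw polyline; no smoothing is applied.

## Statistics

Proportion comparisons use the pooled two-proportion z-test, two-sided, at
α = 0.05 per comparison and uncorrected for multiplicity. A pooled
proportion of 0 or 1 carries no information; z is defined as 0 and p as 1.
Power is computed with the standard normal approximation (pooled standard
error under the null, unpooled under the alternative); a Monte-Carlo option
(≥ 10⁴ replicates) agrees with the analytic value to within 2 percentage
points. The design statement — a 30-point difference detectable with power
0.8 — is evaluated at the worst-case baseline (0.35 vs 0.65) and the lower
bound of the 50–100 couples-per-condition range, making it a checkable lower
bound.

Chauvenet's criterion is applied in a single pass with the sample mean and
standard deviation (ddof = 1): value i is rejected iff
n · P(|Z| ≥ |vᵢ − x̄|/s) < 0.5. Scalar readouts spanning decades (IL-2
mRNA-like data) are natural-log transformed before ANOVA — one-way with
Tukey HSD, or two-way (type-II, with interaction) with Sidak-adjusted
pairwise contrasts.

Sensor clustering uses 1 − Pearson correlation of the sensor × (pattern,
time) frequency rows with average linkage — the common defaults of the
classic gene-cluster tools, exposed in the API since the metric is a
convention, not a derivation. Missing cells are imputed as 0 and flagged; a
constant row has undefined correlation and is placed at the maximum distance
(1) from all others, flagged. Trees are exportable as Newick with
ultrametric branch lengths.

## The synthetic-data generator

The generator defines the validation conditions:

* **Cell couple**: a T cell modeled as a 5-µm sphere truncated by a planar
  contact disc of radius 3 µm; the APC is a dark half-space (the analysis
  uses only the T cell channel). Cellular background 100 a.u.; accumulation
  regions at 2 × background by default; Poisson shot noise at 50 expected
  photons per background voxel plus 2 a.u. Gaussian read noise. For
  grid-aligned couples the contact plane is snapped onto a voxel boundary so
  the first cell layer sits half a voxel beneath the interface — without
  this, µm-thin interface patterns can fall between the 1-µm-spaced axial
  voxel centers for unlucky cell sizes.
* **Pattern geometries** (defaults): central — a patch of 0.4 × the
  interface radius, ≤ 1 µm thick; invagination — a central cylinder of
  0.25 × the interface radius reaching 2 µm into the cell; lamellal — a
  ≤ 0.9-µm interface-wide slab; diffuse — the interface slab plus a 0.8-µm
  cortical shell down to 3 µm depth; peripheral — a rim annulus (inner
  radius 0.7 × interface radius); asymmetric — a 90° arc of that annulus.
* **STED fields**: puncta are sharp uniform spheres of the requested volume
  over a near-black half-normal speckle background (σ = 4 against peak
  intensities of 140–200), emulating strongly deconvolved data; a residual
  Gaussian PSF can be re-introduced via `psf_sigma_um`. This regime is what
  makes the 3.5 × Otsu threshold meaningful: with sparse sharp puncta the
  histogram gap is empty, Otsu settles just above the background speckle,
  and the threshold lands stably between speckle and the dimmest punctum,
  where hard-sphere volumes are insensitive to its exact value. With large
  soft (Gaussian-profile) puncta, by contrast, flank voxels fill the
  histogram gap, Otsu drifts toward mid-gap and 3.5 × Otsu can exceed the
  peak — so recovery accuracy on real, partially deconvolved data depends on
  deconvolution quality in a way the synthetic validation does not probe.
* **Membrane traces**: y = A·sin(2πx/λ) polylines; ground-truth arc length
  by adaptive quadrature of √(1 + A²k²cos²(kx)). Spans that are integer
  multiples of the wavelength keep the trace ends on the chord endpoints,
  as the trace invariant requires.

What passing the synthetic suite shows: the geometry, calibration and
statistics are implemented correctly, and the pipeline inverts the
generator's forward model essentially exactly. What it does not show: that
segmentation, background estimation or pattern thresholds are robust to real
cells' irregular shapes, heterogeneous expression, photobleaching, drift, or
imperfect deconvolution — none of which the generator emulates.

## Problem sizes used in the validation suite

The suite favors sizes a single CPU handles in seconds while keeping the
statistics meaningful: pattern round-trips use 20 couples per label with
cell radius 4.6–5.4 µm and interface radius 2.6–3.2 µm; cohort recovery uses
60 cells over a 0–120 s schedule (49% → 25% central decay) under default
noise, checked against 95% binomial confidence bands; puncta recovery uses
two 12-cell groups with on average four puncta per cell (lognormal volumes,
CV 25%, means 0.23 and 0.12 µm³) plus injected sub-cutoff debris and six
control fields for the size calibration; z-test calibration uses 10⁴ null
replicates at n = 60 per arm.

## Known limitations

* The radial shape mapping assumes a star-shaped cell; deeply folded or
  dumbbell-shaped cells are not representable on the template.
* Interface-disc geometry is estimated from the top layer of the segmented
  mask, which slightly overestimates the contact-disc radius for strongly
  curved cells (the truncated sphere is widest just below the contact
  plane); classifier thresholds absorb this at default geometry.
* The six-pattern thresholds reproduce the published one-line definitions,
  not the original numeric criteria (which live in prior work's supplementary
  material); they are config-exposed for recalibration.
* Rotation invariance of enrichment is limited by the 3:1 anisotropy of the
  acquisition grid: a cell imaged at 90° to the reference orientation
  carries its fine structure in the coarsely sampled axis, and enrichment
  of a sharply bounded accumulation can shift by ~2%.
* No deconvolution, drift correction, multi-channel registration, APC
  segmentation or q-value estimation is provided.
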