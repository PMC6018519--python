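# Methods

This note documents the models, defaults and numerical choices behind
`lc3screen`, and what the synthetic benchmark does and does not show about
real screen data.

## The screen being modeled

A 96-well high-content screen for small-molecule modulators of nuclear LC3.
Border wells (36 of 96) carry vehicle (DMSO/PBS); interior wells carry one
library compound each, by default at 8.89 µM, in 2–4 independent replicate
plates. Each well is imaged in two 16-bit channels, DNA (Hoechst) and LC3
(TRITC); acquisitions may arrive as 2×2 montages that are split into single
fields before analysis. The readouts per well are nuclear LC3 intensity,
cytoplasmic LC3 intensity, nuclear holes per nucleus, nuclear area and cell
density.

## Segmentation

**MoG threshold.** Nuclei are separated from background by thresholding the
σ = 1 px Gaussian-smoothed DNA channel. A two-component Gaussian mixture
with a *tied* variance is fitted to the log-transformed intensities by EM
(≤ 200 iterations, relative log-likelihood tolerance 1e-6) with a fixed,
deterministic initialization: component means at the 25th and 90th
log-percentiles, weights ½. The threshold is the intensity where the
posterior responsibility of the brighter component reaches 0.5, which for
tied variances has the closed form
`log t = (μ₀+μ₁)/2 + σ² ln(w₀/w₁)/(μ₁−μ₀)` and always lies between the two
means. The variance is tied deliberately: with free variances the
background component of a low-noise image collapses onto a near-delta and
the posterior-0.5 crossing degenerates to the background mode, swallowing
the smoothing halo into the foreground. If EM does not converge the
between-class-variance (Otsu) threshold is used and flagged. A constant
field raises a degenerate-input error at the threshold level and yields an
empty labeling (with a warning) at the segmentation level — a blank field is
a legitimate outcome.

**Nuclei.** Foreground pixels are labeled with 8-connectivity; interior
holes of each component are filled (low-DNA holes are features *of* a
nucleus and must remain part of its mask to be measurable); components
outside [50, 5000] px are removed; labels are renumbered in raster-scan
order, making the labeling a deterministic function of the raster. The
recovered boundary sits 1–2 px outside a hard synthetic edge (the smoothing
halo crosses the posterior-0.5 threshold slightly outside the true edge), so
per-object IoU against hard-ellipse truth is typically 0.6–0.85 while object
counts and IoU-0.5 matching are exact on noiseless renders. Border-touching
nuclei are kept by default (`exclude_border_nuclei` flips this).

**Rings.** A cell's cytoplasmic ring is the disk-dilation of its nucleus by
`ring_radius` (default 10 px) minus all nuclear pixels; contested pixels go
to the nucleus at the smallest Euclidean distance, ties to the lower label
(implemented as per-label distance transforms with a strict-less update, so
the tie rule is exact). Rings partition: no pixel carries two labels.

**Holes.** Within each nucleus, pixels of the smoothed DNA channel below
`hole_intensity_fraction` (default 0.5) of that nucleus's median intensity
form hole candidates; 8-connected components with area ≥ `hole_min_area`
(default 10 px) that do not touch the nuclear boundary are holes.
Boundary-touching low regions are indentations, not holes.

**Puncta.** The LC3 channel's white top-hat (disk radius 3 px) isolates
structures smaller than the disk. Per cell, candidate pixels exceed
mean + `puncta_k_sigma`·SD (default k = 3) of the response over the combined
nucleus∪ring region; components ≥ 2 px become puncta, with compartment
decided by the component's center pixel (nuclear mask takes priority over
ring). The per-cell threshold adapts to each cell's local response
distribution; it presumes at least some genuine puncta in the region (see
generator notes below).

## Cytometry and QC

One record per nucleus: area, eccentricity (form factor 4πA/P² available as
a config alternative), mean DNA and LC3 intensities per compartment, puncta
count/total area/integrated intensity per compartment, hole count. Well
summaries are unweighted means over all cells of the well's QC-passing
fields (a mean of cells, not of field means), plus cell density = cells per
passing field.

Field QC fails a field for: ≤ 2 cells (toxicity indicator), sharpness below
0.25× the plate's median sharpness (sharpness = variance of the discrete
Laplacian divided by the squared mean intensity, invariant to exposure
scaling; the threshold is plate-relative because there is no absolute focus
scale), or presence on a manual exclusion list. A field passes iff no
reason applies; wells with no passing field are omitted and logged.

## Normalization and plate effects

Each plate's well table is divided, per parameter, by that parameter's mean
over included wells, so the plate mean is exactly 1. The operation is
idempotent and invariant to positive rescaling — it removes plate-to-plate
gain, not spatial structure within a plate.

Replicate reliability is the squared Pearson r between two replicate
plates' normalized well values, computed twice: aligned (well w vs w) and
rotated (w vs its 180° partner, (r,c) → (7−r, 11−c), so B3 pairs with G10).
Missing wells are dropped pairwise; fewer than 3 common wells or zero
variance on either side is an error (recorded as a missing entry in the
report rather than aborting it). Under treatment effects the aligned r² is
high and the rotated r² near zero; under spatially structured plate effects
both are elevated — the left-right and radial gradients are (anti)symmetric
under 180° rotation, so a pure gradient yields nearly equal aligned and
rotated r². The report aggregates per pair (mean ± SD across parameters)
and per parameter (mean across pairs), ranked by aligned mean. Whether
correlations are computed on normalized or raw well means is configurable;
normalized is the default here.

## Hit statistics

After normalization a compound's evidence is its 2–4 replicate-well values.
Two tests are provided:

* **One-sample t** against the global average 1.0 (df = n−1). Correctly
  calibrated, but with n = 3 its two-sided α = 0.001 critical value is
  t₂ ≈ 31.6, so the test has essentially no power at screening effect sizes.
* **Vehicle-referenced t** (pipeline default): the null center is the pooled
  normalized vehicle-well mean and the null SD is pooled from the
  per-plate-centered vehicle wells (df = Σ(36−1) per plate ≈ 105 for 3
  replicates), with the two-sample standard error
  `sd·√(1/n + 1/n_vehicle)`. The 36 vehicle border wells exist precisely to
  estimate the null; referencing them also removes the bias that appears
  when active compounds shift the plate mean away from the vehicle level.

A hit is a compound with p < α (default 0.001) on at least one hit
parameter (nuclear LC3, cytoplasmic LC3, holes, nuclear area) that is not
viability-flagged. The default viability rule flags a significant
*decrease* in normalized cell density (p < α, direction down); the
alternative `sd_band` rule flags densities more than 2 SD below the global
compound mean — note the band variant flags ~2.3% of perfectly null
compounds by construction, since the band scales with the noise.

Waterfall rankings sort compounds ascending by mean of replicate means with
lexicographic tie-breaks; the SD of replicate means is the plot's error bar.

## Dose-response and FDR

Follow-up compounds are fit by ordinary least squares of the normalized
response on dose over the serial-dilution grid {1.25, 2.5, 5, 10, 20} µM,
on well-level means (not single cells, to avoid pseudo-replication).
Reported per compound × parameter: slope (per µM), intercept, two-sided p
for slope ≠ 0, F = t² (the simple-regression identity), r², dof = n−2 and
the slope sign. Fewer than 3 points or a constant dose is an error; a
constant response reports slope 0 and r² 0 with a flag. The
Benjamini–Hochberg step-up (adjusted_i = min_{j≥i} p_(j)·m/j, clipped at 1,
flags at adjusted ≤ q = 0.05) is applied within each parameter family
across compounds; a global family is a config switch.

## The synthetic generator

The generator emulates the screen's statistical structure at two levels.

**Well tables** (fast path): vehicle wells draw baseline values; compound
wells draw baseline × planted multiplier; all wells carry multiplicative
lognormal noise with mean exactly 1 and CV `well_cv` (default 5%, a typical
well-to-well CV for normalized HCS readouts). Toxicity scales expected
density by (1−toxicity). Lognormal noise keeps multiplicative effects and
gradients composable without sign violations. Plate gradients are
multiplicative, mean-centered over the 8×12 grid (left-right, top-bottom or
radial), so they perturb spatial structure without moving the plate mean —
isolating plate-effect detection from normalization. With `well_cv = 0` the
normalized value of a compound is exactly its multiplier over the plate's
mean multiplier (a closed form the tests exploit).

**Rendered fields**: non-overlapping elliptical nuclei (axis ratio 0.6–1.0,
semi-axis ~12 px at an emulated 40× scale, ~10–40 cells per 256² field,
default 15) with per-cell brightness jitter; interior low-DNA holes
(Poisson-planted, disk radius 3 px at 10% nuclear intensity); an LC3
channel of smooth diffuse compartment signal (σ = 6 px blur) plus hard
bright puncta disks (radius 2 px, amplitude 20,000 counts). Noise is
signal-dependent Gaussian, sd = `noise_level`·√(I+1) — a shot-plus-read
camera approximation; `noise_level_for_dna_snr` converts a target
foreground SNR into this knob. Ground truth records what was actually
*placed*, and placement enforces recoverability: holes and nuclear puncta
keep an interior margin, puncta keep a minimum mutual separation, and
cytoplasmic puncta keep clearance from neighboring cells' ring partitions.
Every cell receives at least two cytoplasmic puncta (constitutive
autophagosomes), which anchors the per-cell mean+k·SD puncta threshold —
the detector's adaptive threshold needs genuine spots in the region to
scale against, and biologically a basal autophagosome count is the norm.

What the synthetic benchmark does **not** emulate: textured chromatin,
overlapping/touching nuclei (no watershed is implemented), illumination
falloff within a field, focus drift, debris and dye precipitates,
compound auto-fluorescence, or cell-cycle/area covariation. Passing tests
demonstrate the pipeline's correctness under its stated model, not
robustness to those artifacts.

## Numerical and design choices

- Pixel coordinates are 0-based row-major, origin top-left; well columns
  are 1-based as printed on plates. Montage quadrants return in TL, TR,
  BL, BR order (the original acquisition order is not recoverable; the
  convention is fixed and documented).
- TIFF I/O is strictly 16-bit single-channel with no silent conversion, so
  intensity statistics stay comparable across fields.
- 8-connectivity everywhere; smoothing σ = 1 px before thresholding.
- Zero-prediction precision convention in segmentation scoring = 1.0
  (vacuously correct), configurable.
- Matching in `evaluate_segmentation` is greedy one-to-one by descending
  IoU with ties broken toward lower labels, after discarding pairs below
  the IoU threshold.
- Degenerate hit-test inputs: zero replicate variance gives p = 1 at the
  null and p = 0 away from it, flagged.
- Determinism: every generator operation is a pure function of its
  arguments including the seed; segmentation contains no randomized step
  after the fixed EM initialization; pipeline outputs are byte-identical
  given (config, seed). Tables mode re-reads CSVs with round-trip float
  parsing so re-ingested runs reproduce downstream statistics bit-for-bit.

## Problem sizes

Defaults keep everything desk-scale: 256² px fields, ~12–15 cells per
field, one field per well, 96-well plates, 2–4 replicates. The calibration
and power studies in the test suite and acceptance script use 10,000
simulated null compounds, 1,000 power trials, 200 all-null FDR replicates,
20 rendered fields per segmentation condition and 20-seed correlation
studies — sizes at which the binomial error of each estimate is comfortably
inside the asserted bands.

## Known limitations

- The MoG threshold is global per field; strong within-field illumination
  gradients would need a correction step that is out of scope.
- Touching nuclei merge into one label (no watershed); the generator never
  produces them, real data will.
- The vehicle-referenced test assumes compound and vehicle wells share the
  well-level noise scale after normalization; heteroscedastic compounds
  (e.g. strongly toxic wells with few cells) violate this and are only
  partially protected by the viability flag.
- The rotated-plate control detects 180°-symmetric and antisymmetric plate
  effects well (edge/corner gradients); a perfectly rotation-*invariant*
  artifact is indistinguishable from replicate agreement by construction.
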