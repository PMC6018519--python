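# lc3screen

High-content screening analysis for **nuclear LC3 localization**: per-cell
image cytometry, plate quality control, plate-mean normalization, replicate
correlation with a 180°-rotated-plate control, hit selection, and
dose-response validation with Benjamini–Hochberg FDR control — exercised end
to end on a synthetic plate/image generator with pixel-level ground truth.

## Who this is for

Screening groups that quantify autophagy markers (LC3/MAP1LC3B) by automated
fluorescence microscopy on 96-well plates and need a reproducible, tested
pipeline from raw 16-bit TIFFs (or well-level tables) to a hit list. The
synthetic generator doubles as a benchmark: every stage can be validated
against planted ground truth before touching real screen data.

## The analysis

Per field (one DNA/Hoechst and one LC3/TRITC channel):

1. **Nuclei** are traced by mixture-of-Gaussians thresholding: a tied-variance
   two-component Gaussian mixture is fitted to log-intensities by EM and the
   foreground threshold is the posterior-0.5 crossing,
   `log t = (μ₀+μ₁)/2 + σ² ln(w₀/w₁)/(μ₁−μ₀)`.
2. The **cytoplasmic compartment** is a ring: each nuclear mask dilated by a
   set radius (default 10 px), contested pixels to the nearest nucleus.
3. **Nuclear holes** are connected low-DNA regions fully interior to a
   nucleus (below 0.5× its median DNA intensity, ≥ 10 px).
4. **LC3 puncta** are white-top-hat maxima thresholded per cell at
   mean + 3·SD of the response over the nucleus∪ring region, assigned
   nuclear/cytoplasmic by their center pixel.

Cells are pooled per well (Plate > Well > Field > Cell); fields with ≤ 2
cells, low relative sharpness (Var∇²I/Ī² below 0.25× the plate median) or a
manual exclusion are dropped. Each plate is normalized so every parameter's
mean over included wells is exactly 1. Replicate reliability is the squared
Pearson correlation r² between replicate plates, computed aligned (B3↔B3)
and after rotating one plate 180° (B3↔G10): treatment effects give high
aligned and low rotated r², while spatial plate effects (edge evaporation,
temperature) inflate both — a small gap flags plate effects.

A compound's evidence is its 2–4 normalized replicate-well means, tested
against the plate's vehicle (DMSO/PBS) border wells with a
vehicle-referenced t statistic; hits require p < 0.001 on ≥ 1 readout
(nuclear/cytoplasmic LC3 intensity, nuclear holes, nuclear area) without a
significant viability drop. Follow-up fits ordinary least squares of
response on dose over a 1.25–20 µM serial dilution, reporting slope, p, F
(= t²), r² and dof = n−2, with BH correction per readout family.

## Worked example

```python
from lc3screen.config import RunConfig
from lc3screen.pipeline import run_primary_screen

cfg = RunConfig()
cfg.seed = 7
cfg.synthetic.n_compounds = 60
cfg.synthetic.n_replicates = 3
cfg.synthetic.well_cv = 0.05
cfg.synthetic.effects = (
    [{"compound_id": "C001", "effect_multipliers": {"nuclear_lc3_intensity": 1.6}}]
    + [{"compound_id": f"C{i:03d}", "effect_multipliers": {}} for i in range(2, 61)]
)
res = run_primary_screen(cfg, outdir="screen_out")
print(res.log["n_hits"], "hits of", res.log["n_compounds_tested"], "compounds")
row = res.compound_tests.query(
    "compound_id == 'C001' and parameter == 'nuclear_lc3_intensity'"
).iloc[0]
print(f"C001 normalized mean {row.mean_of_means:.3f}  p = {row.p_value:.2e}")
```

prints

```
1 hits of 60 compounds
C001 normalized mean 1.612  p = 3.16e-42
```

The planted +60% compound is the single hit: its normalized nuclear-LC3 mean
(≈ 1.6 divided by the plate mean multiplier) is compared with the 36 vehicle
wells of each of the 3 replicate plates, giving a t of ~23 on 105 df. All
stage outputs (well table, normalized table, correlation report, hit table,
waterfall ranking, run log) land in `screen_out/`.

The same pipeline runs from the shell:

```bash
lc3screen run-all --seed 7 --outdir screen_out          # synthetic table mode
lc3screen config-init --out run.yaml                     # all defaults, documented
lc3screen run-all --config run.yaml --mode images \
    --plate-map P1-R1.csv --plate-map P1-R2.csv --images tiffs/ --outdir out/
```

## Layout

- `lc3screen.synthgen` — synthetic screens: designs, well tables, plate
  gradients, rendered two-channel fields with ground truth, segmentation
  scoring.
- `lc3screen.imaging_io` — strict 16-bit TIFF I/O, 2×2 montage splitting,
  plate-map CSVs, well algebra (including the 180° rotation map).
- `lc3screen.segmentation` — MoG thresholding, nuclei, rings, holes, puncta.
- `lc3screen.cytometry` — per-cell records, image sharpness, well summaries.
- `lc3screen.plate_qc` — field QC flags, plate-mean normalization,
  replicate-correlation report.
- `lc3screen.screen_stats` — hit tests, waterfall ranking, dose-response
  OLS, Benjamini–Hochberg.
- `lc3screen.pipeline` / `lc3screen.cli` — end-to-end orchestration.

See `docs/methods.md` for the model assumptions, parameter defaults and
known limitations.
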