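"""End-to-end orchestration of the screening analysis.

``run_primary_screen`` composes the stages — generate (or ingest) → segment
→ cytometry → field QC → plate-mean normalization → replicate correlation →
hit selection — and writes every stage output plus a run log (config hash,
seed, versions, counts) to the output directory.  ``run_followup`` simulates
or analyzes the dose-response validation screen and applies the
Benjamini-Hochberg correction per parameter family.

Modes: ``synthetic`` (generate a screen; table fast path by default,
rendered images when ``synthetic.render_images`` is true), ``images``
(plate-map CSVs + per-field TIFFs) and ``tables`` (re-ingest a previously
written well table — stage outputs are closed under re-ingestion).
"""

from __future__ import annotations

import hashlib
import itertools
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__, cytometry, imaging_io, plate_qc, screen_stats, synthgen
from .config import RunConfig
from .errors import DesignError, ScreenError
from .imaging_io import PlateLayout
from .synthgen import PARAMETERS, EffectSpec, GradientSpec

logger = logging.getLogger(__name__)


def _effects_from_config(cfg: RunConfig) -> Optional[list[EffectSpec]]:
    if not cfg.synthetic.effects:
        return None
    effects = []
    for d in cfg.synthetic.effects:
        effects.append(
            EffectSpec(
                compound_id=d["compound_id"],
                effect_multipliers=dict(d.get("effect_multipliers", {})),
                toxicity=float(d.get("toxicity", 0.0)),
            )
        )
    return effects


@dataclass
class PrimaryScreenResult:
    """All stage outputs of one primary-screen run."""

    config: RunConfig
    layouts: list[PlateLayout]
    effect_table: Optional[pd.DataFrame]
    well_table: pd.DataFrame
    normalized_wells: pd.DataFrame
    compound_tests: pd.DataFrame
    hit_table: pd.DataFrame
    waterfall: pd.DataFrame
    correlation: plate_qc.CorrelationReport
    qc_flags: Optional[pd.DataFrame] = None
    cell_records: Optional[pd.DataFrame] = None
    log: dict = field(default_factory=dict)

    def save(self, outdir: str | Path) -> Path:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for layout in self.layouts:
            imaging_io.save_plate_map(layout, outdir / f"plate_map_{layout.plate_id}.csv")
        if self.effect_table is not None:
            self.effect_table.to_csv(outdir / "effect_table.csv", index=False)
        self.well_table.to_csv(outdir / "well_table.csv", index=False)
        self.normalized_wells.to_csv(outdir / "normalized_wells.csv", index=False)
        tests = self.compound_tests.copy()
        if "replicate_values" in tests.columns:
            tests["replicate_values"] = tests["replicate_values"].map(
                lambda v: ";".join(f"{x:.6g}" for x in v)
            )
        tests.to_csv(outdir / "compound_tests.csv", index=False)
        self.hit_table.to_csv(outdir / "hit_table.csv", index=False)
        self.waterfall.to_csv(outdir / "waterfall.csv", index=False)
        self.correlation.entries.to_csv(outdir / "correlation_entries.csv", index=False)
        self.correlation.per_pair.to_csv(outdir / "correlation_per_pair.csv", index=False)
        self.correlation.per_parameter.to_csv(
            outdir / "correlation_per_parameter.csv", index=False
        )
        if self.qc_flags is not None:
            self.qc_flags.to_csv(outdir / "qc_flags.csv", index=False)
        if self.cell_records is not None:
            self.cell_records.to_csv(outdir / "cell_records.csv", index=False)
        with open(outdir / "run_log.json", "w") as fh:
            json.dump(self.log, fh, indent=2, default=str)
        return outdir


# ---------------------------------------------------------------------------
# Image-route helpers
# ---------------------------------------------------------------------------

def analyze_field(field_img: imaging_io.FieldImage, seg_params) -> tuple[pd.DataFrame, int, float]:
    """Segment one field and extract cell records, count and DNA sharpness."""
    from . import segmentation

    labels = segmentation.segment_nuclei(field_img.dna, seg_params)
    rings = segmentation.cytoplasm_rings(labels, seg_params.ring_radius)
    holes = segmentation.detect_nuclear_holes(field_img.dna, labels, seg_params)
    puncta = segmentation.detect_puncta(field_img.lc3, labels, rings, seg_params)
    cells = cytometry.extract_cell_records(field_img, labels, rings, holes, puncta)
    sharpness = cytometry.image_sharpness(field_img.dna)
    return cells, int(labels.max()), sharpness


def _well_table_from_images(
    cfg: RunConfig,
    layouts: Sequence[PlateLayout],
    fields: Sequence[imaging_io.FieldImage],
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Run segmentation + cytometry + QC over fields; aggregate to wells."""
    all_cells = []
    field_rows = []
    for fi in fields:
        cells, n_cells, sharp = analyze_field(fi, cfg.segmentation)
        all_cells.append(cells)
        field_rows.append(
            {
                "plate_id": fi.plate_id,
                "well_id": fi.well_id,
                "field_index": fi.field_index,
                "cell_count": n_cells,
                "sharpness": sharp,
            }
        )
    cell_records = (
        pd.concat(all_cells, ignore_index=True) if all_cells else pd.DataFrame(columns=cytometry.CELL_COLUMNS)
    )
    field_table = pd.DataFrame(field_rows)
    qc_flags = plate_qc.flag_fields(
        field_table,
        sharpness_fraction=cfg.qc.sharpness_fraction,
        exclusions=[tuple(e) for e in cfg.qc.exclusions],
    )
    wells = cytometry.aggregate_wells(cell_records, qc_flags)
    # attach layout metadata
    meta = {}
    for layout in layouts:
        for w, info in layout.wells.items():
            meta[(layout.plate_id, w)] = info
    rows = []
    for rec in wells.to_dict("records"):
        info = meta.get((rec["plate_id"], rec["well_id"]))
        if info is None or info.role == "empty":
            continue
        rec.update(
            role=info.role,
            compound_id=info.compound_id or "",
            dose_uM=info.dose_uM,
            replicate_group=info.replicate_group,
        )
        rows.append(rec)
    well_table = pd.DataFrame(rows)
    return well_table, qc_flags, cell_records


def _render_screen_fields(
    cfg: RunConfig, layouts: Sequence[PlateLayout], effect_map: dict[str, EffectSpec], seed: int
) -> list[imaging_io.FieldImage]:
    rng = np.random.default_rng(seed)
    fields = []
    for layout in layouts:
        for w in imaging_io.all_wells():
            info = layout.wells[w]
            if info.role == "empty":
                continue
            eff = effect_map.get(info.compound_id) if info.role == "compound" else None
            density_mult = 1.0
            if eff is not None:
                density_mult = eff.multiplier_for("cell_density") * (1.0 - eff.toxicity)
            for fidx in range(cfg.synthetic.fields_per_well):
                n_cells = int(rng.poisson(cfg.render.cells_per_field * density_mult))
                fseed = int(rng.integers(0, 2**31 - 1))
                fi, _truth = synthgen.render_field(
                    well_truth=eff,
                    n_cells=n_cells,
                    noise_level=cfg.synthetic.noise_level,
                    seed=fseed,
                    params=cfg.render,
                    plate_id=layout.plate_id,
                    well_id=w,
                    field_index=fidx,
                )
                fields.append(fi)
    return fields


# ---------------------------------------------------------------------------
# Primary screen
# ---------------------------------------------------------------------------

def run_primary_screen(cfg: RunConfig, outdir: Optional[str | Path] = None) -> PrimaryScreenResult:
    """Run the full primary-screen analysis for the configured mode.

    Returns a :class:`PrimaryScreenResult`; also writes all stage outputs to
    ``outdir`` (or ``cfg.outdir``) when ``outdir`` is not None.  Determinism:
    the result is a pure function of (config, seed).
    """
    stage = "setup"
    try:
        seed = cfg.seed
        qc_flags = None
        cell_records = None
        effect_table = None

        if cfg.mode == "synthetic":
            stage = "design"
            effects = _effects_from_config(cfg)
            layouts, effect_table = synthgen.make_screen_design(
                cfg.synthetic.n_compounds,
                cfg.synthetic.n_replicates,
                effects=effects,
                seed=seed,
                dose_uM=cfg.synthetic.dose_uM,
            )
            effect_map = {e.compound_id: e for e in (effects or [])}
            if cfg.synthetic.render_images:
                stage = "render+segment"
                fields = _render_screen_fields(cfg, layouts, effect_map, seed)
                well_table, qc_flags, cell_records = _well_table_from_images(
                    cfg, layouts, fields
                )
            else:
                stage = "simulate"
                well_table = synthgen.simulate_screen_tables(
                    (layouts, effect_table),
                    well_cv=cfg.synthetic.well_cv,
                    seed=seed,
                    baselines=cfg.baselines,
                )
                if cfg.synthetic.gradient_orientation:
                    well_table = synthgen.inject_plate_gradient(
                        well_table,
                        GradientSpec(
                            cfg.synthetic.gradient_orientation,
                            cfg.synthetic.gradient_amplitude,
                        ),
                    )
        elif cfg.mode == "images":
            stage = "ingest-images"
            layouts = [imaging_io.load_plate_map(pm) for pm in cfg.plate_maps]
            fields = _load_fields(cfg, layouts)
            stage = "segment"
            well_table, qc_flags, cell_records = _well_table_from_images(cfg, layouts, fields)
        else:  # tables
            stage = "ingest-tables"
            well_table = pd.read_csv(
                cfg.well_table,
                dtype={"compound_id": str},
                keep_default_na=False,
                float_precision="round_trip",
            )
            for p in PARAMETERS:
                well_table[p] = pd.to_numeric(well_table[p])
            well_table["dose_uM"] = pd.to_numeric(well_table["dose_uM"])
            layouts = []

        stage = "normalize"
        normalized = plate_qc.normalize_screen(well_table, PARAMETERS)

        stage = "correlate"
        correlation = _replicate_correlation(normalized)

        stage = "hits"
        tests = screen_stats.screen_compound_tests(
            normalized, PARAMETERS, reference=cfg.stats.reference
        )
        hit_table = screen_stats.select_hits(
            tests,
            alpha=cfg.stats.alpha,
            hit_parameters=tuple(cfg.stats.hit_parameters),
            viability_rule=cfg.stats.viability_rule,
            viability_sd_mult=cfg.stats.viability_sd_mult,
        )
        waterfall = screen_stats.waterfall_rank(tests, "nuclear_lc3_intensity")

        log = {
            "version": __version__,
            "seed": seed,
            "mode": cfg.mode,
            "config_sha256": hashlib.sha256(
                json.dumps(cfg.to_dict(), sort_keys=True, default=str).encode()
            ).hexdigest(),
            "n_plates": int(well_table["plate_id"].nunique()),
            "n_wells": int(len(well_table)),
            "n_fields_imaged": int(len(qc_flags)) if qc_flags is not None else 0,
            "n_fields_passing": int(qc_flags["pass"].sum()) if qc_flags is not None else 0,
            "n_compounds_tested": int(hit_table["compound_id"].nunique()) if len(hit_table) else 0,
            "n_hits": int(hit_table["hit"].sum()) if len(hit_table) else 0,
        }
        result = PrimaryScreenResult(
            config=cfg,
            layouts=layouts,
            effect_table=effect_table,
            well_table=well_table,
            normalized_wells=normalized,
            compound_tests=tests,
            hit_table=hit_table,
            waterfall=waterfall,
            correlation=correlation,
            qc_flags=qc_flags,
            cell_records=cell_records,
            log=log,
        )
        if outdir is not None:
            result.save(outdir)
        return result
    except ScreenError as exc:
        raise type(exc)(f"[stage {stage}] {exc}") from exc


def _load_fields(cfg: RunConfig, layouts: Sequence[PlateLayout]) -> list[imaging_io.FieldImage]:
    """Load {plate}_{well}_{field}_{channel}.tif pairs for every mapped well."""
    image_dir = Path(cfg.image_dir)
    fields = []
    for layout in layouts:
        for w, info in layout.wells.items():
            if info.role == "empty":
                continue
            fidx = 0
            while True:
                dna_path = image_dir / imaging_io.field_tiff_name(layout.plate_id, w, fidx, "dna")
                lc3_path = image_dir / imaging_io.field_tiff_name(layout.plate_id, w, fidx, "lc3")
                if not dna_path.exists():
                    if fidx == 0:
                        raise DesignError(
                            f"plate {layout.plate_id} well {w}: no image "
                            f"{dna_path.name} in {image_dir}"
                        )
                    break
                fields.append(
                    imaging_io.FieldImage(
                        dna=imaging_io.read_channel_tiff(dna_path),
                        lc3=imaging_io.read_channel_tiff(lc3_path),
                        plate_id=layout.plate_id,
                        well_id=w,
                        field_index=fidx,
                    )
                )
                fidx += 1
    return fields


def _replicate_correlation(normalized: pd.DataFrame) -> plate_qc.CorrelationReport:
    """Correlation report over all unordered pairs of replicate plates."""
    plates = list(dict.fromkeys(normalized["plate_id"]))
    tables = {p: normalized[normalized["plate_id"] == p] for p in plates}
    pairs = [
        (f"{a}|{b}", tables[a], tables[b]) for a, b in itertools.combinations(plates, 2)
    ]
    if not pairs:
        # single plate: self-pair so the report structure is always present
        pairs = [(f"{plates[0]}|{plates[0]}", tables[plates[0]], tables[plates[0]])]
    return plate_qc.correlation_report(pairs, PARAMETERS)


# ---------------------------------------------------------------------------
# Follow-up dose-response screen
# ---------------------------------------------------------------------------

def derive_dose_effects(
    effects: Sequence[EffectSpec], reference_dose_uM: float = 10.0
) -> list[EffectSpec]:
    """Convert flat screening multipliers into linear dose slopes.

    A compound with multiplier m at the reference dose gets slope
    (m - 1) / reference_dose per uM, so its planted effect is monotone in
    dose and reproduces m at the reference dose.
    """
    out = []
    for e in effects:
        slopes = {
            p: (m - 1.0) / reference_dose_uM for p, m in e.effect_multipliers.items()
        }
        out.append(
            EffectSpec(
                compound_id=e.compound_id,
                effect_multipliers=dict(e.effect_multipliers),
                toxicity=e.toxicity,
                dose_slopes=slopes,
            )
        )
    return out


def run_followup(
    cfg: RunConfig,
    hit_effects: Sequence[EffectSpec],
    dose_grid: Optional[Sequence[float]] = None,
    outdir: Optional[str | Path] = None,
) -> pd.DataFrame:
    """Simulate and analyze the dose-response validation screen.

    Each hit compound is exposed to the serial-dilution dose grid (default
    1.25-20 uM) on replicate plates; wells are normalized per plate and each
    compound x parameter is fit by linear regression with BH correction per
    parameter family.  An empty hit list returns an empty table.
    """
    dose_grid = list(dose_grid if dose_grid is not None else cfg.stats.dose_grid)
    if not hit_effects:
        return pd.DataFrame(
            columns=[
                "compound_id", "parameter", "slope", "intercept", "p_value",
                "p_adjusted", "F", "r2", "dof", "slope_sign",
                "constant_response", "bh_significant",
            ]
        )
    dosed = derive_dose_effects(hit_effects)
    layouts = synthgen.make_followup_design(
        dosed, dose_grid=dose_grid, n_replicates=cfg.synthetic.n_replicates, seed=cfg.seed
    )
    wells = synthgen.simulate_screen_tables(
        layouts,
        well_cv=cfg.synthetic.well_cv,
        seed=cfg.seed + 1,
        effects=dosed,
        baselines=cfg.baselines,
    )
    normalized = plate_qc.normalize_screen(wells, PARAMETERS)
    table = screen_stats.dose_response_table(
        normalized, cfg.stats.followup_parameters, q=cfg.stats.q
    )
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        table.to_csv(outdir / "dose_response.csv", index=False)
    return table
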