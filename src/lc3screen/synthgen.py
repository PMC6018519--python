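"""Synthetic screen generation with ground truth.

Two synthetic paths feed the pipeline:

* a *rendered* path (``render_field``) producing two-channel 16-bit rasters —
  a DNA/Hoechst channel with elliptical nuclei carrying low-intensity
  interior holes, and an LC3/TRITC channel with diffuse compartment signal
  plus discrete bright puncta — together with pixel-level ground truth, and
* an *image-free* fast path (``simulate_screen_tables``) producing the same
  well x parameter tables the cytometry stage would, for statistics testing
  at scale.

The generator plants the latent structure the analysis is designed to find:
per-compound multiplicative effects on nuclear LC3 intensity, nuclear holes,
nuclear area and cell density; lognormal well-to-well noise; and optional
multiplicative, mean-centered plate-edge gradients (plate effects).

Every operation is a pure function of its arguments including the seed.
Ground truth records the objects actually *placed*: placement constraints
(interior margins, minimum separations) guarantee that on a noiseless render
every planted nucleus, hole and punctum is recoverable by the segmentation
stage, so truth/recovery equality is a contract rather than a tolerance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import imaging_io
from .errors import ConsistencyError, DesignError, PlacementError
from .imaging_io import FieldImage, PlateLayout, WellInfo

#: The well-level parameters the screen quantifies.
PARAMETERS = [
    "nuclear_lc3_intensity",
    "cytoplasmic_lc3_intensity",
    "holes_count",
    "nuclear_area",
    "cell_density",
]

#: Parameters a compound effect may multiply (cell_density is handled via toxicity
#: as well, but direct multipliers are allowed).
DEFAULT_SCREEN_DOSE_UM = 8.89


# ---------------------------------------------------------------------------
# Effect and gradient specifications
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EffectSpec:
    """Latent per-compound effect being screened for.

    ``effect_multipliers`` maps a parameter name to a positive multiplicative
    effect on that parameter's well value (1.0 everywhere = null compound).
    ``toxicity`` in [0, 1] scales the expected cell count: expected density is
    multiplied by (1 - toxicity).  ``dose_slopes``, when set, makes the
    effect dose-dependent for follow-up simulations: the multiplier at dose d
    is 1 + slope * d (per uM), overriding the flat multiplier.
    """

    compound_id: str
    effect_multipliers: dict[str, float] = field(default_factory=dict)
    toxicity: float = 0.0
    dose_slopes: Optional[dict[str, float]] = None

    def __post_init__(self) -> None:
        for p, m in self.effect_multipliers.items():
            if not m > 0:
                raise DesignError(f"{self.compound_id}: multiplier for {p} must be > 0, got {m}")
        if not 0.0 <= self.toxicity <= 1.0:
            raise DesignError(f"{self.compound_id}: toxicity {self.toxicity} outside [0, 1]")

    @property
    def is_null(self) -> bool:
        flat = all(m == 1.0 for m in self.effect_multipliers.values())
        return flat and self.toxicity == 0.0 and not self.dose_slopes

    def multiplier_for(self, parameter: str, dose_uM: Optional[float] = None) -> float:
        if self.dose_slopes is not None and dose_uM is not None:
            m = 1.0 + self.dose_slopes.get(parameter, 0.0) * dose_uM
            if m <= 0:
                raise DesignError(
                    f"{self.compound_id}: dose slope drives {parameter} multiplier "
                    f"non-positive at {dose_uM} uM"
                )
            return m
        return self.effect_multipliers.get(parameter, 1.0)


def null_effect(compound_id: str) -> EffectSpec:
    return EffectSpec(compound_id=compound_id)


@dataclass(frozen=True)
class GradientSpec:
    """Multiplicative spatial plate effect, mean-centered at 1 over the 8x12 grid.

    ``orientation`` is one of ``left-right``, ``top-bottom``, ``radial``;
    ``amplitude`` >= 0 is the peak deviation from 1 (amplitude 0 is the
    identity).  Mean-centering isolates plate-effect *detection* from
    plate-mean normalization, which the gradient leaves untouched.
    """

    orientation: str
    amplitude: float

    ORIENTATIONS = ("left-right", "top-bottom", "radial")

    def __post_init__(self) -> None:
        if self.orientation not in self.ORIENTATIONS:
            raise DesignError(
                f"unknown gradient orientation {self.orientation!r}; "
                f"expected one of {self.ORIENTATIONS}"
            )
        if self.amplitude < 0:
            raise DesignError(f"gradient amplitude must be >= 0, got {self.amplitude}")
        if self.amplitude >= 1.0:
            raise DesignError("gradient amplitude >= 1 would produce non-positive factors")

    def factors(self) -> np.ndarray:
        """8x12 array of per-well factors; exact identity at amplitude 0."""
        if self.amplitude == 0.0:
            return np.ones((imaging_io.N_ROWS, imaging_io.N_COLS))
        if self.orientation == "left-right":
            g = np.tile(np.linspace(-1.0, 1.0, imaging_io.N_COLS), (imaging_io.N_ROWS, 1))
        elif self.orientation == "top-bottom":
            g = np.tile(
                np.linspace(-1.0, 1.0, imaging_io.N_ROWS)[:, None], (1, imaging_io.N_COLS)
            )
        else:  # radial: edge wells high (evaporation), center low
            rr, cc = np.mgrid[0 : imaging_io.N_ROWS, 0 : imaging_io.N_COLS]
            d = np.hypot(
                (rr - (imaging_io.N_ROWS - 1) / 2.0),
                (cc - (imaging_io.N_COLS - 1) / 2.0),
            )
            g = d / d.max()
        g = g - g.mean()
        g = g / np.abs(g).max()
        return 1.0 + self.amplitude * g

    def factor_for_well(self, well_id: str) -> float:
        r, c = imaging_io.parse_well(well_id)
        return float(self.factors()[r, c])


# ---------------------------------------------------------------------------
# Screen design
# ---------------------------------------------------------------------------

def make_screen_design(
    n_compounds: int,
    n_replicates: int,
    effects: Optional[Sequence[EffectSpec]] = None,
    seed: int = 0,
    dose_uM: float = DEFAULT_SCREEN_DOSE_UM,
    plate_prefix: str = "P1",
) -> tuple[list[PlateLayout], pd.DataFrame]:
    """Lay out one compound set over ``n_replicates`` replicate plates.

    Each 96-well plate has its 36 border wells assigned to vehicle and up to
    60 interior wells to compounds (default screening dose 8.89 uM); all
    replicate plates share identical compound placement.  Returns the plate
    layouts and an effect table recording the planted truth (one row per
    compound with its well, multipliers and toxicity).
    """
    if not 2 <= n_replicates <= 4:
        raise DesignError(f"n_replicates must be in 2..4, got {n_replicates}")
    interior = imaging_io.interior_wells()
    if n_compounds > len(interior):
        raise DesignError(
            f"{n_compounds} compounds exceed the {len(interior)} interior wells of one "
            "plate; multi-plate splitting is not enabled"
        )
    if n_compounds < 0:
        raise DesignError("n_compounds must be >= 0")
    if effects is None:
        effects = [null_effect(f"C{i + 1:03d}") for i in range(n_compounds)]
    if len(effects) != n_compounds:
        raise DesignError(f"got {len(effects)} effect specs for {n_compounds} compounds")
    ids = [e.compound_id for e in effects]
    if len(set(ids)) != len(ids):
        raise DesignError("duplicate compound_id in effects")

    rng = np.random.default_rng(seed)
    wells_for_compounds = list(rng.permutation(interior)[:n_compounds])

    layouts = []
    for r in range(1, n_replicates + 1):
        wells: dict[str, WellInfo] = {}
        group = f"R{r}"
        for w in imaging_io.border_wells():
            wells[w] = WellInfo(role="vehicle", dose_uM=0.0, replicate_group=group)
        for w, eff in zip(wells_for_compounds, effects):
            wells[w] = WellInfo(
                role="compound",
                compound_id=eff.compound_id,
                dose_uM=dose_uM,
                replicate_group=group,
            )
        layouts.append(PlateLayout(plate_id=f"{plate_prefix}-{group}", wells=wells))

    rows = []
    for w, eff in zip(wells_for_compounds, effects):
        row = {
            "compound_id": eff.compound_id,
            "well": w,
            "toxicity": eff.toxicity,
            "is_null": eff.is_null,
        }
        for p in PARAMETERS:
            row[f"mult_{p}"] = eff.multiplier_for(p)
        rows.append(row)
    effect_table = pd.DataFrame(
        rows,
        columns=["compound_id", "well", "toxicity", "is_null"]
        + [f"mult_{p}" for p in PARAMETERS],
    )
    return layouts, effect_table


def make_followup_design(
    effects: Sequence[EffectSpec],
    dose_grid: Sequence[float] = (1.25, 2.5, 5.0, 10.0, 20.0),
    n_replicates: int = 2,
    seed: int = 0,
    plate_prefix: str = "FU",
) -> list[PlateLayout]:
    """Dose-response layouts: each compound occupies one interior well per dose.

    Compounds are split over as many plates as the 60 interior wells require;
    border wells stay vehicle.  Replicate plates share placement.
    """
    if not 2 <= n_replicates <= 4:
        raise DesignError(f"n_replicates must be in 2..4, got {n_replicates}")
    if len(dose_grid) < 3:
        raise DesignError("dose grid needs >= 3 levels for a defined regression")
    interior = imaging_io.interior_wells()
    per_plate = len(interior) // len(dose_grid)
    if per_plate == 0:
        raise DesignError("dose grid longer than the interior well count")
    rng = np.random.default_rng(seed)
    layouts: list[PlateLayout] = []
    chunks = [list(effects)[i : i + per_plate] for i in range(0, len(effects), per_plate)]
    for pi, chunk in enumerate(chunks, start=1):
        slots = [(e, d) for e in chunk for d in dose_grid]
        wells_used = list(rng.permutation(interior)[: len(slots)])
        for r in range(1, n_replicates + 1):
            group = f"R{r}"
            wells: dict[str, WellInfo] = {}
            for w in imaging_io.border_wells():
                wells[w] = WellInfo(role="vehicle", dose_uM=0.0, replicate_group=group)
            for w, (eff, dose) in zip(wells_used, slots):
                wells[w] = WellInfo(
                    role="compound",
                    compound_id=eff.compound_id,
                    dose_uM=dose,
                    replicate_group=group,
                )
            layouts.append(PlateLayout(plate_id=f"{plate_prefix}{pi}-{group}", wells=wells))
    return layouts


# ---------------------------------------------------------------------------
# Image-free well-table simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WellBaselines:
    """Baseline (vehicle) expectations of the screened parameters.

    Values are in raw feature units (counts, px, cells/field) and only their
    ratios matter after plate-mean normalization; they are chosen to match a
    default noiseless render.
    """

    nuclear_lc3_intensity: float = 2000.0
    cytoplasmic_lc3_intensity: float = 1200.0
    holes_count: float = 0.8
    nuclear_area: float = 360.0
    cell_density: float = 15.0

    def as_dict(self) -> dict[str, float]:
        return {p: getattr(self, p) for p in PARAMETERS}


def _lognormal_noise(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Multiplicative lognormal noise with mean exactly 1 and the given CV."""
    if cv == 0.0:
        return np.ones(size)
    sigma2 = math.log(1.0 + cv * cv)
    return rng.lognormal(mean=-sigma2 / 2.0, sigma=math.sqrt(sigma2), size=size)


def simulate_screen_tables(
    design: tuple[Sequence[PlateLayout], pd.DataFrame] | Sequence[PlateLayout],
    well_cv: float,
    seed: int = 0,
    effects: Optional[Sequence[EffectSpec]] = None,
    baselines: Optional[WellBaselines] = None,
) -> pd.DataFrame:
    """Simulate the well x parameter table the cytometry stage would produce.

    Vehicle wells draw from the baseline; compound wells from baseline x
    effect multiplier; both carry multiplicative lognormal well noise with
    coefficient of variation ``well_cv`` (mean 1, so ``well_cv = 0`` is exact
    arithmetic).  Cell density is additionally scaled by (1 - toxicity).
    ``design`` is the (layouts, effect_table) pair from ``make_screen_design``
    or a bare list of layouts with ``effects`` passed separately.
    """
    if well_cv < 0:
        raise DesignError(f"well_cv must be >= 0, got {well_cv}")
    if isinstance(design, tuple):
        layouts = list(design[0])
    else:
        layouts = list(design)
    effect_map: dict[str, EffectSpec] = {}
    for e in effects or []:
        effect_map[e.compound_id] = e
    if isinstance(design, tuple) and effects is None:
        # reconstruct effect specs from the effect table
        for rec in design[1].itertuples(index=False):
            mult = {p: getattr(rec, f"mult_{p}") for p in PARAMETERS}
            effect_map[rec.compound_id] = EffectSpec(
                compound_id=rec.compound_id,
                effect_multipliers=mult,
                toxicity=rec.toxicity,
            )
    base = (baselines or WellBaselines()).as_dict()
    rng = np.random.default_rng(seed)

    records = []
    for layout in layouts:
        well_ids = imaging_io.all_wells()
        noise = _lognormal_noise(rng, well_cv, size=(len(well_ids), len(PARAMETERS)))
        for i, w in enumerate(well_ids):
            info = layout.wells[w]
            if info.role == "empty":
                continue
            eff = None
            if info.role == "compound":
                eff = effect_map.get(info.compound_id)
                if eff is None:
                    raise ConsistencyError(
                        f"plate {layout.plate_id} well {w}: no effect spec for "
                        f"compound {info.compound_id!r}"
                    )
            rec = {
                "plate_id": layout.plate_id,
                "well_id": w,
                "role": info.role,
                "compound_id": info.compound_id or "",
                "dose_uM": info.dose_uM,
                "replicate_group": info.replicate_group,
            }
            for j, p in enumerate(PARAMETERS):
                mult = 1.0 if eff is None else eff.multiplier_for(p, info.dose_uM or None)
                value = base[p] * mult * noise[i, j]
                if p == "cell_density" and eff is not None:
                    value *= 1.0 - eff.toxicity
                rec[p] = value
            records.append(rec)
    return pd.DataFrame.from_records(records)


def inject_plate_gradient(
    well_table: pd.DataFrame,
    gradient: GradientSpec,
    parameters: Sequence[str] = tuple(PARAMETERS),
) -> pd.DataFrame:
    """Multiply each well's parameter values by its spatial gradient factor.

    The table must cover the full 8x12 grid for every plate present (the
    gradient is a whole-plate physical effect).  Amplitude 0 returns an
    identical copy.
    """
    fac = gradient.factors()
    out = well_table.copy()
    for plate_id, idx in out.groupby("plate_id").groups.items():
        wells = set(out.loc[idx, "well_id"])
        missing = set(imaging_io.all_wells()) - wells
        if missing:
            raise DesignError(
                f"plate {plate_id}: gradient requires the full 8x12 grid; "
                f"missing {len(missing)} wells (e.g. {sorted(missing)[:3]})"
            )
    rc = np.array([imaging_io.parse_well(w) for w in out["well_id"]])
    factors = fac[rc[:, 0], rc[:, 1]]
    for p in parameters:
        out[p] = out[p].to_numpy() * factors
    return out


# ---------------------------------------------------------------------------
# Field rendering
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RenderParams:
    """Raster-rendering parameters for the synthetic microscope.

    Geometry is in pixels at roughly the screen's 40x scale (nuclei ~12 px
    semi-axis).  Intensities are 16-bit counts.  ``noise_level`` scales a
    signal-dependent Gaussian model: sd = noise_level * sqrt(signal + 1),
    a standard shot-plus-read fluorescence camera approximation.
    """

    image_size: int = 256
    cells_per_field: int = 15
    background_dna: float = 400.0
    nucleus_dna: float = 12000.0
    nucleus_dna_cv: float = 0.05
    nucleus_radius: float = 12.0
    nucleus_radius_jitter: float = 0.12
    axis_ratio_min: float = 0.6
    axis_ratio_max: float = 1.0
    cell_margin: float = 14.0
    hole_rate: float = 0.8
    hole_radius: float = 3.0
    hole_dna_fraction: float = 0.1
    hole_margin: float = 4.0
    background_lc3: float = 800.0
    nuclear_lc3: float = 1200.0
    cytoplasmic_lc3: float = 400.0
    cyto_annulus: float = 10.0
    diffuse_sigma: float = 6.0
    puncta_amplitude: float = 20000.0
    puncta_radius: float = 2.0
    nuclear_puncta_rate: float = 1.0
    cytoplasmic_puncta_min: int = 2
    cytoplasmic_puncta_rate: float = 1.0
    max_puncta_per_cell: int = 6
    puncta_separation: float = 9.0
    puncta_margin: float = 4.0
    max_place_tries: int = 400

    def noise_level_for_dna_snr(self, snr: float) -> float:
        """Noise level giving the requested nuclear-vs-background DNA SNR."""
        contrast = self.nucleus_dna - self.background_dna
        return contrast / (snr * math.sqrt(self.nucleus_dna))


@dataclass
class NucleusTruth:
    label: int
    center: tuple[float, float]  # (row, col)
    semi_axes: tuple[float, float]  # (major, minor)
    angle: float
    dna_value: float
    hole_centers: list[tuple[float, float]] = field(default_factory=list)


@dataclass
class PunctumTruth:
    center: tuple[int, int]  # (row, col) pixel
    compartment: str  # "nuclear" | "cytoplasmic"
    amplitude: float
    owner: int  # nucleus label


@dataclass
class GroundTruth:
    """Pixel-level truth for one rendered field."""

    labels: np.ndarray  # uint16 label raster, 0 = background
    nuclei: list[NucleusTruth]
    puncta: list[PunctumTruth]
    field_effect: EffectSpec

    @property
    def n_nuclei(self) -> int:
        return len(self.nuclei)

    @property
    def holes_per_nucleus(self) -> dict[int, int]:
        return {n.label: len(n.hole_centers) for n in self.nuclei}

    def puncta_counts(self) -> dict[str, int]:
        out = {"nuclear": 0, "cytoplasmic": 0}
        for p in self.puncta:
            out[p.compartment] += 1
        return out


def _ellipse_mask(shape, center, semi_axes, angle) -> np.ndarray:
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    dy = rr - center[0]
    dx = cc - center[1]
    ca, sa = math.cos(angle), math.sin(angle)
    u = dx * ca + dy * sa
    v = -dx * sa + dy * ca
    a, b = semi_axes
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def _disk_mask(shape, center, radius) -> np.ndarray:
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2


def render_field(
    well_truth: EffectSpec | None = None,
    n_cells: Optional[int] = None,
    image_size: Optional[int] = None,
    noise_level: float = 0.0,
    seed: int = 0,
    params: Optional[RenderParams] = None,
    plate_id: str = "SYN",
    well_id: str = "A1",
    field_index: int = 0,
) -> tuple[FieldImage, GroundTruth]:
    """Render one two-channel field with pixel-level ground truth.

    The DNA channel contains ``n_cells`` non-overlapping elliptical nuclei
    (axis ratio 0.6-1.0) with planted interior low-intensity holes; the LC3
    channel contains smooth diffuse nuclear + perinuclear signal scaled by
    the effect multipliers plus discrete bright puncta.  ``noise_level`` adds
    signal-dependent Gaussian noise; 0 renders a noiseless field.  Raises
    :class:`PlacementError` if the nuclei cannot be placed without overlap
    within the bounded retry budget.
    """
    p = params or RenderParams()
    if image_size is not None:
        p = replace(p, image_size=image_size)
    if p.image_size < 128:
        raise DesignError(f"image_size must be >= 128 px, got {p.image_size}")
    eff = well_truth or null_effect("vehicle")
    if n_cells is None:
        n_cells = p.cells_per_field
    if n_cells < 0:
        raise DesignError("n_cells must be >= 0")

    rng = np.random.default_rng(seed)
    shape = (p.image_size, p.image_size)

    area_mult = eff.multiplier_for("nuclear_area")
    axis_scale = math.sqrt(area_mult)
    hole_mult = eff.multiplier_for("holes_count")
    nlc3_mult = eff.multiplier_for("nuclear_lc3_intensity")
    clc3_mult = eff.multiplier_for("cytoplasmic_lc3_intensity")

    # --- place nuclei (rejection sampling, bounded retries) ---
    nuclei: list[NucleusTruth] = []
    placed: list[tuple[float, float, float]] = []  # (row, col, semi_major)
    tries = 0
    budget = p.max_place_tries * max(n_cells, 1)
    while len(nuclei) < n_cells:
        if tries > budget:
            raise PlacementError(
                f"could not place {n_cells} non-overlapping nuclei of semi-axis "
                f"~{p.nucleus_radius * axis_scale:.1f} px with margin {p.cell_margin} px in a "
                f"{p.image_size}x{p.image_size} px field after {budget} tries"
            )
        tries += 1
        a = p.nucleus_radius * axis_scale * (
            1.0 + p.nucleus_radius_jitter * (2.0 * rng.random() - 1.0)
        )
        ratio = rng.uniform(p.axis_ratio_min, p.axis_ratio_max)
        b = a * ratio
        angle = rng.uniform(0.0, math.pi)
        edge = a + p.cyto_annulus / 2.0 + 2.0
        cy = rng.uniform(edge, p.image_size - edge)
        cx = rng.uniform(edge, p.image_size - edge)
        ok = all(
            math.hypot(cy - oy, cx - ox) >= a + oa + p.cell_margin
            for oy, ox, oa in placed
        )
        if not ok:
            continue
        label = len(nuclei) + 1
        dna_value = p.nucleus_dna * float(
            _lognormal_noise(rng, p.nucleus_dna_cv, size=1)[0]
        )
        nuclei.append(
            NucleusTruth(
                label=label,
                center=(cy, cx),
                semi_axes=(a, b),
                angle=angle,
                dna_value=dna_value,
            )
        )
        placed.append((cy, cx, a))

    labels = np.zeros(shape, dtype=np.uint16)
    for n in nuclei:
        labels[_ellipse_mask(shape, n.center, n.semi_axes, n.angle)] = n.label

    # --- plant holes (interior, separated; truth = placed) ---
    for n in nuclei:
        target = rng.poisson(p.hole_rate * hole_mult)
        a, b = n.semi_axes
        inner = 1.0 - (p.hole_radius + p.hole_margin) / b
        if inner <= 0.15:
            continue
        for _ in range(target):
            for _try in range(p.max_place_tries):
                rho = math.sqrt(rng.random()) * inner
                phi = rng.uniform(0.0, 2.0 * math.pi)
                u = rho * a * math.cos(phi)
                v = rho * b * math.sin(phi)
                # guard against the major-axis direction exceeding the minor margin
                ca, sa = math.cos(n.angle), math.sin(n.angle)
                hy = n.center[0] + u * sa + v * ca
                hx = n.center[1] + u * ca - v * sa
                # must be interior with margin (check in ellipse coords)
                du = (hx - n.center[1]) * ca + (hy - n.center[0]) * sa
                dv = -(hx - n.center[1]) * sa + (hy - n.center[0]) * ca
                grown = (du / (a - p.hole_radius - p.hole_margin)) ** 2 + (
                    dv / (b - p.hole_radius - p.hole_margin)
                ) ** 2
                if grown > 1.0:
                    continue
                if all(
                    math.hypot(hy - oy, hx - ox) >= 2 * p.hole_radius + 4.0
                    for oy, ox in n.hole_centers
                ):
                    n.hole_centers.append((hy, hx))
                    break

    # --- plant puncta ---
    puncta: list[PunctumTruth] = []
    all_centers: list[tuple[float, float]] = []

    def _far_enough(y, x) -> bool:
        return all(
            math.hypot(y - oy, x - ox) >= p.puncta_separation for oy, ox in all_centers
        )

    for n in nuclei:
        a, b = n.semi_axes
        n_nuc = int(rng.poisson(p.nuclear_puncta_rate))
        n_cyt = p.cytoplasmic_puncta_min + int(rng.poisson(p.cytoplasmic_puncta_rate))
        total = n_nuc + n_cyt
        if total > p.max_puncta_per_cell:
            n_nuc = max(0, p.max_puncta_per_cell - n_cyt)
            n_cyt = min(n_cyt, p.max_puncta_per_cell)
        ca, sa = math.cos(n.angle), math.sin(n.angle)
        inner = 1.0 - (p.puncta_radius + p.puncta_margin) / b
        for _ in range(n_nuc):
            if inner <= 0.1:
                break
            for _try in range(p.max_place_tries):
                rho = math.sqrt(rng.random()) * inner
                phi = rng.uniform(0.0, 2.0 * math.pi)
                u = rho * a * math.cos(phi)
                v = rho * b * math.sin(phi)
                du_lim = (u / (a - p.puncta_radius - p.puncta_margin)) ** 2 + (
                    v / (b - p.puncta_radius - p.puncta_margin)
                ) ** 2
                if du_lim > 1.0:
                    continue
                py = n.center[0] + u * sa + v * ca
                px = n.center[1] + u * ca - v * sa
                if _far_enough(py, px):
                    ctr = (int(round(py)), int(round(px)))
                    puncta.append(
                        PunctumTruth(
                            center=ctr,
                            compartment="nuclear",
                            amplitude=p.puncta_amplitude,
                            owner=n.label,
                        )
                    )
                    all_centers.append((py, px))
                    break
        for _ in range(n_cyt):
            for _try in range(p.max_place_tries):
                phi = rng.uniform(0.0, 2.0 * math.pi)
                # boundary point + outward offset in [margin, annulus - 2]
                bu = a * math.cos(phi)
                bv = b * math.sin(phi)
                # outward normal of the ellipse at parameter phi
                ny_, nx_ = b * math.cos(phi), a * math.sin(phi)
                nn = math.hypot(ny_, nx_)
                d = rng.uniform(p.puncta_margin, p.cyto_annulus - 2.0)
                ou = bu + d * ny_ / nn
                ov = bv + d * nx_ / nn
                py = n.center[0] + ou * sa + ov * ca
                px = n.center[1] + ou * ca - ov * sa
                ctr = (int(round(py)), int(round(px)))
                if not (0 <= ctr[0] < p.image_size and 0 <= ctr[1] < p.image_size):
                    continue
                if labels[ctr] != 0:
                    continue
                # every pixel of the spot must be nearer to its own nucleus
                # than to any other (ring ownership), with slack for the
                # segmentation's ~1 px boundary tolerance
                clearance = d + 2.0 * p.puncta_radius + 3.0
                if any(
                    math.hypot(py - oy, px - ox) - oa < clearance
                    for oy, ox, oa in placed
                    if (oy, ox) != (n.center[0], n.center[1])
                ):
                    continue
                if _far_enough(py, px):
                    puncta.append(
                        PunctumTruth(
                            center=ctr,
                            compartment="cytoplasmic",
                            amplitude=p.puncta_amplitude,
                            owner=n.label,
                        )
                    )
                    all_centers.append((py, px))
                    break

    # --- render DNA channel ---
    dna = np.full(shape, p.background_dna, dtype=float)
    for n in nuclei:
        mask = labels == n.label
        dna[mask] = n.dna_value
        for hc in n.hole_centers:
            hole = _disk_mask(shape, hc, p.hole_radius) & mask
            dna[hole] = p.hole_dna_fraction * n.dna_value

    # --- render LC3 channel (smooth diffuse + hard puncta) ---
    from scipy.ndimage import gaussian_filter, binary_dilation

    lc3 = np.full(shape, p.background_lc3, dtype=float)
    nuc_any = labels > 0
    if nuc_any.any():
        ann_r = int(math.ceil(p.cyto_annulus))
        yy, xx = np.mgrid[-ann_r : ann_r + 1, -ann_r : ann_r + 1]
        disk = (yy**2 + xx**2) <= p.cyto_annulus**2
        cyto_zone = binary_dilation(nuc_any, structure=disk) & ~nuc_any
        lc3[cyto_zone] += p.cytoplasmic_lc3 * clc3_mult
        lc3[nuc_any] += p.nuclear_lc3 * nlc3_mult
    lc3 = gaussian_filter(lc3, sigma=p.diffuse_sigma, mode="nearest")
    for pt in puncta:
        spot = _disk_mask(shape, pt.center, p.puncta_radius)
        lc3[spot] += pt.amplitude

    # --- camera noise and quantization ---
    def _finish(img: np.ndarray) -> np.ndarray:
        if noise_level > 0:
            img = img + rng.normal(0.0, noise_level * np.sqrt(img + 1.0), size=img.shape)
        return np.clip(np.rint(img), 0, 65535).astype(np.uint16)

    fi = FieldImage(
        dna=_finish(dna),
        lc3=_finish(lc3),
        plate_id=plate_id,
        well_id=well_id,
        field_index=field_index,
    )
    truth = GroundTruth(labels=labels, nuclei=nuclei, puncta=puncta, field_effect=eff)
    return fi, truth


# ---------------------------------------------------------------------------
# Segmentation evaluation against truth
# ---------------------------------------------------------------------------

def evaluate_segmentation(
    predicted: np.ndarray,
    truth: GroundTruth | np.ndarray,
    iou_threshold: float = 0.5,
    empty_prediction_precision: float = 1.0,
) -> tuple[float, float, list[tuple[int, int, float]]]:
    """Match predicted objects to true objects one-to-one by descending IoU.

    Objects are matched greedily (highest IoU first, ties to lower labels) and
    count as correct iff IoU >= ``iou_threshold``.  Precision = matched /
    n_predicted, recall = matched / n_truth.  By the zero-prediction
    convention an empty prediction has precision ``empty_prediction_precision``
    (default 1.0: no predictions, none wrong); empty truth likewise yields
    recall 1.0.
    """
    if not 0.0 < iou_threshold <= 1.0:
        raise DesignError(f"iou_threshold must be in (0, 1], got {iou_threshold}")
    truth_labels = truth.labels if isinstance(truth, GroundTruth) else np.asarray(truth)
    predicted = np.asarray(predicted)
    if predicted.shape != truth_labels.shape:
        raise ConsistencyError(
            f"shape mismatch: predicted {predicted.shape} vs truth {truth_labels.shape}"
        )
    pred_ids = np.unique(predicted)
    pred_ids = pred_ids[pred_ids > 0]
    true_ids = np.unique(truth_labels)
    true_ids = true_ids[true_ids > 0]

    # contingency of overlapping (pred, true) label pairs
    both = (predicted > 0) & (truth_labels > 0)
    pairs: dict[tuple[int, int], int] = {}
    if both.any():
        pv = predicted[both].astype(np.int64)
        tv = truth_labels[both].astype(np.int64)
        key = pv * (int(truth_labels.max()) + 1) + tv
        uniq, counts = np.unique(key, return_counts=True)
        for k, cnt in zip(uniq, counts):
            pairs[(int(k // (int(truth_labels.max()) + 1)), int(k % (int(truth_labels.max()) + 1)))] = int(cnt)

    pred_area = {int(l): int((predicted == l).sum()) for l in pred_ids}
    true_area = {int(l): int((truth_labels == l).sum()) for l in true_ids}

    cand = []
    for (pl, tl), inter in pairs.items():
        union = pred_area[pl] + true_area[tl] - inter
        iou = inter / union
        if iou >= iou_threshold:
            cand.append((iou, pl, tl))
    cand.sort(key=lambda t: (-t[0], t[1], t[2]))

    matched_pred: set[int] = set()
    matched_true: set[int] = set()
    matches: list[tuple[int, int, float]] = []
    for iou, pl, tl in cand:
        if pl in matched_pred or tl in matched_true:
            continue
        matched_pred.add(pl)
        matched_true.add(tl)
        matches.append((pl, tl, iou))

    n_match = len(matches)
    precision = (
        empty_prediction_precision if len(pred_ids) == 0 else n_match / len(pred_ids)
    )
    recall = 1.0 if len(true_ids) == 0 else n_match / len(true_ids)
    return precision, recall, matches


# ---------------------------------------------------------------------------
# Vectorized normalized-replicate simulation (calibration / power studies)
# ---------------------------------------------------------------------------

@dataclass
class ReplicateSimulation:
    """Normalized replicate values of one tracked compound over many screens."""

    replicate_values: np.ndarray  # (n_screens, n_replicates)
    vehicle_sd: np.ndarray  # (n_screens,) pooled per-well SD of vehicle wells
    vehicle_df: int


def simulate_normalized_replicates(
    n_screens: int,
    multiplier: float = 1.0,
    well_cv: float = 0.05,
    n_replicates: int = 3,
    n_compounds: int = 60,
    seed: int = 0,
) -> ReplicateSimulation:
    """Fast vectorized model of the normalized readout of one compound.

    Each screen is ``n_replicates`` plates of 36 vehicle wells and
    ``n_compounds`` interior wells, one of which carries ``multiplier`` on the
    tracked parameter (the rest are null).  Every well draws baseline x
    multiplier x lognormal(CV = well_cv) noise; plates are normalized to mean
    1 and the tracked compound's normalized replicate values are returned
    together with the pooled vehicle-well SD (plate-null reference for the
    vehicle-referenced hit test).  This reproduces exactly what
    ``simulate_screen_tables`` + ``normalize_plate`` compute, in bulk.
    """
    if n_compounds < 1 or n_compounds > 60:
        raise DesignError("n_compounds must be in 1..60")
    rng = np.random.default_rng(seed)
    n_wells = 36 + n_compounds
    mult = np.ones(n_wells)
    mult[36] = multiplier  # first interior well carries the effect
    noise = _lognormal_noise(rng, well_cv, size=(n_screens, n_replicates, n_wells))
    raw = mult[None, None, :] * noise
    plate_mean = raw.mean(axis=2, keepdims=True)
    norm = raw / plate_mean
    target = norm[:, :, 36]
    veh = norm[:, :, :36]
    veh_centered = veh - veh.mean(axis=2, keepdims=True)
    ss = (veh_centered**2).sum(axis=(1, 2))
    df = n_replicates * (36 - 1)
    return ReplicateSimulation(
        replicate_values=target,
        vehicle_sd=np.sqrt(ss / df),
        vehicle_df=df,
    )
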