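"""Run configuration with documented defaults and YAML round-tripping.

A :class:`RunConfig` bundles every stage parameter (generator, segmentation,
QC, normalization, statistics) plus the run mode and seed, and serializes
losslessly to/from YAML so an analysis is reproducible from its config file
and seed alone.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from .errors import DesignError
from .segmentation import SegmentationParams
from .synthgen import DEFAULT_SCREEN_DOSE_UM, RenderParams, WellBaselines

RUN_MODES = ("synthetic", "images", "tables")


@dataclass
class QCConfig:
    sharpness_fraction: float = 0.25
    exclusions: list = field(default_factory=list)  # [plate_id, well_id, field_index]


@dataclass
class StatsConfig:
    alpha: float = 0.001
    q: float = 0.05
    hit_parameters: list = field(
        default_factory=lambda: [
            "nuclear_lc3_intensity",
            "cytoplasmic_lc3_intensity",
            "holes_count",
            "nuclear_area",
        ]
    )
    reference: str = "vehicle"  # "vehicle" | "one_sample"
    viability_rule: str = "significant"  # "significant" | "sd_band"
    viability_sd_mult: float = 2.0
    dose_grid: list = field(default_factory=lambda: [1.25, 2.5, 5.0, 10.0, 20.0])
    followup_parameters: list = field(
        default_factory=lambda: ["nuclear_lc3_intensity", "holes_count", "nuclear_area"]
    )


@dataclass
class SyntheticConfig:
    n_compounds: int = 60
    n_replicates: int = 2
    well_cv: float = 0.05
    dose_uM: float = DEFAULT_SCREEN_DOSE_UM
    render_images: bool = False  # True: render+segment fields; False: table fast path
    fields_per_well: int = 1
    noise_level: float = 0.0
    gradient_orientation: Optional[str] = None
    gradient_amplitude: float = 0.0
    # planted effects: list of {compound_id, effect_multipliers, toxicity}
    effects: list = field(default_factory=list)


@dataclass
class RunConfig:
    mode: str = "synthetic"
    seed: int = 0
    outdir: str = "lc3screen_out"
    plate_maps: list = field(default_factory=list)  # images/tables mode inputs
    image_dir: str = ""
    well_table: str = ""  # tables mode input CSV
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    render: RenderParams = field(default_factory=RenderParams)
    baselines: WellBaselines = field(default_factory=WellBaselines)
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    qc: QCConfig = field(default_factory=QCConfig)
    stats: StatsConfig = field(default_factory=StatsConfig)

    def __post_init__(self) -> None:
        if self.mode not in RUN_MODES:
            raise DesignError(f"mode must be one of {RUN_MODES}, got {self.mode!r}")

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        for key, typ in (
            ("synthetic", SyntheticConfig),
            ("render", RenderParams),
            ("baselines", WellBaselines),
            ("segmentation", SegmentationParams),
            ("qc", QCConfig),
            ("stats", StatsConfig),
        ):
            if key in d and isinstance(d[key], dict):
                d[key] = typ(**d[key])
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))
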