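"""Field-level quality control, plate-mean normalization, and the
rotated-replicate correlation control for plate effects.

QC removes fields with low viability (2 cells or fewer, indicating
toxicity), low image sharpness relative to the plate (default: below a
quarter of the plate's median sharpness) or a manual exclusion.  Each
plate's well table is normalized so the mean of every parameter over the
included wells equals 1, making plates comparable.  Replicate reliability is
assessed by the squared Pearson correlation of well values between replicate
plates — once aligned (w vs w) and once after rotating one plate 180 degrees
(w vs its rotated partner, B3 vs G10).  Treatment effects produce a high
aligned and a low rotated r-squared; spatial plate effects inflate both, so
a small aligned-minus-rotated gap flags plate effects rather than real
compound activity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DesignError, StatsError
from .imaging_io import rotate_well_180

logger = logging.getLogger(__name__)

QC_REASONS = ("low_viability", "low_sharpness", "manual_exclusion")

#: fields with this many cells or fewer fail viability QC
LOW_VIABILITY_MAX_CELLS = 2


# ---------------------------------------------------------------------------
# Field QC
# ---------------------------------------------------------------------------

def flag_fields(
    field_table: pd.DataFrame,
    sharpness_fraction: float = 0.25,
    exclusions: Optional[Iterable[tuple[str, str, int]]] = None,
) -> pd.DataFrame:
    """Apply the field QC rules; returns the table with ``pass``/``reasons``.

    ``field_table`` needs columns plate_id, well_id, field_index, cell_count,
    sharpness.  Rules: ``low_viability`` iff cell_count <= 2;
    ``low_sharpness`` iff sharpness < sharpness_fraction x the median
    sharpness of the same plate's fields; ``manual_exclusion`` for any
    (plate, well, field) in ``exclusions``.  ``pass`` is true iff no reason
    applies.
    """
    req = {"plate_id", "well_id", "field_index", "cell_count", "sharpness"}
    missing = req - set(field_table.columns)
    if missing:
        raise DesignError(f"field table missing columns {sorted(missing)}")
    excl = set(map(tuple, exclusions or []))
    out = field_table.copy()
    med = out.groupby("plate_id")["sharpness"].transform("median")
    low_v = out["cell_count"] <= LOW_VIABILITY_MAX_CELLS
    low_s = out["sharpness"] < sharpness_fraction * med
    manual = [
        (p, w, f) in excl
        for p, w, f in zip(out["plate_id"], out["well_id"], out["field_index"])
    ]
    manual = np.asarray(manual, dtype=bool)
    reasons = []
    for v, s, m in zip(low_v, low_s, manual):
        r = []
        if v:
            r.append("low_viability")
        if s:
            r.append("low_sharpness")
        if m:
            r.append("manual_exclusion")
        reasons.append(";".join(r))
    out["reasons"] = reasons
    out["pass"] = ~(low_v | low_s | manual)
    return out


# ---------------------------------------------------------------------------
# Plate-mean normalization
# ---------------------------------------------------------------------------

def normalize_plate(
    well_table: pd.DataFrame,
    parameters: Sequence[str],
    include: Optional[pd.Series | np.ndarray] = None,
) -> pd.DataFrame:
    """Divide each parameter column by its mean over the included wells.

    After normalization the mean of every parameter over included wells is 1
    (to floating tolerance); excluded wells carry NaN.  The operation is
    idempotent and invariant to positive rescaling of a raw column.  A zero
    plate mean is an error naming the parameter.
    """
    out = well_table.copy()
    if include is None:
        mask = np.ones(len(out), dtype=bool)
    else:
        mask = np.asarray(include, dtype=bool)
    if mask.sum() < 1:
        raise StatsError("normalization requires at least one included well")
    for p in parameters:
        col = out[p].to_numpy(dtype=float)
        mean = np.nanmean(col[mask])
        if mean == 0 or not np.isfinite(mean):
            raise StatsError(f"plate mean of parameter {p!r} is zero or undefined")
        norm = col / mean
        norm[~mask] = np.nan
        out[p] = norm
    return out


def normalize_screen(
    well_table: pd.DataFrame,
    parameters: Sequence[str],
    include: Optional[pd.Series] = None,
) -> pd.DataFrame:
    """Apply :func:`normalize_plate` per plate_id over a multi-plate table."""
    parts = []
    for plate, grp in well_table.groupby("plate_id", sort=False):
        inc = include.loc[grp.index] if include is not None else None
        parts.append(normalize_plate(grp, parameters, inc))
    return pd.concat(parts, axis=0)


# ---------------------------------------------------------------------------
# Replicate correlation with the rotated-plate control
# ---------------------------------------------------------------------------

def pair_correlation(
    table_a: pd.DataFrame,
    table_b: pd.DataFrame,
    parameter: str,
    alignment: str = "aligned",
) -> float:
    """Squared Pearson correlation of a parameter between two replicate plates.

    ``aligned`` pairs well w with well w; ``rotated`` pairs w with its
    180-degree partner (B3 with G10, F5 with C8).  Wells missing or NaN on
    either side are dropped pairwise; fewer than 3 common wells or zero
    variance on either side is an error.
    """
    if alignment not in ("aligned", "rotated"):
        raise DesignError(f"alignment must be 'aligned' or 'rotated', got {alignment!r}")
    a = table_a.set_index("well_id")[parameter]
    b = table_b.set_index("well_id")[parameter]
    if a.index.has_duplicates or b.index.has_duplicates:
        raise DesignError("duplicate well ids within one plate table")
    rows = []
    for w, va in a.items():
        partner = w if alignment == "aligned" else rotate_well_180(w)
        if partner in b.index:
            rows.append((va, b[partner]))
    arr = np.asarray(rows, dtype=float)
    if len(arr):
        arr = arr[~np.isnan(arr).any(axis=1)]
    if len(arr) < 3:
        raise StatsError(
            f"parameter {parameter!r}: only {len(arr)} common wells; need >= 3"
        )
    if arr[:, 0].std() == 0 or arr[:, 1].std() == 0:
        raise StatsError(f"parameter {parameter!r}: zero variance on one side")
    r = stats.pearsonr(arr[:, 0], arr[:, 1]).statistic
    return float(r * r)


@dataclass
class CorrelationReport:
    """Per-(pair, parameter, alignment) r-squared entries with aggregates."""

    entries: pd.DataFrame  # columns: pair, parameter, alignment, r2
    per_pair: pd.DataFrame  # pair x alignment: mean, sd over parameters; ranked
    per_parameter: pd.DataFrame  # parameter x alignment: mean over pairs; ranked


def correlation_report(
    pairs: Sequence[tuple[str, pd.DataFrame, pd.DataFrame]],
    parameters: Sequence[str],
) -> CorrelationReport:
    """Aligned and rotated r-squared for every (replicate pair, parameter).

    Failures of individual correlations (too few wells, zero variance) are
    recorded as missing entries rather than aborting the report.  Aggregates:
    per-pair mean and SD across parameters, per-parameter mean across pairs,
    each ranked by aligned mean descending.
    """
    if len(pairs) < 1:
        raise DesignError("correlation report needs at least one plate pair")
    rows = []
    for pair_id, ta, tb in pairs:
        for param in parameters:
            for alignment in ("aligned", "rotated"):
                try:
                    r2 = pair_correlation(ta, tb, param, alignment)
                except StatsError as exc:
                    logger.warning("pair %s %s %s: %s", pair_id, param, alignment, exc)
                    r2 = np.nan
                rows.append(
                    {"pair": pair_id, "parameter": param, "alignment": alignment, "r2": r2}
                )
    entries = pd.DataFrame(rows, columns=["pair", "parameter", "alignment", "r2"])

    per_pair = (
        entries.groupby(["pair", "alignment"])["r2"]
        .agg(mean="mean", sd="std")
        .reset_index()
    )
    aligned_rank = (
        per_pair[per_pair["alignment"] == "aligned"]
        .sort_values("mean", ascending=False)["pair"]
        .tolist()
    )
    per_pair["rank"] = per_pair["pair"].map({p: i + 1 for i, p in enumerate(aligned_rank)})
    per_pair = per_pair.sort_values(["rank", "alignment"]).reset_index(drop=True)

    per_parameter = (
        entries.groupby(["parameter", "alignment"])["r2"].mean().rename("mean").reset_index()
    )
    param_rank = (
        per_parameter[per_parameter["alignment"] == "aligned"]
        .sort_values("mean", ascending=False)["parameter"]
        .tolist()
    )
    per_parameter["rank"] = per_parameter["parameter"].map(
        {p: i + 1 for i, p in enumerate(param_rank)}
    )
    per_parameter = per_parameter.sort_values(["rank", "alignment"]).reset_index(drop=True)
    return CorrelationReport(entries=entries, per_pair=per_pair, per_parameter=per_parameter)
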