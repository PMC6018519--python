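"""Per-cell feature extraction and well-level aggregation.

Features follow the Plate > Well > Field > Cell hierarchy: each traced
nucleus yields one :data:`CELL_COLUMNS` record (compartment intensity means,
puncta counts/areas/integrated intensities per compartment, hole count,
nuclear area and shape), and cells from QC-passing fields are pooled into
well summaries.  The well statistic is the unweighted mean over all cells of
the well (not a mean of field means); cell density is cells per passing
field.
"""

from __future__ import annotations

import logging
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import measure

from .errors import ConsistencyError, DesignError
from .imaging_io import FieldImage
from .segmentation import Punctum

logger = logging.getLogger(__name__)

CELL_COLUMNS = [
    "plate_id",
    "well_id",
    "field_index",
    "cell_label",
    "nuclear_area",
    "nuclear_shape",
    "nuclear_dna_intensity",
    "nuclear_lc3_intensity",
    "cytoplasmic_lc3_intensity",
    "cytoplasmic_dna_intensity",
    "nuclear_puncta_count",
    "cytoplasmic_puncta_count",
    "nuclear_puncta_area",
    "cytoplasmic_puncta_area",
    "nuclear_puncta_intensity",
    "cytoplasmic_puncta_intensity",
    "holes_count",
]

#: cell-level columns averaged into the well summary
WELL_MEAN_COLUMNS = [
    "nuclear_area",
    "nuclear_shape",
    "nuclear_dna_intensity",
    "nuclear_lc3_intensity",
    "cytoplasmic_lc3_intensity",
    "cytoplasmic_dna_intensity",
    "nuclear_puncta_count",
    "cytoplasmic_puncta_count",
    "nuclear_puncta_area",
    "cytoplasmic_puncta_area",
    "nuclear_puncta_intensity",
    "cytoplasmic_puncta_intensity",
    "holes_count",
]


def extract_cell_records(
    field: FieldImage,
    nuclei_labels: np.ndarray,
    ring_labels: np.ndarray,
    holes: dict[int, list[dict]],
    puncta: Iterable[Punctum],
    shape_metric: str = "eccentricity",
) -> pd.DataFrame:
    """One record per traced nucleus of a field.

    Compartment intensity means are computed over the nuclear / ring masks of
    each label; puncta and hole features are joined by owner label.
    ``shape_metric`` is ``eccentricity`` (default) or ``form_factor``
    (4*pi*A/P^2).  A hole or punctum owner absent from the label raster is a
    consistency error.
    """
    if shape_metric not in ("eccentricity", "form_factor"):
        raise DesignError(f"unknown shape metric {shape_metric!r}")
    nuclei_labels = np.asarray(nuclei_labels)
    ring_labels = np.asarray(ring_labels)
    present = set(int(l) for l in np.unique(nuclei_labels) if l > 0)
    for lab in holes:
        if lab not in present:
            raise ConsistencyError(f"hole owner label {lab} absent from nuclei raster")
    puncta = list(puncta)
    for pt in puncta:
        if pt.owner_cell not in present:
            raise ConsistencyError(
                f"punctum owner label {pt.owner_cell} absent from nuclei raster"
            )

    dna = field.dna.astype(float)
    lc3 = field.lc3.astype(float)
    records = []
    for region in measure.regionprops(nuclei_labels):
        lab = int(region.label)
        nuc_mask = nuclei_labels == lab
        ring_mask = ring_labels == lab
        if shape_metric == "eccentricity":
            shape_val = float(region.eccentricity)
        else:
            shape_val = float(4.0 * np.pi * region.area / max(region.perimeter, 1e-9) ** 2)
        rec = {
            "plate_id": field.plate_id,
            "well_id": field.well_id,
            "field_index": field.field_index,
            "cell_label": lab,
            "nuclear_area": int(region.area),
            "nuclear_shape": shape_val,
            "nuclear_dna_intensity": float(dna[nuc_mask].mean()),
            "nuclear_lc3_intensity": float(lc3[nuc_mask].mean()),
            "cytoplasmic_lc3_intensity": float(lc3[ring_mask].mean()) if ring_mask.any() else 0.0,
            "cytoplasmic_dna_intensity": float(dna[ring_mask].mean()) if ring_mask.any() else 0.0,
            "holes_count": len(holes.get(lab, [])),
        }
        for comp in ("nuclear", "cytoplasmic"):
            mine = [pt for pt in puncta if pt.owner_cell == lab and pt.compartment == comp]
            rec[f"{comp}_puncta_count"] = len(mine)
            rec[f"{comp}_puncta_area"] = int(sum(pt.area for pt in mine))
            rec[f"{comp}_puncta_intensity"] = float(
                sum(pt.integrated_intensity for pt in mine)
            )
        records.append(rec)
    return pd.DataFrame(records, columns=CELL_COLUMNS)


def image_sharpness(raster: np.ndarray) -> float:
    """Normalized focus metric: Var(Laplacian) / mean(I)^2.

    The normalization makes the metric invariant to multiplying the raster by
    a positive constant (exposure/gain), so the QC threshold can be
    plate-relative.  A constant raster returns 0.
    """
    x = np.asarray(raster, dtype=float)
    if x.size == 0 or x.max() == x.min():
        return 0.0
    lap = ndimage.laplace(x)
    mean = x.mean()
    if mean == 0:
        return 0.0
    return float(lap.var() / mean**2)


def aggregate_wells(
    cell_records: pd.DataFrame,
    qc_flags: pd.DataFrame,
) -> pd.DataFrame:
    """Pool cells from QC-passing fields into per-well summaries.

    ``qc_flags`` must cover every (plate, well, field) present in the cell
    table, with a boolean ``pass`` column (column name ``passed`` also
    accepted).  Cells from failing fields are excluded; per-parameter values
    are unweighted means over the remaining cells; ``cell_density`` is total
    cells divided by the number of passing fields.  Wells whose fields all
    fail QC are omitted with a log message.
    """
    qc = qc_flags.copy()
    pass_col = "pass" if "pass" in qc.columns else "passed"
    if pass_col not in qc.columns:
        raise DesignError("qc_flags needs a 'pass' boolean column")
    key = ["plate_id", "well_id", "field_index"]
    qc_idx = qc.set_index(key)
    if not cell_records.empty:
        cells_fields = set(map(tuple, cell_records[key].drop_duplicates().to_numpy()))
        missing = cells_fields - set(qc_idx.index)
        if missing:
            raise DesignError(
                f"qc_flags missing {len(missing)} fields present in cell records, "
                f"e.g. {sorted(missing)[:3]}"
            )

    summaries = []
    for (plate, well), grp in qc.groupby(["plate_id", "well_id"], sort=True):
        n_pass = int(grp[pass_col].astype(bool).sum())
        if n_pass == 0:
            logger.info("well %s/%s: all fields failed QC; summary omitted", plate, well)
            continue
        ok_fields = set(grp.loc[grp[pass_col].astype(bool), "field_index"])
        if cell_records.empty:
            cells = cell_records
        else:
            cells = cell_records[
                (cell_records["plate_id"] == plate)
                & (cell_records["well_id"] == well)
                & (cell_records["field_index"].isin(ok_fields))
            ]
        rec = {
            "plate_id": plate,
            "well_id": well,
            "n_fields_passing": n_pass,
            "cell_density": len(cells) / n_pass,
        }
        for col in WELL_MEAN_COLUMNS:
            rec[col] = float(cells[col].mean()) if len(cells) else np.nan
        summaries.append(rec)
    cols = ["plate_id", "well_id", "n_fields_passing", "cell_density"] + WELL_MEAN_COLUMNS
    return pd.DataFrame(summaries, columns=cols)
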