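"""Image and plate-map I/O plus 96-well coordinate algebra.

The screen's rasters are 16-bit single-channel grayscale TIFFs, one file per
fluorescence channel (DNA/Hoechst and LC3/TRITC).  Microscope acquisitions
that arrive as 2x2 montages are split into four single fields before
analysis.  Plates are standard 8x12 (rows A-H, columns 1-12); the
180-degree rotation map used by the plate-effect control lives here because
it is pure well-coordinate algebra.

Conventions: pixel coordinates are 0-based, row-major, origin top-left;
well columns are 1-based as printed on plates.  Montage quadrants are
returned in top-left, top-right, bottom-left, bottom-right order.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import tifffile

from .errors import ImageFormatError, PlateMapError

ROW_LETTERS = "ABCDEFGH"
N_ROWS = 8
N_COLS = 12

_WELL_RE = re.compile(r"^([A-H])([1-9]|1[0-2])$")

PLATE_MAP_COLUMNS = ["well", "role", "compound_id", "dose_uM", "replicate_group"]
WELL_ROLES = frozenset({"vehicle", "compound", "empty"})


# ---------------------------------------------------------------------------
# Well coordinate algebra
# ---------------------------------------------------------------------------

def parse_well(well_id: str) -> tuple[int, int]:
    """Parse ``"B3"`` into 0-based ``(row, col)`` = ``(1, 2)``."""
    m = _WELL_RE.match(str(well_id).strip())
    if m is None:
        raise PlateMapError(f"invalid well id {well_id!r} (expected A1..H12)")
    return ROW_LETTERS.index(m.group(1)), int(m.group(2)) - 1


def format_well(row: int, col: int) -> str:
    """Format 0-based ``(row, col)`` as a printed well id, e.g. (1, 2) -> B3."""
    if not (0 <= row < N_ROWS and 0 <= col < N_COLS):
        raise PlateMapError(f"well coordinates ({row}, {col}) outside the 8x12 grid")
    return f"{ROW_LETTERS[row]}{col + 1}"


def all_wells() -> list[str]:
    """All 96 well ids in row-major order A1..H12."""
    return [format_well(r, c) for r in range(N_ROWS) for c in range(N_COLS)]


def border_wells() -> list[str]:
    """The 36 edge wells (vehicle positions in the screen design)."""
    return [
        format_well(r, c)
        for r in range(N_ROWS)
        for c in range(N_COLS)
        if r in (0, N_ROWS - 1) or c in (0, N_COLS - 1)
    ]


def interior_wells() -> list[str]:
    """The 60 non-edge wells (compound positions), row-major B2..G11."""
    return [
        format_well(r, c)
        for r in range(1, N_ROWS - 1)
        for c in range(1, N_COLS - 1)
    ]


def rotate_well_180(well_id: str) -> str:
    """Map a well to its 180-degree-rotated partner (B3 -> G10, F5 -> C8).

    Rotating the plate maps 0-based ``(r, c)`` to ``(7 - r, 11 - c)``.  The
    map is a fixed-point-free involution on the 8x12 grid.
    """
    r, c = parse_well(well_id)
    return format_well(N_ROWS - 1 - r, N_COLS - 1 - c)


# ---------------------------------------------------------------------------
# Plate layout
# ---------------------------------------------------------------------------

@dataclass
class WellInfo:
    role: str
    compound_id: Optional[str] = None
    dose_uM: float = 0.0
    replicate_group: str = ""

    def __post_init__(self) -> None:
        if self.role not in WELL_ROLES:
            raise PlateMapError(f"unknown well role {self.role!r}")
        if self.role == "compound" and not self.compound_id:
            raise PlateMapError("compound well lacks a compound_id")
        if self.role != "compound" and self.compound_id:
            raise PlateMapError(
                f"{self.role} well must not carry a compound_id ({self.compound_id!r})"
            )
        if self.dose_uM < 0:
            raise PlateMapError(f"negative dose {self.dose_uM}")


@dataclass
class PlateLayout:
    """One 96-well plate: well id -> role / compound / dose / replicate."""

    plate_id: str
    wells: dict[str, WellInfo] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for w in self.wells:
            parse_well(w)  # validates
        # missing wells default to empty
        for w in all_wells():
            self.wells.setdefault(w, WellInfo(role="empty"))

    def role_counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for info in self.wells.values():
            out[info.role] = out.get(info.role, 0) + 1
        return out

    def compound_wells(self) -> dict[str, WellInfo]:
        return {w: i for w, i in self.wells.items() if i.role == "compound"}

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for w in all_wells():
            info = self.wells[w]
            rows.append(
                {
                    "well": w,
                    "role": info.role,
                    "compound_id": info.compound_id or "",
                    "dose_uM": info.dose_uM,
                    "replicate_group": info.replicate_group,
                }
            )
        return pd.DataFrame(rows, columns=PLATE_MAP_COLUMNS)


def save_plate_map(layout: PlateLayout, path: str | Path) -> None:
    layout.to_frame().to_csv(path, index=False)


def load_plate_map(path: str | Path, plate_id: Optional[str] = None) -> PlateLayout:
    """Load and validate a plate-map CSV into a :class:`PlateLayout`.

    The dialect is comma-separated UTF-8 with header exactly
    ``well,role,compound_id,dose_uM,replicate_group``.  Wells absent from the
    file default to ``empty``.  Errors report the offending CSV row number
    (1-based, counting the header as row 1).
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if list(df.columns) != PLATE_MAP_COLUMNS:
        raise PlateMapError(
            f"{path.name}: header must be exactly {','.join(PLATE_MAP_COLUMNS)}, "
            f"got {','.join(df.columns)}"
        )
    wells: dict[str, WellInfo] = {}
    for i, rec in enumerate(df.itertuples(index=False), start=2):
        try:
            parse_well(rec.well)
        except PlateMapError as exc:
            raise PlateMapError(f"{path.name} row {i}: {exc}") from None
        if rec.well in wells:
            raise PlateMapError(f"{path.name} row {i}: duplicate well id {rec.well!r}")
        try:
            dose = float(rec.dose_uM) if rec.dose_uM != "" else 0.0
        except ValueError:
            raise PlateMapError(
                f"{path.name} row {i}: dose_uM {rec.dose_uM!r} is not a number"
            ) from None
        try:
            wells[rec.well] = WellInfo(
                role=rec.role,
                compound_id=rec.compound_id or None,
                dose_uM=dose,
                replicate_group=rec.replicate_group,
            )
        except PlateMapError as exc:
            raise PlateMapError(f"{path.name} row {i}: {exc}") from None
    return PlateLayout(plate_id=plate_id or path.stem, wells=wells)


# ---------------------------------------------------------------------------
# Field image container
# ---------------------------------------------------------------------------

@dataclass
class FieldImage:
    """Aligned two-channel 16-bit rasters for one imaged field."""

    dna: np.ndarray
    lc3: np.ndarray
    plate_id: str = ""
    well_id: str = ""
    field_index: int = 0

    def __post_init__(self) -> None:
        for name, arr in (("dna", self.dna), ("lc3", self.lc3)):
            if arr.ndim != 2:
                raise ImageFormatError(f"{name} raster must be 2-D, got {arr.ndim}-D")
            if arr.dtype != np.uint16:
                raise ImageFormatError(f"{name} raster must be uint16, got {arr.dtype}")
        if self.dna.shape != self.lc3.shape:
            raise ImageFormatError(
                f"channel shape mismatch: dna {self.dna.shape} vs lc3 {self.lc3.shape}"
            )


def field_tiff_name(plate_id: str, well_id: str, field_index: int, channel: str) -> str:
    """Filename convention for exported fields: {plate}_{well}_{field}_{channel}.tif."""
    return f"{plate_id}_{well_id}_{field_index}_{channel}.tif"


# ---------------------------------------------------------------------------
# TIFF I/O (strict 16-bit single channel, no silent conversion)
# ---------------------------------------------------------------------------

def read_channel_tiff(path: str | Path) -> np.ndarray:
    """Read a single-channel 16-bit grayscale TIFF as a 2-D uint16 array."""
    arr = tifffile.imread(path)
    if arr.ndim != 2:
        raise ImageFormatError(
            f"{Path(path).name}: expected a single-channel 2-D image, "
            f"got shape {arr.shape} (multi-channel/RGB or stack)"
        )
    if arr.dtype != np.uint16:
        raise ImageFormatError(
            f"{Path(path).name}: expected 16-bit unsigned pixels, got {arr.dtype}; "
            "refusing silent conversion"
        )
    return arr


def write_channel_tiff(raster: np.ndarray, path: str | Path) -> None:
    """Write a 2-D integer raster as 16-bit grayscale TIFF (bit-exact round trip)."""
    raster = np.asarray(raster)
    if raster.ndim != 2:
        raise ImageFormatError(f"raster must be 2-D, got {raster.ndim}-D")
    if not np.issubdtype(raster.dtype, np.integer):
        raise ImageFormatError(
            f"raster dtype {raster.dtype} is not integer; values must be exact 16-bit counts"
        )
    if raster.size and (raster.min() < 0 or raster.max() > np.iinfo(np.uint16).max):
        raise ImageFormatError(
            f"raster values [{raster.min()}, {raster.max()}] outside the 16-bit range [0, 65535]"
        )
    tifffile.imwrite(path, raster.astype(np.uint16))


# ---------------------------------------------------------------------------
# Montage splitting
# ---------------------------------------------------------------------------

def split_montage(raster: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Split a 2x2 tiled montage into (top-left, top-right, bottom-left, bottom-right).

    Each quadrant is exactly half-height x half-width; reassembling the four
    quadrants reconstructs the input bit-exactly.
    """
    raster = np.asarray(raster)
    if raster.ndim != 2:
        raise ImageFormatError(f"montage must be 2-D, got {raster.ndim}-D")
    h, w = raster.shape
    if h % 2 or w % 2:
        raise ImageFormatError(f"montage dimensions {raster.shape} must both be even")
    hh, hw = h // 2, w // 2
    return (
        raster[:hh, :hw].copy(),
        raster[:hh, hw:].copy(),
        raster[hh:, :hw].copy(),
        raster[hh:, hw:].copy(),
    )


def reassemble_montage(tl: np.ndarray, tr: np.ndarray, bl: np.ndarray, br: np.ndarray) -> np.ndarray:
    """Inverse of :func:`split_montage`."""
    return np.block([[tl, tr], [bl, br]])
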