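"""File binding for fields, plate layouts, manifests and result tables.

Conventions used throughout the package:

* pixel coordinates are 0-based ``(row, col)``, row-major;
* channel pairing is by filename convention recorded in the manifest
  (``{well}_{field:02d}_{channel}.tif`` with channel in {chl, gfp}), never
  by TIFF metadata;
* tables are plain CSV with a fixed, documented column order.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "FieldImage",
    "LayoutRow",
    "PlateLayout",
    "LayoutError",
    "RegistrationError",
    "read_field",
    "write_field",
    "read_layout",
    "write_layout",
    "read_manifest",
    "iter_manifest_fields",
    "write_cell_table",
    "read_cell_table",
    "write_well_table",
    "read_well_table",
    "CELL_TABLE_COLUMNS",
    "WELL_TABLE_COLUMNS",
]

ROLES = ("treated", "wt_control", "blank")

CELL_TABLE_COLUMNS = [
    "cell_uid",
    "well_id",
    "field_index",
    "label",
    "area_px",
    "centroid_row_px",
    "centroid_col_px",
    "chl_median",
    "chl_mean",
    "gfp_median",
    "gfp_mean",
    "gfp_positive",
    "gfp_margin_positive",
]

WELL_TABLE_COLUMNS = [
    "well_id",
    "condition",
    "n_fields",
    "n_cells_total",
    "n_gfp_positive",
    "n_margin_positive",
    "efficiency_percent",
]


class LayoutError(ValueError):
    """Invalid plate-layout table."""


class RegistrationError(ValueError):
    """Channel images of one field do not align."""


@dataclass
class FieldImage:
    """One imaged position in a well: registered chlorophyll + GFP rasters."""

    well_id: str
    field_index: int
    chl: np.ndarray
    gfp: np.ndarray
    bit_depth: int

    def __post_init__(self) -> None:
        if self.chl.shape != self.gfp.shape:
            raise RegistrationError(
                f"channel shapes differ: chl {self.chl.shape} vs gfp {self.gfp.shape}"
            )
        if self.bit_depth not in (8, 16):
            raise ValueError("bit_depth must be 8 or 16")

    @property
    def shape(self) -> tuple[int, int]:
        return self.chl.shape


@dataclass(frozen=True)
class LayoutRow:
    well_id: str
    condition: str
    role: str
    n_fields: int


@dataclass
class PlateLayout:
    """Assignment of wells to conditions and roles.

    Roles: ``treated`` (co-cultivated wells), ``wt_control`` (untreated
    wild-type wells used to calibrate the positivity threshold) and
    ``blank`` (ignored).
    """

    rows: list[LayoutRow]

    def validate(self, require_control: bool = False) -> None:
        ids = [r.well_id for r in self.rows]
        if len(set(ids)) != len(ids):
            dupes = sorted({w for w in ids if ids.count(w) > 1})
            raise LayoutError(f"duplicate well ids in layout: {dupes}")
        for r in self.rows:
            if r.role not in ROLES:
                raise LayoutError(f"unknown role {r.role!r} for well {r.well_id}")
            if r.n_fields < 1:
                raise LayoutError(f"n_fields must be >= 1 for well {r.well_id}")
        if require_control and not self.control_wells():
            raise LayoutError(
                "layout designates no wt_control well; the GFP positivity "
                "threshold cannot be calibrated"
            )

    def control_wells(self) -> list[str]:
        return [r.well_id for r in self.rows if r.role == "wt_control"]

    def condition_of(self, well_id: str) -> str:
        for r in self.rows:
            if r.well_id == well_id:
                return r.condition
        raise KeyError(well_id)


def _load_gray(path: Path) -> np.ndarray:
    if not path.exists():
        raise FileNotFoundError(path)
    arr = tifffile.imread(path)
    if arr.ndim != 2:
        raise ValueError(f"unsupported TIFF (expected single-page 2-D grayscale): {path}")
    if arr.dtype not in (np.dtype(np.uint8), np.dtype(np.uint16)):
        raise ValueError(f"unsupported TIFF dtype {arr.dtype} in {path}")
    return arr


def read_field(
    chl_path: str | Path, gfp_path: str | Path, well_id: str, field_index: int
) -> FieldImage:
    """Read one field's two channel TIFFs; shape mismatch is an error."""
    chl = _load_gray(Path(chl_path))
    gfp = _load_gray(Path(gfp_path))
    if chl.shape != gfp.shape:
        raise RegistrationError(
            f"channel shapes differ for {well_id} field {field_index}: "
            f"{chl.shape} vs {gfp.shape}"
        )
    if chl.dtype != gfp.dtype:
        raise RegistrationError(
            f"channel dtypes differ for {well_id} field {field_index}"
        )
    bit_depth = 8 if chl.dtype == np.uint8 else 16
    return FieldImage(well_id, field_index, chl, gfp, bit_depth)


def write_field(field: FieldImage, out_dir: str | Path) -> dict[str, Path]:
    """Write one TIFF per channel using the package naming convention."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for channel, raster in (("chl", field.chl), ("gfp", field.gfp)):
        p = out_dir / f"{field.well_id}_{field.field_index:02d}_{channel}.tif"
        tifffile.imwrite(p, raster)
        paths[channel] = p
    return paths


def read_layout(path: str | Path) -> PlateLayout:
    """Read a layout CSV with columns well, condition, role, n_fields."""
    df = pd.read_csv(path, dtype={"well": str, "condition": str, "role": str})
    required = {"well", "condition", "role", "n_fields"}
    missing = required - set(df.columns)
    if missing:
        raise LayoutError(f"layout file missing columns: {sorted(missing)}")
    rows = [
        LayoutRow(r.well, r.condition, r.role, int(r.n_fields))
        for r in df.itertuples(index=False)
    ]
    layout = PlateLayout(rows)
    layout.validate()
    return layout


def write_layout(layout: PlateLayout, path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "well": r.well_id,
                "condition": r.condition,
                "role": r.role,
                "n_fields": r.n_fields,
            }
            for r in layout.rows
        ]
    ).to_csv(path, index=False)


def read_manifest(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def iter_manifest_fields(manifest: dict, base_dir: str | Path):
    """Yield (well_id, condition, role, FieldImage) for every field listed."""
    base = Path(base_dir)
    for well_id in sorted(manifest["wells"]):
        entry = manifest["wells"][well_id]
        for f in sorted(entry["fields"], key=lambda e: e["field_index"]):
            field = read_field(
                base / f["chl"], base / f["gfp"], well_id, int(f["field_index"])
            )
            yield well_id, entry["condition"], entry["role"], field


def write_cell_table(records: pd.DataFrame, path: str | Path) -> None:
    """Write the per-cell table in the documented column order."""
    df = records.copy()
    for col in CELL_TABLE_COLUMNS:
        if col not in df.columns:
            df[col] = pd.NA
    df[CELL_TABLE_COLUMNS].to_csv(path, index=False, float_format="%.17g")


def read_cell_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"well_id": str, "cell_uid": str})


def write_well_table(summaries: pd.DataFrame, path: str | Path) -> None:
    df = summaries.copy()
    for col in WELL_TABLE_COLUMNS:
        if col not in df.columns:
            df[col] = pd.NA
    df[WELL_TABLE_COLUMNS].to_csv(path, index=False, float_format="%.17g")


def read_well_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"well_id": str, "condition": str})
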