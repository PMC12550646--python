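"""End-to-end plate analysis: segment -> measure -> calibrate -> classify.

The entry points mirror how the assay is evaluated: all fields of all
non-blank wells are segmented in the chlorophyll channel and measured in
both channels; wild-type control cells are pooled into one positivity
threshold per plate; every cell is then classified and per-well
transformation efficiencies computed.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .classify import (
    DEFAULT_MARGIN_FRACTION,
    DEFAULT_PERCENTILE,
    ThresholdModel,
    calibrate_threshold,
    classify_cells,
    compute_efficiency,
)
from .io import (
    FieldImage,
    PlateLayout,
    iter_manifest_fields,
    read_manifest,
    write_cell_table,
    write_well_table,
)
from .measure import measure_cells
from .segment import SegmentationParams, segment_chlorophyll

__all__ = ["measure_fields", "analyze_plate", "run_plate"]


def measure_fields(
    fields: list[FieldImage], params: SegmentationParams | None = None
) -> pd.DataFrame:
    """Segment and measure a list of fields; returns pooled cell records."""
    frames = [measure_cells(f, segment_chlorophyll(f, params)) for f in fields]
    nonempty = [df for df in frames if not df.empty]
    if not nonempty:
        return frames[0] if frames else pd.DataFrame()
    return pd.concat(nonempty, ignore_index=True)


def analyze_plate(
    fields_by_well: dict[str, list[FieldImage]],
    layout: PlateLayout,
    params: SegmentationParams | None = None,
    percentile: float = DEFAULT_PERCENTILE,
    margin_fraction: float = DEFAULT_MARGIN_FRACTION,
) -> tuple[pd.DataFrame, pd.DataFrame, ThresholdModel]:
    """Analyze in-memory fields of a plate.

    Returns (classified cell records, per-well summaries, threshold model).
    """
    layout.validate(require_control=True)
    params = params or SegmentationParams()
    all_records = []
    for row in layout.rows:
        if row.role == "blank" or row.well_id not in fields_by_well:
            continue
        all_records.append(measure_fields(fields_by_well[row.well_id], params))
    records = pd.concat(
        [df for df in all_records if not df.empty], ignore_index=True
    ) if all_records else pd.DataFrame()

    control_ids = set(layout.control_wells())
    wt_records = records[records["well_id"].isin(control_ids)]
    model = calibrate_threshold(wt_records, percentile=percentile)
    records = classify_cells(records, model, margin_fraction=margin_fraction)
    wells = compute_efficiency(records, layout)
    return records, wells, model


def run_plate(
    manifest_path: str | Path,
    layout: PlateLayout,
    out_dir: str | Path,
    params: SegmentationParams | None = None,
    percentile: float = DEFAULT_PERCENTILE,
    margin_fraction: float = DEFAULT_MARGIN_FRACTION,
) -> tuple[pd.DataFrame, pd.DataFrame, ThresholdModel]:
    """Analyze a plate from disk and write cells.csv / wells.csv / threshold.json.

    ``manifest_path`` points at the JSON manifest produced by the simulator
    (or an equivalent hand-written one); images are resolved relative to it.
    """
    manifest_path = Path(manifest_path)
    manifest = read_manifest(manifest_path)
    base = manifest_path.parent
    fields_by_well: dict[str, list[FieldImage]] = {}
    for well_id, _cond, _role, field in iter_manifest_fields(manifest, base):
        fields_by_well.setdefault(well_id, []).append(field)

    records, wells, model = analyze_plate(
        fields_by_well, layout, params, percentile, margin_fraction
    )
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    write_cell_table(records, out_dir / "cells.csv")
    write_well_table(wells, out_dir / "wells.csv")
    with open(out_dir / "threshold.json", "w") as fh:
        json.dump(model.to_dict(), fh, indent=1, sort_keys=True)
    return records, wells, model
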