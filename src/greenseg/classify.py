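"""GFP positivity calibrated on wild-type control cells.

The positivity cutoff is not an absolute intensity: it is the 99.5th
percentile of the per-cell *median* GFP intensity of untreated wild-type
cells pooled across all control wells of a plate. By construction ~0.5% of
control-like cells exceed it by chance, which bounds the false-positive
rate while excluding the cells' intrinsic background autofluorescence.
A cell is GFP-positive when its median GFP intensity is strictly greater
than the cutoff. Per-well transformation efficiency is the percentage of
GFP-positive cells among all cells detected in the chlorophyll channel.

Because the design rate leaves ~0.5% of statistical positives even in a
true-negative well, a secondary review flag ``gfp_margin_positive`` marks
cells exceeding the cutoff by a documented multiplicative margin; wells are
reviewed on this flag when the qualitative call "no transformants present"
matters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import WELL_TABLE_COLUMNS, PlateLayout

__all__ = [
    "ThresholdModel",
    "CalibrationError",
    "calibrate_threshold",
    "classify_cells",
    "compute_efficiency",
    "DEFAULT_PERCENTILE",
    "DEFAULT_MARGIN_FRACTION",
    "MIN_WT_CELLS",
]

DEFAULT_PERCENTILE = 99.5
DEFAULT_MARGIN_FRACTION = 0.5
MIN_WT_CELLS = 200


class CalibrationError(ValueError):
    """Threshold calibration could not be performed reliably."""


@dataclass(frozen=True)
class ThresholdModel:
    """Wild-type-calibrated GFP positivity cutoff.

    ``statistic`` records which per-cell summary the cutoff applies to;
    only the per-cell median is supported, the mean being retained in the
    records purely for diagnostics.
    """

    percentile: float
    threshold_value: float
    n_wt_cells: int
    wt_well_ids: tuple[str, ...] = ()
    statistic: str = "median"

    def to_dict(self) -> dict:
        return {
            "percentile": self.percentile,
            "threshold_value": self.threshold_value,
            "n_wt_cells": self.n_wt_cells,
            "wt_well_ids": list(self.wt_well_ids),
            "statistic": self.statistic,
        }


def percentile_linear(values: np.ndarray, q: float) -> float:
    """Percentile with linear interpolation between order statistics.

    rank r = (n-1) * q / 100; value = x_(floor r) + frac(r) * (x_(floor r + 1)
    - x_(floor r)) on the sorted sample. This is the convention pinned for
    threshold calibration (numpy's default "linear" method).
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("cannot take a percentile of an empty sample")
    return float(np.percentile(values, q, method="linear"))


def calibrate_threshold(
    wt_records: pd.DataFrame,
    percentile: float = DEFAULT_PERCENTILE,
    min_cells: int = MIN_WT_CELLS,
) -> ThresholdModel:
    """Calibrate the positivity cutoff from pooled wild-type cell records.

    ``wt_records`` must hold the per-cell measurements of all wild-type
    control wells of the plate (pooled across wells and fields to maximize
    the sample behind an extreme percentile).
    """
    if not (0.0 < percentile <= 100.0):
        raise ValueError("percentile must lie in (0, 100]")
    n = len(wt_records)
    if n < min_cells:
        raise CalibrationError(
            f"only {n} wild-type cells available; at least {min_cells} are "
            "required for a reliable extreme-percentile threshold"
        )
    medians = wt_records["gfp_median"].to_numpy(dtype=float)
    value = percentile_linear(medians, percentile)
    wells = tuple(sorted(map(str, pd.unique(wt_records["well_id"]))))
    return ThresholdModel(
        percentile=float(percentile),
        threshold_value=value,
        n_wt_cells=n,
        wt_well_ids=wells,
    )


def classify_cells(
    records: pd.DataFrame,
    model: ThresholdModel,
    margin_fraction: float = DEFAULT_MARGIN_FRACTION,
) -> pd.DataFrame:
    """Flag every record as GFP-positive or not; none are dropped.

    ``gfp_positive`` uses the strict inequality gfp_median > cutoff.
    ``gfp_margin_positive`` additionally requires
    gfp_median > cutoff * (1 + margin_fraction); this is the conservative
    review flag for declaring a well free of transformants.
    """
    if margin_fraction < 0:
        raise ValueError("margin_fraction must be nonnegative")
    out = records.copy()
    medians = out["gfp_median"].to_numpy(dtype=float)
    out["gfp_positive"] = medians > model.threshold_value
    out["gfp_margin_positive"] = medians > model.threshold_value * (1.0 + margin_fraction)
    return out


def compute_efficiency(
    records: pd.DataFrame, layout: PlateLayout | None = None
) -> pd.DataFrame:
    """Per-well transformation efficiency from classified cell records.

    efficiency_percent = 100 * n_gfp_positive / n_cells_total. A well with
    zero detected cells reports NaN, never a silent 0%. Output columns
    follow the per-well CSV contract; stored at full precision (rendering
    to one decimal place happens only in reports).
    """
    if not records.empty and records["gfp_positive"].isna().any():
        raise ValueError("records must be classified before computing efficiency")
    rows = []
    if layout is not None:
        # wells with zero detected cells still get a row, flagged undefined
        seen = set(records["well_id"]) if not records.empty else set()
        for lay_row in layout.rows:
            if lay_row.role == "blank" or lay_row.well_id in seen:
                continue
            rows.append(
                {
                    "well_id": lay_row.well_id,
                    "condition": lay_row.condition,
                    "n_fields": 0,
                    "n_cells_total": 0,
                    "n_gfp_positive": 0,
                    "n_margin_positive": 0,
                    "efficiency_percent": float("nan"),
                }
            )
    if records.empty:
        return pd.DataFrame(rows, columns=WELL_TABLE_COLUMNS)
    for well_id, grp in records.groupby("well_id", sort=True):
        n_total = len(grp)
        n_pos = int(grp["gfp_positive"].sum())
        n_margin = int(grp["gfp_margin_positive"].sum())
        eff = 100.0 * n_pos / n_total if n_total > 0 else float("nan")
        rows.append(
            {
                "well_id": well_id,
                "condition": layout.condition_of(well_id) if layout else "",
                "n_fields": int(grp["field_index"].nunique()),
                "n_cells_total": n_total,
                "n_gfp_positive": n_pos,
                "n_margin_positive": n_margin,
                "efficiency_percent": eff,
            }
        )
    out = pd.DataFrame(rows, columns=WELL_TABLE_COLUMNS)
    return out.sort_values("well_id", ignore_index=True)
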