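"""Per-cell intensity measurement under the transferred chlorophyll mask.

The label mask derived from the chlorophyll channel is superimposed
unchanged onto the GFP channel, so both channels are summarized over
exactly the same pixels of each cell. Summaries are the median and the
arithmetic mean (median of an even pixel count is the midpoint of the two
central order statistics), plus area and intensity-unweighted centroid.
No background is subtracted at measurement time: the wild-type-calibrated
threshold downstream absorbs the intrinsic background.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .io import CELL_TABLE_COLUMNS, FieldImage

__all__ = ["measure_cells", "count_cells_per_well", "summarize_counts"]


def _empty_records() -> pd.DataFrame:
    df = pd.DataFrame(columns=CELL_TABLE_COLUMNS)
    return df.astype(
        {
            "field_index": int,
            "label": int,
            "area_px": int,
            "centroid_row_px": float,
            "centroid_col_px": float,
            "chl_median": float,
            "chl_mean": float,
            "gfp_median": float,
            "gfp_mean": float,
        }
    )


def measure_cells(field: FieldImage, mask: np.ndarray) -> pd.DataFrame:
    """Measure every labeled cell of ``field`` under ``mask``.

    Returns one row per label (columns as in the per-cell CSV contract);
    ``gfp_positive`` / ``gfp_margin_positive`` are left unset until
    classification. An empty mask yields an empty table.
    """
    if mask.shape != field.shape:
        raise ValueError(
            f"mask shape {mask.shape} does not match field shape {field.shape}"
        )
    n = int(mask.max())
    if n == 0:
        return _empty_records()
    index = np.arange(1, n + 1)

    areas = ndi.sum_labels(np.ones(mask.shape, dtype=np.int64), mask, index)
    centroids = np.asarray(ndi.center_of_mass(np.ones(mask.shape), mask, index))
    chl = field.chl.astype(np.float64)
    gfp = field.gfp.astype(np.float64)
    chl_median = ndi.labeled_comprehension(chl, mask, index, np.median, float, np.nan)
    gfp_median = ndi.labeled_comprehension(gfp, mask, index, np.median, float, np.nan)
    chl_mean = ndi.mean(chl, mask, index)
    gfp_mean = ndi.mean(gfp, mask, index)

    df = pd.DataFrame(
        {
            "cell_uid": [
                f"{field.well_id}_{field.field_index:02d}_L{lbl:05d}" for lbl in index
            ],
            "well_id": field.well_id,
            "field_index": field.field_index,
            "label": index,
            "area_px": areas.astype(int),
            "centroid_row_px": centroids[:, 0],
            "centroid_col_px": centroids[:, 1],
            "chl_median": chl_median,
            "chl_mean": chl_mean,
            "gfp_median": gfp_median,
            "gfp_mean": gfp_mean,
            "gfp_positive": pd.NA,
            "gfp_margin_positive": pd.NA,
        },
        columns=CELL_TABLE_COLUMNS,
    )
    return df


def count_cells_per_well(records: pd.DataFrame) -> pd.DataFrame:
    """Total detected cells per well (summed over that well's fields)."""
    if records.empty:
        return pd.DataFrame(columns=["well_id", "n_cells"]).astype({"n_cells": int})
    out = (
        records.groupby("well_id", sort=True)
        .size()
        .rename("n_cells")
        .reset_index()
    )
    return out


def summarize_counts(per_well: pd.DataFrame) -> dict[str, float]:
    """Mean +/- sample SD (n-1 denominator) of cells per well."""
    counts = per_well["n_cells"].to_numpy(dtype=float)
    return {
        "n_wells": float(counts.size),
        "mean_cells_per_well": float(np.mean(counts)) if counts.size else float("nan"),
        "sd_cells_per_well": float(np.std(counts, ddof=1)) if counts.size > 1 else float("nan"),
    }
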