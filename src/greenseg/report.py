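"""Condition-level aggregation, group comparisons and QC overlays.

Per-well efficiencies and cell counts are aggregated per condition as
mean +/- sample SD (n-1). Group differences are tested with the classical
two-sample Student's t-test (pooled variance, two-sided); Welch's form is
available behind a flag. No multiple-testing correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import PlateLayout
from .segment import extract_borders

__all__ = [
    "ConditionSummary",
    "GroupComparison",
    "aggregate_conditions",
    "compare_groups",
    "render_overlay",
    "render_condition_table",
]

CONDITION_TABLE_COLUMNS = [
    "condition",
    "n_wells",
    "n_undefined_wells",
    "mean_efficiency_percent",
    "sd_efficiency_percent",
    "mean_cells_per_well",
    "sd_cells_per_well",
]


@dataclass(frozen=True)
class ConditionSummary:
    condition: str
    n_wells: int
    n_undefined_wells: int
    mean_efficiency_percent: float
    sd_efficiency_percent: float
    mean_cells_per_well: float
    sd_cells_per_well: float


@dataclass(frozen=True)
class GroupComparison:
    condition_a: str
    condition_b: str
    statistic_name: str
    t_value: float
    degrees_of_freedom: float
    p_value: float
    two_sided: bool = True


def _mean_sd(x: np.ndarray) -> tuple[float, float]:
    if x.size == 0:
        return float("nan"), float("nan")
    m = float(np.mean(x))
    s = float(np.std(x, ddof=1)) if x.size > 1 else float("nan")
    return m, s


def aggregate_conditions(
    summaries: pd.DataFrame, layout: PlateLayout | None = None
) -> pd.DataFrame:
    """Per-condition mean and sample SD of efficiency and cells per well.

    Wells with undefined efficiency (zero detected cells) are excluded
    from the efficiency aggregates but counted in ``n_undefined_wells``;
    a condition whose wells are all undefined is still reported.
    """
    rows = []
    for condition, grp in summaries.groupby("condition", sort=True):
        eff = grp["efficiency_percent"].to_numpy(dtype=float)
        defined = eff[~np.isnan(eff)]
        counts = grp.loc[~np.isnan(eff), "n_cells_total"].to_numpy(dtype=float)
        m_eff, s_eff = _mean_sd(defined)
        m_cnt, s_cnt = _mean_sd(counts)
        rows.append(
            {
                "condition": condition,
                "n_wells": int(len(grp)),
                "n_undefined_wells": int(np.isnan(eff).sum()),
                "mean_efficiency_percent": m_eff,
                "sd_efficiency_percent": s_eff,
                "mean_cells_per_well": m_cnt,
                "sd_cells_per_well": s_cnt,
            }
        )
    return pd.DataFrame(rows, columns=CONDITION_TABLE_COLUMNS)


def compare_groups(
    a: np.ndarray | list,
    b: np.ndarray | list,
    condition_a: str = "a",
    condition_b: str = "b",
    welch: bool = False,
) -> GroupComparison:
    """Two-sample t-test between per-well values of two conditions.

    Classical Student form by default: pooled variance, two-sided p-value
    from the t distribution with n_a + n_b - 2 degrees of freedom. With
    zero pooled variance the test degenerates: equal means give t = 0,
    p = 1; unequal means are a degenerate-input error.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    if not welch:
        pooled = ((a.size - 1) * np.var(a, ddof=1) + (b.size - 1) * np.var(b, ddof=1)) / (
            a.size + b.size - 2
        )
        if pooled == 0.0:
            if np.mean(a) == np.mean(b):
                return GroupComparison(
                    condition_a, condition_b, "two-sample t", 0.0,
                    float(a.size + b.size - 2), 1.0,
                )
            raise ValueError(
                "zero pooled variance with unequal means: t statistic undefined"
            )
    res = stats.ttest_ind(a, b, equal_var=not welch)
    return GroupComparison(
        condition_a=condition_a,
        condition_b=condition_b,
        statistic_name="two-sample t" if not welch else "Welch t",
        t_value=float(res.statistic),
        degrees_of_freedom=float(res.df),
        p_value=float(res.pvalue),
        two_sided=True,
    )


def render_overlay(field_chl: np.ndarray, mask: np.ndarray, records: pd.DataFrame) -> np.ndarray:
    """RGB QC image: chlorophyll grayscale with cell outlines colored by call.

    GFP-positive cells get green outlines, negative cells gray ones. An
    empty mask returns the unmodified grayscale composite. Diagnostic only.
    """
    lo, hi = float(field_chl.min()), float(field_chl.max())
    scale = (field_chl.astype(np.float64) - lo) / (hi - lo) if hi > lo else np.zeros(
        field_chl.shape
    )
    rgb = np.repeat((scale * 255).astype(np.uint8)[..., None], 3, axis=2)
    if mask.max() == 0:
        return rgb
    borders = extract_borders(mask)
    positive_labels = set(
        records.loc[records["gfp_positive"].fillna(False).astype(bool), "label"].astype(int)
    )
    pos_mask = np.isin(mask, sorted(positive_labels)) & borders
    neg_mask = borders & ~pos_mask
    rgb[neg_mask] = (160, 160, 160)
    rgb[pos_mask] = (0, 220, 0)
    return rgb


def render_condition_table(conditions: pd.DataFrame) -> str:
    """Markdown table of per-condition efficiencies, 1 decimal place."""
    lines = [
        "| Condition | Wells | Efficiency (%) | Cells/well |",
        "| --- | --- | --- | --- |",
    ]
    for r in conditions.itertuples(index=False):
        if np.isnan(r.mean_efficiency_percent):
            eff = "n.d."
        elif np.isnan(r.sd_efficiency_percent):
            eff = f"{r.mean_efficiency_percent:.1f}"
        else:
            eff = f"{r.mean_efficiency_percent:.1f} ± {r.sd_efficiency_percent:.1f}"
        if np.isnan(r.mean_cells_per_well):
            cnt = "n.d."
        elif np.isnan(r.sd_cells_per_well):
            cnt = f"{r.mean_cells_per_well:.0f}"
        else:
            cnt = f"{r.mean_cells_per_well:.0f} ± {r.sd_cells_per_well:.0f}"
        lines.append(f"| {r.condition} | {r.n_wells} | {eff} | {cnt} |")
    return "\n".join(lines) + "\n"
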