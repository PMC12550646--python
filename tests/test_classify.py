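"""Wild-type percentile calibration, positivity calls and efficiency."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from greenseg import (
    CalibrationError,
    PlateLayout,
    calibrate_threshold,
    classify_cells,
    compute_efficiency,
)
from greenseg.classify import ThresholdModel, percentile_linear
from greenseg.io import LayoutRow

from conftest import make_wt_records


def _records(values, well="T01"):
    n = len(values)
    return pd.DataFrame(
        {
            "cell_uid": [f"{well}_{i}" for i in range(n)],
            "well_id": well,
            "field_index": 0,
            "label": np.arange(1, n + 1),
            "area_px": 300,
            "centroid_row_px": 0.0,
            "centroid_col_px": 0.0,
            "chl_median": 2000.0,
            "chl_mean": 2000.0,
            "gfp_median": np.asarray(values, dtype=float),
            "gfp_mean": np.asarray(values, dtype=float),
            "gfp_positive": None,
            "gfp_margin_positive": None,
        }
    )


def _oracle_percentile(values, q):
    """Independent oracle: explicit sorted linear interpolation,
    rank r = (n-1) q/100, value = x_(floor r) + frac * (x_(floor r + 1) - x_(floor r))."""
    xs = sorted(values)
    r = (len(xs) - 1) * q / 100.0
    lo = int(np.floor(r))
    if lo == len(xs) - 1:
        return xs[-1]
    return xs[lo] + (r - lo) * (xs[lo + 1] - xs[lo])


class TestCalibration:
    def test_degenerate_distribution(self):
        model = calibrate_threshold(_records([100.0] * 500))
        assert model.threshold_value == 100.0

    def test_integers_1_to_1000_give_995_005(self):
        """99.5th percentile of 1..1000 with linear interpolation:
        r = 999 * 0.995 = 994.005 -> 995.005."""
        model = calibrate_threshold(_records(np.arange(1, 1001)))
        assert model.threshold_value == pytest.approx(995.005, abs=1e-9)
        assert model.percentile == 99.5  # the default

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(
        values=st.lists(st.floats(0, 1e4, allow_nan=False), min_size=2, max_size=400),
        q=st.floats(0.5, 100.0),
    )
    def test_percentile_matches_interpolation_oracle(self, values, q):
        assert percentile_linear(np.array(values), q) == pytest.approx(
            _oracle_percentile(values, q), rel=1e-9, abs=1e-9
        )

    def test_threshold_within_wt_range_and_metadata(self):
        rng = np.random.default_rng(42)
        wt = make_wt_records(rng, 1000)
        model = calibrate_threshold(wt)
        assert wt.gfp_median.min() <= model.threshold_value <= wt.gfp_median.max()
        assert model.n_wt_cells == 1000
        assert model.statistic == "median"
        assert set(model.wt_well_ids) == set(wt.well_id.unique())

    def test_too_few_wt_cells_is_calibration_error(self):
        with pytest.raises(CalibrationError):
            calibrate_threshold(_records([1.0] * 100))

    @pytest.mark.parametrize("q", [0.0, -5.0, 120.0])
    def test_percentile_out_of_range(self, q):
        with pytest.raises(ValueError):
            calibrate_threshold(_records([1.0] * 500), percentile=q)


class TestClassification:
    def test_strict_inequality_at_threshold(self):
        model = ThresholdModel(99.5, 100.0, 500)
        rec = classify_cells(_records([100.0, 100.0 + 1e-9, 99.9]), model)
        assert list(rec.gfp_positive) == [False, True, False]

    def test_margin_flag_requires_exceedance_by_margin(self):
        model = ThresholdModel(99.5, 100.0, 500)
        rec = classify_cells(_records([120.0, 151.0]), model, margin_fraction=0.5)
        assert list(rec.gfp_positive) == [True, True]
        assert list(rec.gfp_margin_positive) == [False, True]

    def test_no_records_dropped(self):
        model = ThresholdModel(99.5, 100.0, 500)
        rec = classify_cells(_records(np.linspace(0, 200, 57)), model)
        assert len(rec) == 57
        assert rec.gfp_positive.notna().all()

    def test_held_out_null_rate_matches_design(self):
        """Cells drawn from the calibration distribution exceed the 99.5th
        percentile threshold at ~0.5%, within 3 binomial SDs."""
        rng = np.random.default_rng(314)
        model = calibrate_threshold(make_wt_records(rng, 20_000))
        held_out = make_wt_records(rng, 10_000)
        rec = classify_cells(held_out, model)
        rate = rec.gfp_positive.mean()
        assert abs(rate - 0.005) <= 3 * np.sqrt(0.005 * 0.995 / 10_000)

    def test_self_calibration_respects_design_bound(self):
        """Classifying the calibration set with its own threshold yields a
        positive fraction of at most (100 - percentile)/100 + 1/n."""
        rng = np.random.default_rng(11)
        for percentile in (95.0, 99.5):
            wt = make_wt_records(rng, 5000)
            model = calibrate_threshold(wt, percentile=percentile)
            rate = classify_cells(wt, model).gfp_positive.mean()
            assert rate <= (100.0 - percentile) / 100.0 + 1.0 / len(wt)

    def test_increasing_threshold_never_increases_positives(self):
        rng = np.random.default_rng(7)
        rec = make_wt_records(rng, 2000)
        counts = []
        for thr in np.linspace(100, 800, 15):
            model = ThresholdModel(99.5, thr, 2000)
            counts.append(int(classify_cells(rec, model).gfp_positive.sum()))
        assert counts == sorted(counts, reverse=True)


class TestEfficiency:
    def _classified(self, n_pos, n_total, well="T01"):
        vals = [200.0] * n_pos + [50.0] * (n_total - n_pos)
        rec = classify_cells(_records(vals, well), ThresholdModel(99.5, 100.0, 500))
        return rec

    @pytest.mark.parametrize(
        "n_pos,n_total,expected",
        [(0, 4000, 0.0), (994, 1000, 99.4), (1000, 1000, 100.0)],
    )
    def test_efficiency_percent(self, n_pos, n_total, expected):
        wells = compute_efficiency(self._classified(n_pos, n_total))
        assert wells.iloc[0].efficiency_percent == pytest.approx(expected)
        assert wells.iloc[0].n_cells_total == n_total
        assert wells.iloc[0].n_gfp_positive == n_pos

    def test_zero_cell_well_is_undefined_not_zero(self):
        layout = PlateLayout(
            [
                LayoutRow("T01", "x", "treated", 5),
                LayoutRow("E01", "x", "treated", 5),
                LayoutRow("W01", "wt", "wt_control", 5),
            ]
        )
        wells = compute_efficiency(self._classified(5, 100), layout)
        empty = wells.set_index("well_id").loc["E01"]
        assert empty.n_cells_total == 0
        assert np.isnan(empty.efficiency_percent)

    def test_unclassified_records_rejected(self):
        with pytest.raises(ValueError, match="classified"):
            compute_efficiency(_records([1.0, 2.0]))
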