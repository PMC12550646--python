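"""Shared fixtures: small, fast simulation configs for unit tests.

Unit tests run on 256x256 fields with a few dozen cells; the acceptance
suite uses the full-scale default geometry (1080x1080, ~640 cells/field).
"""

import pytest

from greenseg import CountSpec, LogNormalSpec, RadiusSpec, SimulationConfig


@pytest.fixture
def small_config() -> SimulationConfig:
    """~40 clumped cells on a 256x256 field, defaults otherwise."""
    return SimulationConfig(
        image_height_px=256,
        image_width_px=256,
        cells_per_field=CountSpec(mean=40, dispersion=float("inf")),
        seed=12345,
    )


@pytest.fixture
def sparse_config(small_config) -> SimulationConfig:
    """~20 well-separated cells (no clumping): every cell individually
    resolvable, used when tests need a known one-to-one segmentation."""
    from dataclasses import replace

    return replace(
        small_config,
        cells_per_field=CountSpec(mean=20, dispersion=float("inf")),
        cell_radius_px=RadiusSpec(mean=12.0, sd=2.0, minimum=8.0),
        clumping_fraction=0.0,
        placement_spacing_factor=1.3,
        seed=999,
    )


@pytest.fixture
def mixed_config(small_config) -> SimulationConfig:
    """Half of the cells transformed."""
    from dataclasses import replace

    return replace(small_config, true_positive_fraction=0.5, seed=777)


def make_wt_records(rng, n, loc=5.8, scale=0.3):
    """Synthetic per-cell record table for classification-level tests,
    bypassing imaging: gfp_median drawn from a lognormal null."""
    import numpy as np
    import pandas as pd

    gfp = rng.lognormal(loc, scale, size=n)
    return pd.DataFrame(
        {
            "cell_uid": [f"wt_{i}" for i in range(n)],
            "well_id": np.where(rng.random(n) < 0.5, "W01", "W02"),
            "field_index": rng.integers(0, 5, size=n),
            "label": np.arange(1, n + 1),
            "area_px": 400,
            "centroid_row_px": 0.0,
            "centroid_col_px": 0.0,
            "chl_median": 3000.0,
            "chl_mean": 3000.0,
            "gfp_median": gfp,
            "gfp_mean": gfp * 1.05,
            "gfp_positive": None,
            "gfp_margin_positive": None,
        }
    )
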