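"""Synthetic two-channel fluorescence microscopy fields with ground truth.

Each simulated cell is a radially symmetric soft-edged disk. It contributes
its full amplitude to the chlorophyll channel (all plant cells
autofluoresce) and either a background-level or an expression-level
amplitude to the GFP channel depending on its Bernoulli(p) transformation
status. The camera forward model is: optical blur, Poisson shot noise with
gain, additive Gaussian read noise, constant offset, clipping and
quantization to the configured bit depth.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .config import ConfigError, SimulationConfig
from .io import FieldImage, PlateLayout, write_field

__all__ = [
    "simulate_field",
    "simulate_well",
    "simulate_plate",
    "GROUND_TRUTH_COLUMNS",
]

GROUND_TRUTH_COLUMNS = [
    "cell_uid",
    "well_id",
    "field_index",
    "centroid_row_px",
    "centroid_col_px",
    "radius_px",
    "is_transformed",
    "true_chl_amplitude",
    "true_gfp_amplitude",
]

_EDGE_SOFTNESS_PX = 1.5  # half-width of the soft disk edge
_CLUMP_DISTANCE_FACTOR = 1.8  # clumped neighbor center distance, in radii
_MAX_PLACEMENT_RETRIES = 100


def _place_centers(
    rng: np.random.Generator,
    n_cells: int,
    radii: np.ndarray,
    height: int,
    width: int,
    clumping_fraction: float,
    spacing_factor: float = 1.0,
) -> np.ndarray:
    """Sample cell centers, clumped with probability ``clumping_fraction``.

    A clumped cell is placed in tangent contact (1.8x the pair's mean
    radius) with a random existing cell; otherwise placement is uniform
    with minimal-overlap rejection sampling: the candidate must lie at
    least ``spacing_factor * (r_i + r_j)`` from every placed cell (up to
    100 retries, then the last candidate is accepted anyway).
    """
    centers = np.empty((n_cells, 2), dtype=float)
    margin = 1.0
    for i in range(n_cells):
        r_i = radii[i]
        if i > 0 and rng.random() < clumping_fraction:
            # tangent contact with a random existing cell: 1.8 radii apart
            # for equal-sized cells, scaled by the pair's mean radius. Other
            # cells may touch but not interpenetrate (clumps are grape-like,
            # not nested), hence the same rejection loop over candidates.
            placed = None
            for _ in range(_MAX_PLACEMENT_RETRIES):
                j = int(rng.integers(0, i))
                angle = rng.uniform(0.0, 2.0 * np.pi)
                d = _CLUMP_DISTANCE_FACTOR * 0.5 * (r_i + radii[j])
                cand = centers[j] + d * np.array([np.sin(angle), np.cos(angle)])
                cand[0] = np.clip(cand[0], margin, height - 1 - margin)
                cand[1] = np.clip(cand[1], margin, width - 1 - margin)
                others = np.delete(np.arange(i), j)
                placed = cand
                if others.size == 0:
                    break
                dists = np.hypot(*(centers[others] - cand).T)
                pair = _CLUMP_DISTANCE_FACTOR * 0.5 * (radii[others] + r_i)
                if np.all(dists >= pair - 1e-9):
                    break
            centers[i] = placed
            continue
        placed = None
        for _ in range(_MAX_PLACEMENT_RETRIES):
            cand = np.array(
                [rng.uniform(margin, height - 1 - margin), rng.uniform(margin, width - 1 - margin)]
            )
            if i == 0:
                placed = cand
                break
            dists = np.hypot(*(centers[:i] - cand).T)
            if np.all(dists >= spacing_factor * (radii[:i] + r_i)):
                placed = cand
                break
            placed = cand  # keep the last candidate if all retries overlap
        centers[i] = placed
    return centers


def _render_blobs(
    shape: tuple[int, int],
    centers: np.ndarray,
    radii: np.ndarray,
    amplitudes: np.ndarray,
) -> np.ndarray:
    """Accumulate soft-disk profiles into a float image."""
    img = np.zeros(shape, dtype=np.float64)
    h, w = shape
    for (cy, cx), r, a in zip(centers, radii, amplitudes):
        pad = int(np.ceil(r + 3 * _EDGE_SOFTNESS_PX))
        y0, y1 = max(int(cy) - pad, 0), min(int(cy) + pad + 1, h)
        x0, x1 = max(int(cx) - pad, 0), min(int(cx) + pad + 1, w)
        if y0 >= y1 or x0 >= x1:
            continue
        yy = np.arange(y0, y1, dtype=float) - cy
        xx = np.arange(x0, x1, dtype=float) - cx
        rr = np.hypot(yy[:, None], xx[None, :])
        profile = np.clip((r - rr) / (2.0 * _EDGE_SOFTNESS_PX) + 0.5, 0.0, 1.0)
        img[y0:y1, x0:x1] += a * profile
    return img


def _camera(
    rng: np.random.Generator, noiseless: np.ndarray, config: SimulationConfig
) -> np.ndarray:
    """Apply shot noise, read noise, offset and quantization."""
    gain = config.poisson_scale
    photons = rng.poisson(np.maximum(noiseless, 0.0) / gain)
    signal = photons.astype(np.float64) * gain
    if config.read_noise_sd > 0:
        signal += rng.normal(0.0, config.read_noise_sd, size=signal.shape)
    signal += config.camera_offset
    np.clip(signal, 0, config.max_pixel_value, out=signal)
    dtype = np.uint8 if config.bit_depth == 8 else np.uint16
    return np.rint(signal).astype(dtype)


def simulate_field(
    config: SimulationConfig, field_index: int, well_id: str = "SIM"
) -> tuple[FieldImage, pd.DataFrame]:
    """Simulate one field of view; deterministic given (config, well_id, field_index).

    Returns the rendered two-channel :class:`FieldImage` and the per-cell
    ground-truth table (one row per rendered cell) whose columns are
    :data:`GROUND_TRUTH_COLUMNS`.
    """
    config.validate()
    rng = config.field_rng(well_id, field_index)
    shape = (config.image_height_px, config.image_width_px)

    n_cells = config.cells_per_field.sample(rng)
    radii = config.cell_radius_px.sample(rng, n_cells)
    centers = _place_centers(
        rng,
        n_cells,
        radii,
        shape[0],
        shape[1],
        config.clumping_fraction,
        config.placement_spacing_factor,
    )
    is_transformed = rng.random(n_cells) < config.true_positive_fraction
    chl_amp = config.chl_intensity.sample(rng, n_cells)
    gfp_amp = np.where(
        is_transformed,
        config.gfp_expression.sample(rng, n_cells),
        config.gfp_background.sample(rng, n_cells),
    )
    if n_cells == 0:
        gfp_amp = np.empty(0)

    chl = _render_blobs(shape, centers, radii, chl_amp)
    gfp = _render_blobs(shape, centers, radii, gfp_amp)
    if config.blur_sigma_px > 0:
        chl = ndi.gaussian_filter(chl, config.blur_sigma_px)
        gfp = ndi.gaussian_filter(gfp, config.blur_sigma_px)

    field = FieldImage(
        well_id=well_id,
        field_index=field_index,
        chl=_camera(rng, chl, config),
        gfp=_camera(rng, gfp, config),
        bit_depth=config.bit_depth,
    )
    truth = pd.DataFrame(
        {
            "cell_uid": [f"{well_id}_{field_index:02d}_{i:04d}" for i in range(n_cells)],
            "well_id": well_id,
            "field_index": field_index,
            "centroid_row_px": centers[:, 0] if n_cells else np.empty(0),
            "centroid_col_px": centers[:, 1] if n_cells else np.empty(0),
            "radius_px": radii,
            "is_transformed": is_transformed,
            "true_chl_amplitude": chl_amp,
            "true_gfp_amplitude": gfp_amp,
        },
        columns=GROUND_TRUTH_COLUMNS,
    )
    return field, truth


def simulate_well(
    config: SimulationConfig, n_fields: int, well_id: str
) -> tuple[list[FieldImage], pd.DataFrame]:
    """Simulate ``n_fields`` independent fields of one well.

    Mirrors the acquisition geometry of the assay: 5-6 fields cover a
    96-well, 15 random fields sample a 12-well. Ground truth is
    concatenated with field provenance.
    """
    if n_fields < 1:
        raise ValueError("n_fields must be >= 1")
    fields: list[FieldImage] = []
    truths: list[pd.DataFrame] = []
    for k in range(n_fields):
        f, t = simulate_field(config, k, well_id=well_id)
        fields.append(f)
        truths.append(t)
    truth = pd.concat(truths, ignore_index=True) if truths else pd.DataFrame(
        columns=GROUND_TRUTH_COLUMNS
    )
    return fields, truth


def simulate_plate(
    layout: PlateLayout,
    scenario: dict[str, SimulationConfig],
    output_dir: str | Path,
) -> dict:
    """Simulate every non-blank well of a plate and write it to disk.

    Writes one grayscale TIFF per field per channel
    (``{well}_{field:02d}_{channel}.tif``), a pooled ground-truth CSV and a
    JSON manifest binding files to wells/fields/channels. Wild-type control
    wells must be present (the downstream threshold cannot be calibrated
    without them) and must simulate a transformation rate of exactly zero.
    """
    layout.validate(require_control=True)
    output_dir = Path(output_dir)
    output_dir.mkdir(parents=True, exist_ok=True)

    for row in layout.rows:
        if row.role == "blank":
            continue
        if row.condition not in scenario:
            raise ConfigError(f"no simulation config for condition {row.condition!r}")
        cfg = scenario[row.condition]
        if row.role == "wt_control" and cfg.true_positive_fraction != 0.0:
            raise ConfigError(
                f"WT control condition {row.condition!r} must have "
                "true_positive_fraction = 0"
            )

    manifest: dict = {"wells": {}}
    truths: list[pd.DataFrame] = []
    for row in layout.rows:
        if row.role == "blank":
            continue
        cfg = scenario[row.condition]
        fields, truth = simulate_well(cfg, row.n_fields, row.well_id)
        truths.append(truth)
        entries = []
        for f in fields:
            paths = write_field(f, output_dir)
            entries.append(
                {
                    "field_index": f.field_index,
                    "chl": paths["chl"].name,
                    "gfp": paths["gfp"].name,
                }
            )
        manifest["wells"][row.well_id] = {
            "condition": row.condition,
            "role": row.role,
            "fields": entries,
        }

    truth_all = pd.concat(truths, ignore_index=True) if truths else pd.DataFrame(
        columns=GROUND_TRUTH_COLUMNS
    )
    truth_all.to_csv(output_dir / "ground_truth.csv", index=False)
    manifest["ground_truth"] = "ground_truth.csv"
    with open(output_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
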