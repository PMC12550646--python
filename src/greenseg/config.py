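"""Simulation configuration for synthetic two-channel field images.

The simulator emulates fields of green *Arabidopsis thaliana* suspension
cells imaged on an automated high-content screening microscope: every cell
is bright in the chlorophyll-autofluorescence channel (~690 nm emission),
while only transformed cells are bright in the GFP channel (~540 nm
emission); untransformed cells show a low intrinsic GFP-channel background.

All per-cell brightness distributions are lognormal, which matches the
right-skewed intensity histograms typical of fluorescence reporters.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "LogNormalSpec",
    "RadiusSpec",
    "CountSpec",
    "SimulationConfig",
    "ConfigError",
]


class ConfigError(ValueError):
    """Raised when a simulation configuration violates its invariants."""


@dataclass(frozen=True)
class LogNormalSpec:
    """Lognormal distribution of a per-cell fluorescence amplitude.

    Parameters are on the log scale: ``exp(mean_log)`` is the median
    amplitude in camera intensity units, ``sd_log`` the geometric spread.
    ``upper`` optionally truncates the distribution from above by rejection
    sampling, which is used to model background populations guaranteed to
    stay below a known intensity.
    """

    mean_log: float
    sd_log: float
    upper: float | None = None

    def validate(self, name: str) -> None:
        if not np.isfinite(self.mean_log):
            raise ConfigError(f"{name}.mean_log must be finite")
        if not (self.sd_log > 0):
            raise ConfigError(f"{name}.sd_log must be strictly positive")
        if self.upper is not None and self.upper <= 0:
            raise ConfigError(f"{name}.upper must be positive when set")

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        x = rng.lognormal(self.mean_log, self.sd_log, size=n)
        if self.upper is not None:
            over = x > self.upper
            while np.any(over):
                x[over] = rng.lognormal(self.mean_log, self.sd_log, size=int(over.sum()))
                over = x > self.upper
        return x


@dataclass(frozen=True)
class RadiusSpec:
    """Cell radius distribution in pixels: truncated normal(mean, sd) >= minimum."""

    mean: float = 12.0
    sd: float = 2.5
    minimum: float = 5.0

    def validate(self, name: str) -> None:
        if self.mean <= 0 or self.sd < 0 or self.minimum <= 0:
            raise ConfigError(f"{name} parameters must be positive")
        if self.minimum > self.mean:
            raise ConfigError(f"{name}.minimum must not exceed the mean")

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        return np.maximum(rng.normal(self.mean, self.sd, size=n), self.minimum)


@dataclass(frozen=True)
class CountSpec:
    """Cells-per-field distribution.

    Negative binomial with the given mean and dispersion ``k``
    (variance = mean + mean^2 / k); ``k = inf`` degenerates to Poisson.
    Over-dispersion mimics well-to-well variation in culture density.
    """

    mean: float = 640.0
    dispersion: float = 8.0

    def __post_init__(self) -> None:
        # YAML configs may spell dispersion as the string "inf"
        object.__setattr__(self, "mean", float(self.mean))
        object.__setattr__(self, "dispersion", float(self.dispersion))

    def validate(self, name: str) -> None:
        if self.mean < 0:
            raise ConfigError(f"{name}.mean must be nonnegative")
        if not (self.dispersion > 0):
            raise ConfigError(f"{name}.dispersion must be strictly positive")

    def sample(self, rng: np.random.Generator) -> int:
        if self.mean == 0:
            return 0
        if np.isinf(self.dispersion):
            return int(rng.poisson(self.mean))
        k = self.dispersion
        p = k / (k + self.mean)
        return int(rng.negative_binomial(k, p))


@dataclass(frozen=True)
class SimulationConfig:
    """Full parameterization of a simulated acquisition condition.

    Defaults reproduce the study geometry: 1080x1080 px 16-bit fields with
    on the order of 640 cells each, so that a well covered by 5 fields
    holds roughly 3,200 cells. ``true_positive_fraction`` is the simulated
    transformation rate p that the downstream analysis estimates.
    """

    image_height_px: int = 1080
    image_width_px: int = 1080
    cells_per_field: CountSpec = field(default_factory=CountSpec)
    cell_radius_px: RadiusSpec = field(default_factory=RadiusSpec)
    clumping_fraction: float = 0.3
    chl_intensity: LogNormalSpec = field(
        default_factory=lambda: LogNormalSpec(mean_log=8.0, sd_log=0.4)
    )
    gfp_background: LogNormalSpec = field(
        default_factory=lambda: LogNormalSpec(mean_log=5.0, sd_log=0.35)
    )
    gfp_expression: LogNormalSpec = field(
        default_factory=lambda: LogNormalSpec(mean_log=8.0, sd_log=0.5)
    )
    true_positive_fraction: float = 0.0
    placement_spacing_factor: float = 1.0
    blur_sigma_px: float = 1.5
    poisson_scale: float = 2.0
    read_noise_sd: float = 3.0
    camera_offset: float = 100.0
    bit_depth: int = 16
    seed: int = 0

    def validate(self) -> None:
        if self.image_height_px <= 0 or self.image_width_px <= 0:
            raise ConfigError("image dimensions must be positive")
        self.cells_per_field.validate("cells_per_field")
        self.cell_radius_px.validate("cell_radius_px")
        if not (0.0 <= self.clumping_fraction <= 1.0):
            raise ConfigError("clumping_fraction must lie in [0, 1]")
        self.chl_intensity.validate("chl_intensity")
        self.gfp_background.validate("gfp_background")
        self.gfp_expression.validate("gfp_expression")
        if not (0.0 <= self.true_positive_fraction <= 1.0):
            raise ConfigError("true_positive_fraction must lie in [0, 1]")
        if self.placement_spacing_factor < 1.0:
            raise ConfigError("placement_spacing_factor must be >= 1")
        if self.blur_sigma_px < 0:
            raise ConfigError("blur_sigma_px must be nonnegative")
        if not (self.poisson_scale > 0):
            raise ConfigError("poisson_scale must be strictly positive")
        if self.read_noise_sd < 0:
            raise ConfigError("read_noise_sd must be nonnegative")
        if self.camera_offset < 0:
            raise ConfigError("camera_offset must be nonnegative")
        if self.bit_depth not in (8, 16):
            raise ConfigError("bit_depth must be 8 or 16")

    def validate_separable(self) -> None:
        """Additionally require the GFP expression and background
        distributions to be separable (expression log-mean above the
        background log-mean), as assumed by threshold-based positivity."""
        self.validate()
        if not (self.gfp_expression.mean_log > self.gfp_background.mean_log):
            raise ConfigError(
                "gfp_expression.mean_log must exceed gfp_background.mean_log "
                "for a separable scenario"
            )

    @property
    def max_pixel_value(self) -> int:
        return 2 ** self.bit_depth - 1

    def field_rng(self, well_id: str, field_index: int) -> np.random.Generator:
        """Deterministic per-field generator.

        Seeds are derived hierarchically plate -> well -> field by feeding
        (config seed, CRC-32 of the well id, field index) into a
        SeedSequence, so fields are mutually independent yet reproducible.
        """
        well_hash = zlib.crc32(str(well_id).encode("utf-8"))
        ss = np.random.SeedSequence([int(self.seed) & 0x7FFFFFFF, well_hash, int(field_index)])
        return np.random.default_rng(ss)
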