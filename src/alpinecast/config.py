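"""Configuration objects for the synthetic landscape and the pipeline.

Every stochastic stage takes an explicit seed; a single pipeline seed is
expanded deterministically into per-stage seeds (see :mod:`alpinecast.pipeline`).
All configs round-trip losslessly through ``to_dict``/``from_dict`` and hence
through YAML/JSON.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Any

import numpy as np

from .geometry import ConfigurationError, n_cells

__all__ = [
    "LandscapeConfig",
    "TrueResponseParams",
    "SnowModelParams",
    "DailySynthesisConfig",
    "RunConfig",
]

# Sea-level monthly climatology defaults: a cool-temperate, winter-wet maritime
# profile (deep-snow mountain front). Means in deg C, precip in mm/month.
DEFAULT_SEA_LEVEL_MONTHLY_MEANS = (2.0, 3.0, 7.0, 13.0, 18.0, 21.0, 25.0, 26.0,
                                   22.0, 16.0, 10.0, 5.0)
DEFAULT_SEA_LEVEL_MONTHLY_MINS = tuple(t - 6.0 for t in DEFAULT_SEA_LEVEL_MONTHLY_MEANS)
DEFAULT_MONTHLY_PRECIP_MEANS = (90.0, 90.0, 110.0, 110.0, 120.0, 150.0,
                                180.0, 160.0, 170.0, 120.0, 90.0, 90.0)


@dataclass
class LandscapeConfig:
    """Geometry and physical parameters of the synthetic alpine landscape.

    The default domain is a 12 km x 18 km mountain block with a 100-m terrain
    lattice, 1-km climate lattice and 300-m territory lattice — the same nested
    structure as a real alpine survey region, scaled to run quickly.
    """

    domain_width_m: float = 12_000.0
    domain_height_m: float = 18_000.0
    terrain_resolution_m: float = 100.0
    climate_resolution_m: float = 1_000.0
    territory_resolution_m: float = 300.0
    ruggedness: float = 1.0
    peak_elevation_m: float = 3_000.0
    lapse_rate_c_per_km: float = 6.0
    seed: int = 0

    def __post_init__(self) -> None:
        for res in (self.terrain_resolution_m, self.climate_resolution_m,
                    self.territory_resolution_m):
            n_cells(self.domain_width_m, self.domain_height_m, res)  # raises if bad
        ratio = self.territory_resolution_m / self.terrain_resolution_m
        if abs(ratio - round(ratio)) > 1e-9:
            raise ConfigurationError(
                "territory resolution must be an integer multiple of terrain resolution"
            )
        ratio = self.climate_resolution_m / self.terrain_resolution_m
        if abs(ratio - round(ratio)) > 1e-9:
            raise ConfigurationError(
                "climate resolution must be an integer multiple of terrain resolution"
            )
        if self.ruggedness < 0:
            raise ConfigurationError("ruggedness must be nonnegative")
        if self.peak_elevation_m <= 0:
            raise ConfigurationError("peak elevation must be positive")

    @property
    def terrain_shape(self) -> tuple[int, int]:
        return (int(round(self.domain_height_m / self.terrain_resolution_m)),
                int(round(self.domain_width_m / self.terrain_resolution_m)))

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "LandscapeConfig":
        return cls(**d)


@dataclass
class TrueResponseParams:
    """Ground-truth response functions of the synthetic ecosystem.

    zone: per-survey-free logistic response of alpine-zone suitability to the
    four bioclimatic variables, ``logit s = b_wi*(wi_center - WI) +
    b_msw*(MSW - msw_center) + b_prs*(PRS - prs_center) + b_tmc*(tmc_center - TMC)``.
    The warmth-index term dominates: alpine vegetation sits below a heat-sum
    ceiling (the classical alpine limit is near WI = 15 deg C month).

    fractions: community cover at a fine cell is suitability-gated terrain
    response — stone-pine scrub hugs the ridge (decay length ``pp_decay_m``),
    fellfield is confined still closer to wind-exposed ridge tops, snowbed
    grassland follows moisture accumulation (TWI). A hard establishment gate
    zeroes cover where suitability < ``zone_gate``.

    habitat: per-survey territory probability, logistic in the three community
    fractions and ridge distance.
    """

    # zone response (on WI in deg C month, MSW/PRS in mm, TMC in deg C)
    wi_center: float = 15.0
    b_wi: float = 1.2
    msw_center: float = 300.0
    b_msw: float = 0.004
    prs_center: float = 1000.0
    b_prs: float = 0.001
    tmc_center: float = -8.0
    b_tmc: float = 0.1
    zone_gate: float = 0.05

    # fraction responses
    pp_max: float = 0.6
    pp_decay_m: float = 400.0
    ff_max: float = 0.3
    ff_decay_m: float = 150.0
    sg_max: float = 0.35
    sg_twi_center: float = 6.0
    sg_twi_scale: float = 1.5
    fraction_cap: float = 0.95
    noise_sd: float = 0.05

    # habitat response (territory scale): occurrence is essentially nil away
    # from alpine vegetation (logit intercept -6), rises steeply with
    # stone-pine cover and falls with distance from the ridgeline
    hab_intercept: float = -6.0
    hab_b_pp: float = 10.0
    hab_b_sg: float = 5.0
    hab_b_ff: float = 5.0
    hab_b_dr_per_m: float = -0.004

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "TrueResponseParams":
        return cls(**d)


@dataclass
class SnowModelParams:
    """Degree-day snowpack parameters.

    rain_snow_threshold_c: daily precipitation falls as snow below this air
    temperature (deg C). degree_day_factor: melt per positive degree-day
    (mm water equivalent / deg C / day). melt_base_temp_c: temperature above
    which melt begins (deg C). Mid-range values from standard degree-day
    snow hydrology.
    """

    rain_snow_threshold_c: float = 2.0
    degree_day_factor: float = 4.0
    melt_base_temp_c: float = 0.0

    def __post_init__(self) -> None:
        if self.degree_day_factor <= 0:
            raise ConfigurationError("degree_day_factor must be positive")

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "SnowModelParams":
        return cls(**d)


@dataclass
class DailySynthesisConfig:
    """How daily weather is synthesized from monthly climatology.

    The annual temperature cycle is the exact trigonometric interpolant of the
    12 monthly values placed at month midpoints, plus seeded Gaussian
    day-to-day noise. Precipitation days are drawn with a fixed wet-day
    frequency; each month's total is split evenly over its wet days, so a
    multiplicative change in monthly totals scales daily amounts exactly.
    The hydrological year runs 1 September - 31 August (365 days) so a single
    winter snowpack is contiguous.
    """

    temp_noise_sd_c: float = 2.0
    wet_day_frequency: float = 0.4
    seed: int = 0

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "DailySynthesisConfig":
        return cls(**d)


@dataclass
class RunConfig:
    """Top-level pipeline configuration (serializes to YAML/JSON)."""

    landscape: LandscapeConfig = field(default_factory=LandscapeConfig)
    truth: TrueResponseParams = field(default_factory=TrueResponseParams)
    snow: SnowModelParams = field(default_factory=SnowModelParams)
    daily: DailySynthesisConfig = field(default_factory=DailySynthesisConfig)
    n_scenarios: int = 24
    warming_range_c: tuple[float, float] = (2.5, 6.0)
    precip_ratio_range: tuple[float, float] = (0.9, 1.25)
    scenario_lattice: tuple[int, int] = (4, 3)
    n_trees: int = 500
    sensitivity_cutoff: float = 0.95
    n_bootstrap: int = 100
    ridge_threshold_quantile: float = 0.99
    zone_cover_threshold: float = 0.0
    seed: int = 1
    output_dir: str = "runs/default"

    def to_dict(self) -> dict[str, Any]:
        d = asdict(self)
        d["warming_range_c"] = list(self.warming_range_c)
        d["precip_ratio_range"] = list(self.precip_ratio_range)
        d["scenario_lattice"] = list(self.scenario_lattice)
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "RunConfig":
        d = dict(d)
        for key, sub in (("landscape", LandscapeConfig), ("truth", TrueResponseParams),
                         ("snow", SnowModelParams), ("daily", DailySynthesisConfig)):
            if key in d and isinstance(d[key], dict):
                d[key] = sub.from_dict(d[key])
        for key in ("warming_range_c", "precip_ratio_range", "scenario_lattice"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


def spawn_seed(base_seed: int, *keys: int) -> int:
    """Derive a reproducible sub-stream seed below 2**31 from a base seed."""
    ss = np.random.SeedSequence([int(base_seed), *[int(k) for k in keys]])
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))
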