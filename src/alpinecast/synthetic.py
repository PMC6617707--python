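"""Synthetic alpine landscapes with known generative structure.

Every downstream stage of the cascade is exercised on landscapes generated
here, so each generator has a recoverable ground truth: the DEM has a known
central ridge spine, climate follows a known lapse rate, the alpine-zone
suitability and community fractions are known smooth responses, and territory
presences are Bernoulli draws from a known habitat model thinned by survey
effort. All generators are fully deterministic given their seed.

What this emulates — and what it does not — is documented in
``docs/methods.md``: the landscape is a single smooth mountain block, not a
topographic or climatic replica of any real range.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.special import expit

from .climate import BioclimGrid, ClimateGrid, GcmScenario
from .config import (DEFAULT_MONTHLY_PRECIP_MEANS, DEFAULT_SEA_LEVEL_MONTHLY_MEANS,
                     DEFAULT_SEA_LEVEL_MONTHLY_MINS, LandscapeConfig,
                     TrueResponseParams, spawn_seed)
from .geometry import (ConfigurationError, GridGeometry, block_mean,
                       upsample_nearest)
from .habitat import TerritoryObservations, aggregate_predictors
from .terrain import TerrainGrid

__all__ = [
    "VegetationMap",
    "generate_dem",
    "generate_climatology",
    "generate_gcm_anomalies",
    "true_zone_suitability",
    "generate_vegetation",
    "true_habitat_probability",
    "draw_survey_counts",
    "generate_territories",
]


@dataclass
class VegetationMap:
    """Per-fine-cell area fractions of the three alpine communities.

    ``pp``: stone-pine scrub, ``sg``: snowbed grassland, ``ff``: fellfield.
    Fractions lie in [0,1] and sum to at most 1 per cell.
    """

    pp: np.ndarray
    sg: np.ndarray
    ff: np.ndarray
    geom: GridGeometry

    def __post_init__(self) -> None:
        for name in ("pp", "sg", "ff"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if ((arr < -1e-6) | (arr > 1 + 1e-6)).any():
                raise ValueError(f"fraction {name} outside [0,1]")
            setattr(self, name, arr)
        if (self.total() > 1 + 1e-6).any():
            raise ValueError("community fractions sum above 1")

    def total(self) -> np.ndarray:
        return self.pp + self.sg + self.ff

    def as_dict(self) -> dict[str, np.ndarray]:
        return {"pp": self.pp, "sg": self.sg, "ff": self.ff}


def generate_dem(config: LandscapeConfig) -> tuple[np.ndarray, GridGeometry]:
    """Generate a DEM: a meandering central ridge spine plus smoothed random relief.

    The spine is a locus of local maxima running the length of the domain, so
    ridge extraction has a known answer. ``ruggedness`` scales the whole
    relief; 0 gives a flat (zero-elevation) grid. Deterministic given
    ``config.seed``; elevations lie in [0, peak_elevation_m] with the maximum
    at 95% of the peak for ruggedness 1.
    """
    nrows, ncols = config.terrain_shape
    geom = GridGeometry(nrows, ncols, config.terrain_resolution_m)
    rows = np.arange(nrows)[:, None]
    cols = np.arange(ncols)[None, :]
    # meandering north-south spine
    spine_col = ncols / 2.0 + 0.15 * ncols * np.sin(2.0 * np.pi * 1.5 * rows / nrows)
    dist_cells = np.abs(cols - spine_col)
    sigma_cells = 0.25 * ncols
    profile = np.exp(-0.5 * (dist_cells / sigma_cells) ** 2)
    # along-ridge undulation: the crest has summits and cols, and parts of
    # the ridgeline dip below the alpine zone as on a real massif
    profile = profile * (0.75 + 0.25 * np.cos(2.0 * np.pi * 2.0 * rows / nrows))
    rng = np.random.default_rng(spawn_seed(config.seed, nrows, ncols))
    field = gaussian_filter(rng.standard_normal((nrows, ncols)), sigma=6.0,
                            mode="reflect")
    field = (field - field.min()) / max(field.max() - field.min(), 1e-12)
    relief = 0.85 * profile + 0.15 * field
    relief = relief / relief.max()
    elevation = np.clip(config.ruggedness * 0.95 * config.peak_elevation_m * relief,
                        0.0, config.peak_elevation_m)
    return elevation, geom


def generate_climatology(dem: np.ndarray, config: LandscapeConfig,
                         sea_level_monthly_means=DEFAULT_SEA_LEVEL_MONTHLY_MEANS,
                         sea_level_monthly_mins=DEFAULT_SEA_LEVEL_MONTHLY_MINS,
                         monthly_precip_means=DEFAULT_MONTHLY_PRECIP_MEANS,
                         temp_noise_sd: float = 0.3,
                         precip_noise_cv: float = 0.25,
                         orographic_factor_per_km: float = 0.3) -> ClimateGrid:
    """Monthly climatology on the coarse lattice from lapse-rate physics.

    Elevation is block-averaged to the climate lattice; monthly mean
    temperature is the sea-level value minus ``lapse_rate * elevation_km``
    plus seeded noise, minimums likewise (clipped to stay at or below means),
    and precipitation scales with elevation by the orographic factor.
    """
    means = np.asarray(sea_level_monthly_means, dtype=float)
    mins = np.asarray(sea_level_monthly_mins, dtype=float)
    precip = np.asarray(monthly_precip_means, dtype=float)
    if means.shape != (12,) or mins.shape != (12,) or precip.shape != (12,):
        raise ValueError("sea-level climatology needs 12 monthly values")
    fine_geom = GridGeometry(*dem.shape, config.terrain_resolution_m)
    factor = int(round(config.climate_resolution_m / config.terrain_resolution_m))
    elev_km = block_mean(dem, factor) / 1000.0
    geom = fine_geom.coarsen(factor)
    rng = np.random.default_rng(spawn_seed(config.seed, 12, *elev_km.shape))
    lapse = config.lapse_rate_c_per_km
    t_mean = (means[:, None, None] - lapse * elev_km[None]
              + rng.normal(0.0, temp_noise_sd, size=(12, *elev_km.shape)))
    t_min = (mins[:, None, None] - lapse * elev_km[None]
             + rng.normal(0.0, temp_noise_sd, size=(12, *elev_km.shape)))
    t_min = np.minimum(t_min, t_mean)
    p = (precip[:, None, None] * (1.0 + orographic_factor_per_km * elev_km[None])
         * (1.0 + rng.normal(0.0, precip_noise_cv, size=(12, *elev_km.shape))))
    p = np.clip(p, 0.0, None)
    return ClimateGrid(t_mean, t_min, p, geom)


def generate_gcm_anomalies(n_scenarios: int,
                           warming_range: tuple[float, float] = (2.5, 6.0),
                           precip_ratio_range: tuple[float, float] = (0.9, 1.25),
                           lattice: tuple[int, int] = (4, 3),
                           domain_width_m: float = 12_000.0,
                           domain_height_m: float = 18_000.0,
                           seed: int = 0) -> list[GcmScenario]:
    """Draw an ensemble of climate-model anomaly fields.

    Scenario-mean warmings are spread evenly across ``warming_range`` (so the
    ensemble spans the stated uncertainty) with smooth spatial variation on a
    coarse lattice; minimum-temperature deltas track the mean deltas with a
    small perturbation; precipitation ratios are drawn within
    ``precip_ratio_range``. Every field value stays inside its stated range.
    """
    if n_scenarios < 1:
        raise ConfigurationError("n_scenarios must be >= 1")
    w_lo, w_hi = warming_range
    r_lo, r_hi = precip_ratio_range
    nrows, ncols = lattice
    geom = GridGeometry(nrows, ncols, domain_width_m / ncols)
    if abs(geom.height_m - domain_height_m) > 1e-6:
        geom = GridGeometry(nrows, ncols, max(domain_width_m / ncols,
                                              domain_height_m / nrows))
    rng = np.random.default_rng(spawn_seed(seed, n_scenarios, nrows, ncols))
    if n_scenarios == 1:
        bases = np.array([(w_lo + w_hi) / 2.0])
    else:
        bases = np.linspace(w_lo, w_hi, n_scenarios)
    spatial_amp = 0.1 * (w_hi - w_lo)
    scenarios = []
    for i in range(n_scenarios):
        d_mean = bases[i] + rng.normal(0.0, spatial_amp, size=(nrows, ncols))
        d_mean = np.clip(d_mean, w_lo, w_hi)
        d_min = np.clip(d_mean + rng.normal(0.0, 0.5 * spatial_amp + 1e-9,
                                            size=(nrows, ncols)), w_lo, w_hi)
        base_r = rng.uniform(r_lo, r_hi)
        ratio = np.clip(base_r + rng.normal(0.0, 0.05 * (r_hi - r_lo) + 1e-12,
                                            size=(nrows, ncols)), r_lo, r_hi)
        scenarios.append(GcmScenario(name=f"GCM-{i + 1:02d}",
                                     temp_delta_mean=d_mean, temp_delta_min=d_min,
                                     precip_ratio=ratio, geom=geom))
    return scenarios


def true_zone_suitability(bioclim: BioclimGrid,
                          truth: TrueResponseParams) -> np.ndarray:
    """Ground-truth alpine-zone suitability from the planted logistic response.

    Suitability declines steeply with the warmth index above the alpine heat
    ceiling and rises with snowpack; an establishment gate zeroes suitability
    below ``truth.zone_gate``.
    """
    eta = (truth.b_wi * (truth.wi_center - bioclim.wi)
           + truth.b_msw * (bioclim.msw - truth.msw_center)
           + truth.b_prs * (bioclim.prs - truth.prs_center)
           + truth.b_tmc * (truth.tmc_center - bioclim.tmc))
    s = expit(eta)
    return np.where(s >= truth.zone_gate, s, 0.0)


def _terrain_fraction_responses(terrain: TerrainGrid, truth: TrueResponseParams
                                ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Terrain-only community responses, jointly capped so they sum below 1."""
    dr = terrain.ridge_distance
    twi = terrain.twi
    twi_fill = np.nanmedian(twi)
    twi = np.where(np.isnan(twi), twi_fill, twi)
    g_pp = truth.pp_max * np.exp(-dr / truth.pp_decay_m)
    g_ff = truth.ff_max * np.exp(-dr / truth.ff_decay_m)
    g_sg = truth.sg_max * expit((twi - truth.sg_twi_center) / truth.sg_twi_scale)
    total = g_pp + g_ff + g_sg
    scale = np.minimum(1.0, truth.fraction_cap / np.maximum(total, 1e-12))
    return g_pp * scale, g_sg * scale, g_ff * scale


def true_fractions(bioclim: BioclimGrid, terrain: TerrainGrid,
                   truth: TrueResponseParams) -> VegetationMap:
    """Noise-free ground-truth community fractions on the fine lattice."""
    s_coarse = true_zone_suitability(bioclim, truth)
    factor = terrain.geom.factor_to(bioclim.geom)
    s_fine = upsample_nearest(s_coarse, factor)
    g_pp, g_sg, g_ff = _terrain_fraction_responses(terrain, truth)
    return VegetationMap(pp=s_fine * g_pp, sg=s_fine * g_sg, ff=s_fine * g_ff,
                         geom=terrain.geom)


def generate_vegetation(bioclim: BioclimGrid, terrain: TerrainGrid,
                        truth: TrueResponseParams, seed: int = 0) -> VegetationMap:
    """Community fractions = true responses plus truncated Gaussian noise.

    Noise is added on the pre-gating latent scale (so unsuitable cells stay at
    exactly zero), each fraction is truncated to [0,1], and any cell whose
    fractions sum above 1 is rescaled proportionally.
    """
    s_coarse = true_zone_suitability(bioclim, truth)
    factor = terrain.geom.factor_to(bioclim.geom)
    s_fine = upsample_nearest(s_coarse, factor)
    g_pp, g_sg, g_ff = _terrain_fraction_responses(terrain, truth)
    rng = np.random.default_rng(spawn_seed(seed, *terrain.geom.shape))
    out = []
    for g in (g_pp, g_sg, g_ff):
        eps = rng.normal(0.0, truth.noise_sd, size=g.shape) if truth.noise_sd > 0 \
            else 0.0
        out.append(np.clip(s_fine * (g + eps), 0.0, 1.0))
    total = out[0] + out[1] + out[2]
    over = total > 1.0
    if over.any():
        scale = np.where(over, 1.0 / np.maximum(total, 1e-12), 1.0)
        out = [f * scale for f in out]
    return VegetationMap(pp=out[0], sg=out[1], ff=out[2], geom=terrain.geom)


def true_habitat_probability(af_pp, af_sg, af_ff, dr_m,
                             truth: TrueResponseParams) -> np.ndarray:
    """Ground-truth per-survey territory probability."""
    eta = (truth.hab_intercept + truth.hab_b_pp * np.asarray(af_pp)
           + truth.hab_b_sg * np.asarray(af_sg)
           + truth.hab_b_ff * np.asarray(af_ff)
           + truth.hab_b_dr_per_m * np.asarray(dr_m))
    return expit(eta)


def draw_survey_counts(territory_geom: GridGeometry, seed: int = 0,
                       low: int = 1, high: int = 4) -> np.ndarray:
    """Seeded survey-effort counts, uniform integers on [low, high]."""
    rng = np.random.default_rng(spawn_seed(seed, *territory_geom.shape, 7))
    return rng.integers(low, high + 1, size=territory_geom.shape)


def generate_territories(vegetation: VegetationMap, terrain: TerrainGrid,
                         truth: TrueResponseParams,
                         surveys_per_cell: np.ndarray | int,
                         territory_resolution_m: float = 300.0,
                         seed: int = 0) -> TerritoryObservations:
    """Bernoulli territory observations thinned by survey effort.

    A cell surveyed ``n`` times is observed present with probability
    ``1 - (1 - p_true)^n`` where ``p_true`` is the ground-truth per-survey
    probability from the aggregated fractions and ridge distance — the
    complementary-log construction that a log-effort offset identifies at fit
    time. Cells with zero surveys are excluded; negative counts are invalid.
    """
    factor = int(round(territory_resolution_m / terrain.geom.cell_size_m))
    territory_geom = terrain.geom.coarsen(factor)
    surveys = np.broadcast_to(np.asarray(surveys_per_cell, dtype=int),
                              territory_geom.shape).copy()
    if (surveys < 0).any():
        raise ValueError("survey counts must be nonnegative")
    table = aggregate_predictors(vegetation.as_dict(), terrain.ridge_distance,
                                 terrain.geom, territory_geom)
    p_true = true_habitat_probability(table["AF_Pp"], table["AF_Sg"],
                                      table["AF_Ff"], table["DR_m"], truth)
    n = surveys.ravel()
    p_obs = 1.0 - (1.0 - p_true) ** n
    rng = np.random.default_rng(spawn_seed(seed, *territory_geom.shape, 13))
    presence = (rng.random(len(p_obs)) < p_obs).astype(int)
    table["presence"] = presence
    table["n_surveys"] = n
    table["p_true"] = p_true
    table = table[n > 0].reset_index(drop=True)
    return TerritoryObservations(table=table, geom=territory_geom)
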