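"""Bioclimatic variables and delta-method scenario downscaling.

Four bioclimatic variables drive the vegetation-zone model:

* **WI** (warmth index, deg C month): annual sum of positive monthly-mean
  excesses over +5 deg C — a heat-sum measure of growing conditions.
* **TMC** (deg C): monthly mean daily minimum temperature of the coldest
  month — an extreme-cold measure.
* **PRS** (mm): May-September precipitation — growing-season water supply.
* **MSW** (mm water equivalent): annual maximum of a degree-day snowpack
  simulation driven by synthesized daily weather.

Future climatologies are built by the delta method: additive temperature
anomalies and multiplicative precipitation ratios from a coarse climate-model
lattice are bilinearly interpolated to the baseline lattice and applied to the
observed climatology.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import DailySynthesisConfig, SnowModelParams, spawn_seed
from .geometry import GridGeometry

__all__ = [
    "ClimateGrid",
    "BioclimGrid",
    "GcmScenario",
    "warmth_index",
    "min_temp_coldest_month",
    "summer_precipitation",
    "simulate_snowpack",
    "synthesize_daily_weather",
    "apply_gcm_delta",
    "compute_bioclim",
]

# Hydrological year: 1 September - 31 August (365 days), so one winter pack is
# contiguous. Calendar month of each hydro-month and its length in days.
HYDRO_MONTHS = np.array([9, 10, 11, 12, 1, 2, 3, 4, 5, 6, 7, 8])
MONTH_LENGTHS = {1: 31, 2: 28, 3: 31, 4: 30, 5: 31, 6: 30,
                 7: 31, 8: 31, 9: 30, 10: 31, 11: 30, 12: 31}
N_DAYS = 365


@dataclass
class ClimateGrid:
    """Monthly climatology on the coarse climate lattice.

    Arrays are shaped ``(12, nrows, ncols)``; month index 0 is January.
    """

    monthly_mean_temp: np.ndarray
    monthly_min_temp: np.ndarray
    monthly_precip: np.ndarray
    geom: GridGeometry

    def __post_init__(self) -> None:
        for name in ("monthly_mean_temp", "monthly_min_temp", "monthly_precip"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (12, *self.geom.shape):
                raise ValueError(f"{name} must have shape (12, nrows, ncols)")
            setattr(self, name, arr)
        if np.any(self.monthly_min_temp > self.monthly_mean_temp + 1e-9):
            raise ValueError("monthly minimum temperature exceeds monthly mean")
        if np.any(self.monthly_precip < 0):
            raise ValueError("negative precipitation")


@dataclass
class BioclimGrid:
    """The four bioclimatic variables per climate cell."""

    wi: np.ndarray
    tmc: np.ndarray
    prs: np.ndarray
    msw: np.ndarray
    geom: GridGeometry

    def stack(self) -> np.ndarray:
        """(4, nrows, ncols) array in the order WI, TMC, PRS, MSW."""
        return np.stack([self.wi, self.tmc, self.prs, self.msw])

    def table(self) -> np.ndarray:
        """(n_cells, 4) predictor matrix in the order WI, TMC, PRS, MSW."""
        return self.stack().reshape(4, -1).T


@dataclass
class GcmScenario:
    """Climate-model anomaly fields on their native coarse lattice.

    Temperature anomalies are additive (deg C, one field for monthly means and
    one for monthly minimums); precipitation anomalies are multiplicative
    ratios.
    """

    name: str
    temp_delta_mean: np.ndarray
    temp_delta_min: np.ndarray
    precip_ratio: np.ndarray
    geom: GridGeometry

    def __post_init__(self) -> None:
        self.temp_delta_mean = np.asarray(self.temp_delta_mean, dtype=float)
        td_min = self.temp_delta_min
        # a scenario supplying a single delta field applies it to both
        self.temp_delta_min = (self.temp_delta_mean.copy() if td_min is None
                               else np.asarray(td_min, dtype=float))
        self.precip_ratio = np.asarray(self.precip_ratio, dtype=float)
        if np.any(self.precip_ratio <= 0):
            raise ValueError("precipitation ratio must be positive")
        for f in (self.temp_delta_mean, self.temp_delta_min, self.precip_ratio):
            if f.shape != self.geom.shape:
                raise ValueError("anomaly field shape does not match scenario geometry")

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "temp_delta_mean": self.temp_delta_mean.tolist(),
            "temp_delta_min": self.temp_delta_min.tolist(),
            "precip_ratio": self.precip_ratio.tolist(),
            "geom": {"nrows": self.geom.nrows, "ncols": self.geom.ncols,
                     "cell_size_m": self.geom.cell_size_m,
                     "x0": self.geom.x0, "y0": self.geom.y0},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GcmScenario":
        return cls(name=d["name"],
                   temp_delta_mean=np.array(d["temp_delta_mean"]),
                   temp_delta_min=np.array(d["temp_delta_min"]),
                   precip_ratio=np.array(d["precip_ratio"]),
                   geom=GridGeometry(**d["geom"]))


def _require_12(values: np.ndarray, what: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.shape[0] != 12:
        raise ValueError(f"{what} requires 12 monthly values, got {arr.shape[0]}")
    return arr


def warmth_index(monthly_mean_temp) -> np.ndarray | float:
    """WI = sum over months of max(0, T_m - 5 deg C)."""
    t = _require_12(monthly_mean_temp, "warmth_index")
    return np.maximum(0.0, t - 5.0).sum(axis=0)


def min_temp_coldest_month(monthly_min_temp) -> np.ndarray | float:
    """TMC: minimum over the 12 monthly mean daily minimum temperatures."""
    t = _require_12(monthly_min_temp, "min_temp_coldest_month")
    return t.min(axis=0)


def summer_precipitation(monthly_precip) -> np.ndarray | float:
    """PRS: May-September (calendar months 5-9) precipitation sum."""
    p = _require_12(monthly_precip, "summer_precipitation")
    return p[4:9].sum(axis=0)


def simulate_snowpack(daily_temp, daily_precip, params: SnowModelParams
                      ) -> tuple[np.ndarray, np.ndarray | float]:
    """Degree-day snowpack water balance over one hydrological year.

    Precipitation on days colder than ``rain_snow_threshold_c`` accumulates as
    snow; rain is not stored. Daily potential melt is
    ``degree_day_factor * max(0, T - melt_base_temp_c)``, capped at the current
    snow water equivalent (SWE). Returns the daily SWE series and its maximum
    (MSW). Accepts 1-d series or ``(n_days, n_cells)`` stacks.
    """
    t = np.asarray(daily_temp, dtype=float)
    p = np.asarray(daily_precip, dtype=float)
    if t.shape != p.shape:
        raise ValueError("temperature and precipitation series differ in length")
    if np.any(p < 0):
        raise ValueError("negative precipitation")
    scalar_series = t.ndim == 1
    if scalar_series:
        t = t[:, None]
        p = p[:, None]
    swe = np.zeros_like(t)
    pack = np.zeros(t.shape[1])
    for day in range(t.shape[0]):
        snowfall = np.where(t[day] < params.rain_snow_threshold_c, p[day], 0.0)
        pack = pack + snowfall
        potential_melt = params.degree_day_factor * np.maximum(
            0.0, t[day] - params.melt_base_temp_c)
        pack = pack - np.minimum(potential_melt, pack)
        swe[day] = pack
    msw = swe.max(axis=0)
    if scalar_series:
        return swe[:, 0], float(msw[0])
    return swe, msw


def _trig_interpolate(monthly: np.ndarray, u: np.ndarray) -> np.ndarray:
    """Exact trigonometric interpolant of 12 periodic monthly values.

    ``monthly`` has shape (12, ...); ``u`` is the month-phase coordinate with
    the m-th month midpoint at u = m (period 12). At integer u the interpolant
    reproduces the monthly values to rounding error.
    """
    c = np.fft.rfft(monthly, axis=0) / 12.0  # 7 complex harmonics
    k = np.arange(7)
    ang = (2.0 * np.pi / 12.0) * np.asarray(u)[:, None] * k[None, :]  # (n_u, 7)
    w = np.where((k == 0) | (k == 6), 1.0, 2.0)  # DC and Nyquist appear once
    cos_w = np.cos(ang) * w
    sin_w = np.sin(ang) * w
    return np.tensordot(cos_w, c.real, axes=(1, 0)) - np.tensordot(sin_w, c.imag, axes=(1, 0))


def _hydro_day_phase() -> tuple[np.ndarray, np.ndarray]:
    """Month-phase coordinate u and calendar-month index (0-11) per hydro day."""
    u = np.empty(N_DAYS)
    month_idx = np.empty(N_DAYS, dtype=int)
    d = 0
    for cm in HYDRO_MONTHS:
        ndays = MONTH_LENGTHS[int(cm)]
        days = np.arange(ndays)
        u[d:d + ndays] = (cm - 1) + (days + 0.5) / ndays - 0.5
        month_idx[d:d + ndays] = cm - 1
        d += ndays
    return u, month_idx


_U_PHASE, _MONTH_OF_DAY = _hydro_day_phase()


def synthesize_daily_weather(monthly_mean_temp: np.ndarray,
                             monthly_precip: np.ndarray,
                             cfg: DailySynthesisConfig,
                             ) -> tuple[np.ndarray, np.ndarray]:
    """Synthesize one hydrological year of daily weather from monthly values.

    Temperature: trigonometric interpolation of the monthly means at month
    midpoints plus seeded N(0, temp_noise_sd_c) day-to-day noise. Precipitation:
    wet days drawn with ``wet_day_frequency``; each calendar month's total is
    split evenly over its wet days (at least one wet day per month is forced),
    so scaling a month's total scales its daily amounts exactly.

    Input arrays are ``(12,)`` or ``(12, n_cells)``; outputs are
    ``(365,)`` or ``(365, n_cells)``. Deterministic given ``cfg.seed``.
    """
    t_monthly = np.asarray(monthly_mean_temp, dtype=float)
    p_monthly = np.asarray(monthly_precip, dtype=float)
    single = t_monthly.ndim == 1
    if single:
        t_monthly = t_monthly[:, None]
        p_monthly = p_monthly[:, None]
    n = t_monthly.shape[1]
    rng = np.random.default_rng(spawn_seed(cfg.seed, N_DAYS, n))
    # fixed draw order: noise first, wet-day uniforms second, so the weather
    # noise is shared between a baseline and any temperature-shifted climate
    noise = rng.normal(0.0, cfg.temp_noise_sd_c, size=(N_DAYS, n))
    wet_u = rng.random((N_DAYS, n))

    t_daily = _trig_interpolate(t_monthly, _U_PHASE) + noise  # (365, n)

    wet = wet_u < cfg.wet_day_frequency
    p_daily = np.zeros((N_DAYS, n))
    for m in range(12):
        days = np.flatnonzero(_MONTH_OF_DAY == m)
        wet_m = wet[days]  # (ndays_m, n)
        n_wet = wet_m.sum(axis=0)
        # force at least one wet day so the monthly total is conserved
        dry_cols = np.flatnonzero(n_wet == 0)
        if dry_cols.size:
            wet_m[0, dry_cols] = True
            n_wet[dry_cols] = 1
        amounts = p_monthly[m] / n_wet
        p_daily[days[:, None], np.arange(n)[None, :]] = wet_m * amounts[None, :]
    if single:
        return t_daily[:, 0], p_daily[:, 0]
    return t_daily, p_daily


def _interp_to(geom_from: GridGeometry, field_values: np.ndarray,
               geom_to: GridGeometry) -> np.ndarray:
    """Bilinear interpolation between cell-center lattices, extrapolating at edges."""
    xs, ys = geom_from.cell_centers()
    xt, yt = geom_to.cell_centers()
    if geom_from.nrows == 1 and geom_from.ncols == 1:
        return np.full(geom_to.shape, float(field_values[0, 0]))
    if geom_from.nrows == 1 or geom_from.ncols == 1:
        coord = xs if geom_from.nrows == 1 else ys
        target = xt if geom_from.nrows == 1 else yt
        flat = field_values.ravel()
        interp = np.interp(target, coord, flat)
        return (np.tile(interp, (geom_to.nrows, 1)) if geom_from.nrows == 1
                else np.tile(interp[:, None], (1, geom_to.ncols)))
    # incremental-form bilinear (v00 + t*(v01-v00) + ...): exact on constant
    # fields, linear extrapolation beyond the outermost cell centers
    ix = np.clip(np.searchsorted(xs, xt) - 1, 0, len(xs) - 2)
    iy = np.clip(np.searchsorted(ys, yt) - 1, 0, len(ys) - 2)
    tx = (xt - xs[ix]) / (xs[ix + 1] - xs[ix])
    ty = (yt - ys[iy]) / (ys[iy + 1] - ys[iy])
    iyg, ixg = np.meshgrid(iy, ix, indexing="ij")
    tyg, txg = np.meshgrid(ty, tx, indexing="ij")
    v00 = field_values[iyg, ixg]
    v01 = field_values[iyg, ixg + 1]
    v10 = field_values[iyg + 1, ixg]
    v11 = field_values[iyg + 1, ixg + 1]
    return (v00 + txg * (v01 - v00) + tyg * (v10 - v00)
            + txg * tyg * (v11 - v10 - v01 + v00))


def interpolate_anomaly(scenario: GcmScenario, target: GridGeometry
                        ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Interpolate a scenario's anomaly fields to the target lattice.

    Returns (delta_mean, delta_min, ratio). The ratio is interpolated as
    (ratio - 1) so an identity scenario maps to exactly 1 everywhere.
    """
    if (scenario.geom.width_m < target.width_m - 1e-6
            or scenario.geom.height_m < target.height_m - 1e-6):
        raise ValueError("scenario anomaly fields do not cover the baseline domain")
    d_mean = _interp_to(scenario.geom, scenario.temp_delta_mean, target)
    d_min = _interp_to(scenario.geom, scenario.temp_delta_min, target)
    ratio = 1.0 + _interp_to(scenario.geom, scenario.precip_ratio - 1.0, target)
    return d_mean, d_min, ratio


def apply_gcm_delta(baseline: ClimateGrid, scenario: GcmScenario) -> ClimateGrid:
    """Delta-method downscaling: anomalies applied to the baseline climatology.

    Future monthly mean/minimum temperature = baseline + interpolated additive
    delta; future precipitation = baseline x interpolated ratio. An identity
    scenario (zero deltas, unit ratios) reproduces the baseline bit-for-bit.
    """
    d_mean, d_min, ratio = interpolate_anomaly(scenario, baseline.geom)
    if np.any(ratio <= 0):
        raise ValueError("interpolated precipitation ratio is nonpositive")
    mean_t = baseline.monthly_mean_temp + d_mean[None]
    min_t = baseline.monthly_min_temp + d_min[None]
    # deltas for minimums may exceed deltas for means; keep the invariant
    min_t = np.minimum(min_t, mean_t)
    precip = baseline.monthly_precip * ratio[None]
    return ClimateGrid(mean_t, min_t, precip, baseline.geom)


def compute_bioclim(climate: ClimateGrid, snow_params: SnowModelParams,
                    daily_cfg: DailySynthesisConfig) -> BioclimGrid:
    """Compute WI, TMC, PRS and MSW for every climate cell.

    WI/TMC/PRS are direct monthly aggregates. MSW synthesizes a seeded daily
    weather year per cell from the monthly climatology and runs the degree-day
    snow model; the synthesis is deterministic given ``daily_cfg.seed``, so an
    identity scenario yields bit-identical MSW.
    """
    shape = climate.geom.shape
    wi = warmth_index(climate.monthly_mean_temp)
    tmc = min_temp_coldest_month(climate.monthly_min_temp)
    prs = summer_precipitation(climate.monthly_precip)
    t_flat = climate.monthly_mean_temp.reshape(12, -1)
    p_flat = climate.monthly_precip.reshape(12, -1)
    t_daily, p_daily = synthesize_daily_weather(t_flat, p_flat, daily_cfg)
    _, msw = simulate_snowpack(t_daily, p_daily, snow_params)
    return BioclimGrid(wi=np.asarray(wi), tmc=np.asarray(tmc), prs=np.asarray(prs),
                       msw=msw.reshape(shape), geom=climate.geom)
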