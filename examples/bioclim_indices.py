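"""Compute the four bioclimatic variables for a single mountain climate cell.

Builds a monthly climatology for a cell at 2500 m (sea-level maritime profile
cooled by a 6 degC/km lapse rate), synthesizes a daily weather year, runs the
degree-day snow model and prints WI, TMC, PRS and MSW.
"""

import numpy as np

from alpinecast import (DailySynthesisConfig, SnowModelParams,
                        min_temp_coldest_month, simulate_snowpack,
                        summer_precipitation, synthesize_daily_weather,
                        warmth_index)
from alpinecast.config import (DEFAULT_MONTHLY_PRECIP_MEANS,
                               DEFAULT_SEA_LEVEL_MONTHLY_MEANS,
                               DEFAULT_SEA_LEVEL_MONTHLY_MINS)

elevation_km = 2.5
lapse = 6.0
t_mean = np.array(DEFAULT_SEA_LEVEL_MONTHLY_MEANS) - lapse * elevation_km
t_min = np.array(DEFAULT_SEA_LEVEL_MONTHLY_MINS) - lapse * elevation_km
precip = np.array(DEFAULT_MONTHLY_PRECIP_MEANS) * (1 + 0.3 * elevation_km)

wi = warmth_index(t_mean)
tmc = min_temp_coldest_month(t_min)
prs = summer_precipitation(precip)

daily_t, daily_p = synthesize_daily_weather(t_mean, precip,
                                            DailySynthesisConfig(seed=1))
swe, msw = simulate_snowpack(daily_t, daily_p, SnowModelParams())

print(f"monthly means at {elevation_km*1000:.0f} m: "
      f"{np.round(t_mean, 1).tolist()}")
print(f"WI  (warmth index)        = {wi:7.1f} degC month "
      "(heat available for plant growth; alpine zone needs roughly < 15)")
print(f"TMC (coldest-month min)   = {tmc:7.1f} degC (extreme-cold measure)")
print(f"PRS (May-Sep precip)      = {prs:7.0f} mm (growing-season water)")
print(f"MSW (max snow water eq.)  = {msw:7.0f} mm "
      f"(annual snowpack peak, day {int(np.argmax(swe))} of the hydro year)")
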