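"""Generate synthetic boreal forcing and a two-storied stand.

Builds an 11-year half-hourly weather table (with the ambient CO2 trend
388 → 410 ppm) and a 100 m² mixed pine/birch/spruce plot that is thinned
from above from basal area ~32 to ~10 m² ha⁻¹, then reports the stand's
leaf-area index before and after the harvest.
"""

import numpy as np

from isocanopy import stand_structure as ss
from isocanopy import synthetic_data as sd

weather = sd.generate_weather(sd.WeatherConfig(start_year=2010, end_year=2020, seed=0))
by_year = weather.groupby(weather.timestamp.dt.year)
print("weather: %d half-hourly records, %d years" % (len(weather), by_year.ngroups))
print("ambient CO2 2010 = %.1f, 2020 = %.1f µmol mol⁻¹"
      % (by_year.co2_ppm.mean().iloc[0], by_year.co2_ppm.mean().iloc[-1]))
summer_day = weather[(weather.timestamp.dt.month == 7) & (weather.solar_elev_deg > 0)]
print("July daytime means: T = %.1f °C, RH = %.0f %%, PAR = %.0f µmol m⁻² s⁻¹"
      % (summer_day.tair_c.mean(), summer_day.rh_pct.mean(),
         (summer_day.par_dir_umol + summer_day.par_dif_umol).mean()))

pre, post = sd.generate_stand(sd.make_harvest_config(seed=1))
basal_area = lambda df: float((np.pi / 4 * (df.dbh_cm / 100) ** 2).sum() / 100 * 1e4)
lai = lambda df: ss.build_lad(ss.inventory_from_frame(df)).lai_total
print("\nharvested plot: %d stems → %d stems" % (len(pre), len(post)))
print("basal area %.1f → %.1f m² ha⁻¹" % (basal_area(pre), basal_area(post)))
print("LAI        %.2f → %.2f m² m⁻²" % (lai(pre), lai(post)))
print("(a selection harvest removes the dominant pines/birches and releases "
      "the suppressed spruce understorey)")
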