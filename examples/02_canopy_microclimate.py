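"""Within-canopy microclimate before and after a selection harvest.

Computes the vertical profiles of sunlit fraction, PAR, wind, RH and
needle temperature for the same clear mid-summer noon under the dense
(pre-thinning) and the thinned canopy: the canopy floor gets brighter,
windier, drier and about a degree warmer after the harvest.
"""

import pandas as pd

from isocanopy import microclimate as mc
from isocanopy import stand_structure as ss
from isocanopy import synthetic_data as sd

pre_df, post_df = sd.generate_stand(sd.make_harvest_config(seed=1))
grid_pre = ss.build_lad(ss.inventory_from_frame(pre_df))
grid_post = ss.build_lad(ss.inventory_from_frame(post_df))

noon = dict(
    timestamp=pd.Timestamp("2012-07-01 12:00"), tair_c=20.0, rh_pct=60.0,
    par_dir_umol=1000.0, par_dif_umol=300.0, wind_ms=3.0,
    pressure_kpa=101.3, co2_ppm=400.0, solar_elev_deg=50.0,
)

for label, grid in (("pre-thinning ", grid_pre), ("post-thinning", grid_post)):
    prof = mc.profile_state(noon, grid)
    bottom = 10  # layer index ~2.7 m, inside the spruce crowns
    t_mean = (prof.f_sunlit[bottom] * prof.tneedle_sunlit[bottom]
              + (1 - prof.f_sunlit[bottom]) * prof.tneedle_shaded[bottom])
    print("%s (LAI %.1f): z=%.1f m  f_sunlit=%.3f  PAR_shaded=%.0f  "
          "wind=%.2f m/s  RH=%.1f %%  T_needle=%.2f °C"
          % (label, grid.lai_total, prof.z[bottom], prof.f_sunlit[bottom],
             prof.par_shaded[bottom], prof.wind[bottom], prof.rh[bottom], t_mean))
print("\n(the post-thinning floor sees more direct sun, more diffuse PAR, "
      "more wind, lower RH and warmer needles — the drivers of the "
      "tree-ring isotope response)")
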