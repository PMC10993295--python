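"""The virtual-harvest experiment: does thinning lower tree-ring Δ13C?

Runs the same suppressed spruce, under identical synthetic weather,
beneath the dense pre-thinning canopy and the thinned post-harvest canopy,
and compares the yearly earlywood/latewood isotope means.  Differences
isolate the change in canopy structure, mimicking the paired-plot logic of
a real selection-harvest study.  Takes ~30 s.
"""

from isocanopy import pipeline as pl
from isocanopy import stand_structure as ss
from isocanopy import synthetic_data as sd

weather = sd.generate_weather(sd.WeatherConfig(start_year=2012, end_year=2012, seed=3))
pre_df, post_df = sd.generate_stand(sd.make_harvest_config(seed=1))
grid_pre = ss.build_lad(ss.inventory_from_frame(pre_df))
grid_post = ss.build_lad(ss.inventory_from_frame(post_df))
spruce = [t for t in ss.inventory_from_frame(post_df) if t.species == "spruce"][0]
target = pl.target_tree_from_record(spruce, grid_pre)
print("target: suppressed spruce, DBH %.1f cm, height %.1f m, leaf area %.0f m²"
      % (spruce.dbh, spruce.height, spruce.leaf_area))

result = pl.virtual_harvest_experiment(weather, grid_pre, grid_post, target)
table = result.pivot_table(index="quantity", columns="treatment", values="value_permil")
table["response"] = table["post"] - table["pre"]
print("\nyearly EW/LW mean (‰) under each canopy, and the harvest response:")
print(table.round(2).to_string())
print("\n(Δ13C drops after thinning — weakest for the simple model, "
      "strongest with mesophyll conductance — while Δ18O_lw barely "
      "responds to canopy structure)")
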