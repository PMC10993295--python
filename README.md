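# isocanopy

Forward modelling of tree-ring stable isotopes — carbon-13 discrimination
(Δ¹³C) and leaf-water oxygen-18 enrichment (Δ¹⁸O_lw) — from canopy
structure and half-hourly weather, for ecophysiologists and
dendrochronologists who want to ask *what should the rings of this tree
record, given its light environment?*

The motivating application is a **selection harvest** (thinning from
above) in a boreal mixed stand: removing the dominant pines and birches
floods the suppressed spruce understorey with light, wind and drier air.
The package predicts how that structural change propagates into the
isotope archive of the surviving spruces, and how the answer depends on
the choice of discrimination model.

## Models

**Leaf gas exchange.** Net assimilation follows the
Farquhar–von Caemmerer–Berry model with smooth Rubisco/RuBP co-limitation
and temperature-adjusted kinetics; stomatal conductance for CO₂ follows
the unified (Medlyn) optimal model

    g_s = g0 + (1 + g1/√D_l) · A_n/C_s,

and the CO₂ supply chain A_n = g_b(C_a−C_s) = g_s(C_s−C_i) = g_m(C_i−C_c)
closes the system (solved by a vectorized bisection with exact flux
consistency).

**Carbon.** Three nested variants of photosynthetic ¹³C discrimination:

* simple: Δ¹³C = a_s + (b′ − a_s)·C_i/C_a, with b′ = 27‰, a_s = 4.4‰;
* classical: the full boundary-layer/stomata/mesophyll/carboxylation/
  photorespiration/respiration decomposition with C_c = C_i;
* classical with g_m: the same with C_c = C_i − A_n/g_m
  (default g_m = 0.1 mol m⁻² s⁻¹).

**Oxygen.** Craig–Gordon steady-state leaf-water enrichment
Δ¹⁸O_lw = f₁(ε⁺ + ε_k)(1 − w_a/w_i), with the kinetic factor ε_k mixed by
conductances between its stomatal (28‰) and boundary-layer (19‰) limits,
and optionally the Péclet damping f₁ = (1−e^−℘)/℘, ℘ = EL/(CD).

**Aggregation.** Leaf values are aggregated to tree level with
assimilation weighting over 100 canopy layers and sunlit/shaded classes,
passed through a 24-day maturation window, and split into yearly
earlywood/latewood (EW/LW) means by temperature-threshold phenology —
the resolution at which real rings are sampled.

Synthetic generators supply everything upstream: boreal weather with
diel/seasonal/synoptic/interannual structure and a 388→410 ppm CO₂ trend,
a two-storied stand thinned from basal area 32 to 10 m² ha⁻¹, and noisy
tree-ring series for round-trip tests.

## Worked example

`examples/04_virtual_harvest.py` runs one suppressed spruce under the
dense and the thinned canopy with identical weather:

```
target: suppressed spruce, DBH 11.2 cm, height 14.6 m, leaf area 25 m²

yearly EW/LW mean (‰) under each canopy, and the harvest response:
treatment           post    pre  response
quantity
d13c_classical     22.97  24.51     -1.54
d13c_classical_gm  18.95  22.78     -3.83
d13c_simple        21.57  22.20     -0.63
d18o_cg            10.39   9.42      0.97
d18o_peclet        10.07   9.29      0.78
```

Thinning lowers the tree's Δ¹³C under every variant — the brighter, drier
understorey pushes C_i/C_a down — but the size of the predicted response
roughly triples from the simple model (−0.6‰) to the mesophyll-explicit
model (−3.8‰), because the extra assimilation also deepens the C_i → C_c
drawdown.  Δ¹⁸O_lw barely distinguishes the canopies: its variation is
dominated by year-to-year humidity, not structure.  Which discrimination
model you trust therefore decides how much harvest signal you expect to
find in a ring.

The other examples generate the synthetic inputs (`01`), show the
within-canopy microclimate contrast (`02`), dissect a single leaf (`03`)
and run the one-at-a-time sensitivity analysis (`05`).

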