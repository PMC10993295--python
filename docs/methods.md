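# Methods

This note documents the models implemented in `isocanopy`, their
assumptions, the defaults that matter, and what the synthetic data do and
do not emulate.

## Scope and model chain

The package maps (stand inventory, above-canopy weather) →
(within-canopy microclimate) → (leaf gas exchange per layer and
sunlit/shaded class) → (leaf-level Δ¹³C and Δ¹⁸O_lw) →
(assimilation-weighted tree-level series) → (yearly earlywood/latewood
statistics).  It deliberately replaces heavyweight site-model components
(turbulence closure, full radiative transfer, leaf energy balance,
snow/soil submodels, process-based growth phenology) with parametric
forms whose qualitative shape is pinned by tests; the isotope
conclusions it supports depend on those shapes, not on the machinery
behind them.

## Stand structure

Foliage mass is a power law of diameter, `m = c·DBH^p` (kg, DBH in cm),
converted to one-sided leaf area by a specific leaf area (m² kg⁻¹) and
scaled by the tree's crown ratio relative to a species reference.
Harvested stems recorded by stump diameter re-enter through
`DBH = (D_s − 2)/1.25`.  Each tree's leaf area is spread over
[crown base, height] with a symmetric beta(2,2) density and summed per
species onto 100 uniform layers up to 27 m; layer sums times layer
thickness reproduce each species' LAI to machine precision (tested at
1e-9).  Default coefficients (pine c=0.031, p=1.8, SLA=6; spruce
c=0.104, p=1.6, SLA=5; birch c=0.010, p=1.8, SLA=12) were chosen once so
the default synthetic stands land on the aggregate anchors — LAI ≈ 5.8
(control), 5.3 (pre-thinning), 2.6 m² m⁻² (post-thinning) at basal areas
35/32/10 m² ha⁻¹ — the level at which such plots are reported; per-stem
values are not meant to be species-accurate allometry.  Heights and
crown bases, where unmeasured, come from saturating diameter curves.
The LAD profile of a plot is fixed for a whole simulation; growth-driven
change in canopy structure is not modelled.

## Microclimate

Radiation is two-stream Beer–Lambert.  With sun elevation β and
cumulative overlying leaf area L(z): sunlit fraction
`f_sl = exp(−k_b·L/sin β)` (k_b = 0.5), shaded PAR = diffuse ×
`exp(−k_d·L)` (k_d = 0.65), sunlit PAR = shaded + projected beam
`k_b·I_dir/sin β`; everything is zero at or below the horizon (the
daytime filter used throughout is solar elevation > 0).  Wind decays as
`exp(−0.45·L)`; RH increases by 0.5 % and air temperature falls by
0.1 °C per unit overlying LAI — monotone parametric stand-ins for the
turbulent-transport gradients, sized for a well-ventilated boreal
canopy.  Needle temperature exceeds air temperature by
`1.5·(1 − exp(−0.01·PAR))` °C per leaf class: conifer needles are
aerodynamically well coupled, so the excess saturates near 1.5 °C, and a
formerly shaded bottom layer warms by roughly 1 °C after a heavy
thinning.  Within-canopy CO₂ is held at the ambient value — canopy-air
mixing differences are small enough (<0.3‰ in δ¹³C terms) to neglect,
and modeled Δ¹³C is nearly insensitive to ambient CO₂.  Saturation
vapour pressure uses one Magnus form everywhere:
`e_sat = 0.6112·exp(17.62·T/(243.12+T))` kPa.

## Leaf gas exchange

FvCB assimilation with electron transport J from the θ-quadratic light
response (α = 0.24 mol e⁻ mol photons⁻¹, θ = 0.7) and smooth
co-limitation of the Rubisco- and RuBP-limited rates (curvature 0.98;
exact in the dark, where gross assimilation is zero and A_n = −r_d).
Kinetic constants (K_c = 404.9 µmol mol⁻¹, K_o = 278.4 mmol mol⁻¹,
Γ* = 42.75 µmol mol⁻¹ at 25 °C) and r_d follow Arrhenius temperature
responses; V_cmax (60) and J_max (114 µmol m⁻² s⁻¹ at 25 °C, typical of
boreal spruce shade foliage) use peaked Arrhenius forms.  All constants
are dataclass fields, not hard-coded.

The Medlyn model gives stomatal CO₂ conductance with defaults
g0 = 0.001 mol m⁻² s⁻¹ and g1 = 2.3 kPa^0.5; leaf-to-air vapour pressure
deficit is floored at 0.05 kPa to avoid the √D_l singularity at
saturation.  Boundary-layer conductance is the forced-convection law
`0.223·√(u/d)` (d = 0.01 m) with a 0.2 m s⁻¹ wind floor standing in for
free convection.  Conductance ratios are fixed at 1.6 (stomata) and 1.37
(boundary layer) for H₂O/CO₂.

The coupled system is closed by bisection **on A_n**: the residual
`FvCB(C_c(A_n)) − A_n` is strictly decreasing, so the root is unique;
C_s, C_i and C_c are derived from the final A_n, which makes the
diffusion identities hold exactly (tested to 1e-9 relative, and against
a dense brute-force scan over C_i).  80 iterations put the bracket width
at machine precision; non-convergence is flagged on the state, never
silent.  In darkness the solution is A_n = −r_d with C_i > C_a — the
leaf as a respiratory CO₂ source.  Seasonal photosynthetic acclimation
is not modelled.

## Isotope models

Carbon.  Constants a_b = 2.9, a_s = 4.4, a_m = 1.8, b = 29, b′ = 27,
f = 8, e = −6 ‰.  The full discrimination is

    Δ¹³C = a_b(C_a−C_s)/C_a + a_s(C_s−C_i)/C_a + a_m(C_i−C_c)/C_a
           + b·C_c/C_a − f·Γ*/C_a − e·r_d/(k·C_a),

with carboxylation efficiency k = (A_n+r_d)/(C_c−Γ*); for e = −6‰ the
respiration term is positive.  The three variants share **one**
gas-exchange solution (run with the configured g_m) and differ only in
the carboxylation CO₂ level: C_i/C_a (simple), C_c = C_i (classical) or
the mesophyll-drawn C_c (classical with g_m).  States with C_c ≤ Γ*
(k undefined) propagate as NaN and are excluded from aggregation.  No
offset is applied between resin-extracted wood and leaf sucrose.
δ↔Δ conversions use the absolute-fraction denominator
`(δ_atm − δ_wood)/(1 + δ_wood/1000)` and invert exactly (tested to
1e-12).

Oxygen.  `Δ¹⁸O_lw = f₁(ε⁺ + ε_k)(1 − w_a/w_i)`, assuming ambient vapour
in isotopic equilibrium with source water (Δ¹⁸O_vapour = −ε⁺).
ε_k = (g_b·28 + g_s·19)/(g_b + g_s) ‰.  ε⁺(T) is the Bottinga & Craig
closed form `2.644 − 3.206(10³/T) + 1.534(10⁶/T²)` ‰ (T in K; ≈9.6‰ at
20 °C).  The Péclet variant uses ℘ = EL/(CD) with L = 15 mm (one-sided
leaf-area basis), C = 55.5×10³ mol m⁻³, D = 2.66×10⁻⁹ m² s⁻¹, and
f₁ = (1−e^−℘)/℘ ≤ 1 with f₁ → 1 as E → 0.  Wood-to-leaf-water
back-calculation uses ε_cp = 3.5‰, p_ex·p_x = 0.4 and source water
δ¹⁸O = −10‰ (identical for control and harvested plots, configurable per
plot).  The biochemical water–carbonyl fractionation ε_wc is treated as
linear in temperature, `27.0 − 0.2·(T − 20 °C)` ‰ — the temperature
dependence matters for leaf-water reconstructions but no closed form is
standard, so slope and reference are exposed in `Oxygen18Constants`.

## Tree-level aggregation and phenology

Tree values are `Σ_i Λ_i Σ_j Δ_ij f_ij max(0,A_n,ij) / Σ_i Λ_i Σ_j f_ij
max(0,A_n,ij)` over layers i and sunlit/shaded classes j, where Λ_i is
the target tree's leaf area per layer.  Respiring leaf classes carry no
weight; timesteps with zero total weight (night) propagate as missing,
never as zeros.  The growing season starts 24 days (cell maturation lag)
after the first date whose trailing 5-day mean temperature reaches 5 °C
and stays there for 5 days, ends on the last such date, and splits into
EW/LW at 60 % of its span; these stand in for a process-based
growth-timing model, which the pipeline only consumes as window dates.
Rolling means are trailing 24-day assimilation-weighted averages.
Harvest responses are differences of period means of the yearly EW/LW
values, with a replicate-group standard deviation when several
trees/stands are supplied and a standard error of the difference
otherwise; a two-sample Kolmogorov–Smirnov statistic is available for
distributional comparison, and model–measurement agreement is the
standard R² at EW/LW resolution (<3 pairs flagged).  Measured intra-ring
datapoints can be dated by equal-time partition within their EW/LW
window.

## Sensitivity analysis

Protocol 1 sweeps one driver (RH, PAR, needle temperature, wind, ambient
CO₂) from its simulated minimum to maximum with the others at their
medians over (timestep × layer) states restricted to daytime, growing
season and layers with spruce foliage.  Needle temperature is swept
independently of air temperature (w_a stays tied to air temperature), a
deliberate reading of "needle temperature" as its own driver.  Protocol 2
perturbs each of {V_cmax, J_max, g1, α, r_d, g_m} by ±10 % over a seeded
random subsample of those states (default n = 5000 — a desk-scale
substitute for exhaustive per-state evaluation) and reports the full
distribution of Δ(Δ¹³C) = Δ¹³C(initial) − Δ¹³C(perturbed).  States where
the leaf fixes no carbon return NaN (the respiration term of the
discrimination diverges as k → 0) and are excluded from summaries.

## Synthetic data

Weather: seasonal sinusoid (mean 4.6 °C, amplitude 12 °C, peak
mid-July) + diel sinusoid (8 °C peak-to-peak, warmest mid-afternoon) +
daily AR(1) synoptic anomalies + independent year-level anomalies for
temperature (σ = 0.7 °C), dew-point depression (σ = 1.0 °C), cloudiness
(σ = 0.08) and wind (σ = 0.4 m s⁻¹).  RH derives from a slowly varying
dew point, which produces the realistic diel RH–temperature
anticorrelation; clear-sky PAR is 1800·sin β µmol m⁻² s⁻¹ attenuated by
cloud, with diffuse fraction `clip(0.15 + 0.85·cloud, 0.15, 1)`; ambient
CO₂ takes yearly values on a linear 388→410 µmol mol⁻¹ trend.  The
year-level anomalies matter: without them yearly isotope means barely
vary, whereas interpreting a harvest response requires comparing it
against realistic interannual spread.  Timestamps are local solar time
labelling interval starts.

Stands: stems are drawn per species from Gaussian diameter distributions
(pine 24±3, birch 20±4, spruce 10±2 cm) until each species' share of the
basal-area target is met, the last stem trimmed to hit the target
exactly; thinning from above removes the largest stems while each
removal brings the plot closer to the post-harvest target.

Not emulated: precipitation, snow, soil moisture (the target site type
is not water-limited), weather-station gap structure, stem-level realism
of any particular inventory, post-photosynthetic fractionation, and
day/night discrimination asymmetry.  Passing tests therefore demonstrate
the internal consistency and qualitative structure of the model chain —
sign and ordering of the harvest response, dominance of humidity/light
drivers, parameter identifiability under analytical noise — not
site-level predictive accuracy.

## Numerical choices and problem sizes

All stochastic operations take explicit seeds (numpy `default_rng`);
identical seeds give bit-identical outputs.  The leaf solver uses 80
bisection iterations (bracket [−r_d−1, V_cmax(T)+1]); the inner
mesophyll loop in the brute-force test oracle uses damped fixed-point
iteration.  Degenerate inputs fail loudly: non-positive C_c, empty
species mixes, grid tops below the tallest tree, p_ex·p_x = 1.  The
packaged experiments run at desk scale — single plots, one target tree,
a few synthetic years (the virtual-harvest test uses four), 10³–10⁴
environmental states for sensitivity and recovery — sizes chosen so the
full suite completes in minutes on one core while every scientific
property remains testable.
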