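"""Synthetic boreal forcing, stand inventories and tree-ring isotope noise.

The weather generator emulates the growing-season meteorology of a southern
Finnish peatland forest: a seasonal temperature sinusoid peaking in
mid-July, a diel sinusoid peaking mid-afternoon, AR(1) day-to-day synoptic
anomalies, relative humidity derived from a slowly varying dew point (which
produces the realistic diel RH–temperature anticorrelation), clear-sky PAR
from solar elevation split into direct and diffuse parts by a stochastic
cloud series, and an ambient CO2 mole fraction following a linear yearly
trend (388 → 410 µmol mol⁻¹ over 2010–20 by default).

The stand generator builds a two-storied mixed stand — pine and birch
dominating over a dense spruce understorey — on a 100 m² plot, hitting a
basal-area target exactly (the last stem is trimmed), and thins it from
above to a post-harvest basal-area target.  With the default allometry the
default configurations land on leaf-area-index values of roughly
5.8 (control), 5.3 (pre-thinning) and 2.6 m² m⁻² (post-thinning).

Everything is deterministic given its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .microclimate import saturation_vapour_pressure, solar_elevation
from .stand_structure import DEFAULT_ALLOMETRY, impute_crown_base, impute_height

__all__ = [
    "WeatherConfig",
    "StandConfig",
    "generate_weather",
    "generate_stand",
    "make_harvest_config",
    "make_control_config",
    "generate_isotope_series",
    "WEATHER_COLUMNS",
]

WEATHER_COLUMNS = [
    "timestamp",
    "tair_c",
    "rh_pct",
    "par_dir_umol",
    "par_dif_umol",
    "wind_ms",
    "pressure_kpa",
    "co2_ppm",
]


@dataclass(frozen=True)
class WeatherConfig:
    """Synthetic above-canopy weather configuration.

    Years are inclusive; the CO2 trend runs linearly from ``co2_start`` in
    ``start_year`` to ``co2_end`` in ``end_year`` (yearly values, constant
    within a year).  Temperatures in °C, RH in %, wind in m s⁻¹.
    """

    start_year: int = 2010
    end_year: int = 2020
    latitude: float = 60.6
    timestep_min: int = 30
    co2_start: float = 388.0
    co2_end: float = 410.0
    temp_mean: float = 4.6
    temp_seasonal_amplitude: float = 12.0
    temp_diel_amplitude: float = 8.0
    temp_synoptic_sd: float = 3.0
    rh_mean: float = 75.0
    cloud_fraction_mean: float = 0.5
    wind_mean: float = 2.5
    # year-level (macroclimate) anomalies: some summers are warm/dry/windy,
    # others cool/moist — the dominant source of interannual spread in
    # tree-ring isotope series
    temp_interannual_sd: float = 0.7       # °C on the yearly mean
    dewpoint_dep_interannual_sd: float = 1.0  # °C on the yearly dew-point depression
    cloud_interannual_sd: float = 0.08
    wind_interannual_sd: float = 0.4
    pressure_kpa: float = 101.3
    par_clear_sky: float = 1800.0  # µmol m-2 s-1 at overhead sun, clear sky
    seed: int = 0

    def __post_init__(self):
        if self.end_year < self.start_year:
            raise ValueError("end_year must not precede start_year")
        if abs(self.latitude) > 90:
            raise ValueError("latitude must lie in [-90, 90]")
        if self.timestep_min <= 0 or (24 * 60) % self.timestep_min:
            raise ValueError("timestep must divide 24 h")
        if self.co2_start > self.co2_end:
            raise ValueError("co2_start must not exceed co2_end")


def _ar1(rng, n, phi, sd):
    """Stationary AR(1) series with marginal standard deviation ``sd``."""
    x = np.empty(n)
    x[0] = rng.normal(0.0, sd)
    innov_sd = sd * np.sqrt(1.0 - phi**2)
    eps = rng.normal(0.0, innov_sd, size=n - 1)
    for i in range(1, n):
        x[i] = phi * x[i - 1] + eps[i - 1]
    return x


def _dewpoint_depression(rh_mean: float, t_ref: float = 15.0) -> float:
    """Depression (°C) such that RH(t_ref − dep vs t_ref) equals rh_mean."""
    target = rh_mean / 100.0

    def f(dep):
        return saturation_vapour_pressure(t_ref - dep) / saturation_vapour_pressure(t_ref) - target

    return brentq(f, 0.0, 40.0)


def generate_weather(cfg: WeatherConfig = WeatherConfig()) -> pd.DataFrame:
    """Generate a half-hourly above-canopy forcing table.

    Columns: timestamp, tair_c, rh_pct, par_dir_umol, par_dif_umol,
    wind_ms, pressure_kpa, co2_ppm, plus solar_elev_deg.  Timestamps are
    local solar time labelling the start of each interval.  PAR is exactly
    zero whenever the sun is at or below the horizon; RH is bounded to
    [0, 100]; CO2 stays within [co2_start, co2_end].
    """
    rng = np.random.default_rng(cfg.seed)
    ts = pd.date_range(
        start=f"{cfg.start_year}-01-01",
        end=f"{cfg.end_year}-12-31 23:59",
        freq=f"{cfg.timestep_min}min",
    )
    n = len(ts)
    doy = ts.dayofyear.to_numpy(dtype=float)
    hour = ts.hour.to_numpy(dtype=float) + ts.minute.to_numpy(dtype=float) / 60.0
    day_index = ((ts - ts[0]).days).to_numpy()
    n_days = day_index.max() + 1
    years = ts.year.to_numpy()
    year_index = years - cfg.start_year
    n_years = cfg.end_year - cfg.start_year + 1

    # year-level macroclimate anomalies (drawn first: stable per seed)
    temp_year = rng.normal(0.0, cfg.temp_interannual_sd, size=n_years)
    dep_year = rng.normal(0.0, cfg.dewpoint_dep_interannual_sd, size=n_years)
    cloud_year = rng.normal(0.0, cfg.cloud_interannual_sd, size=n_years)
    wind_year = rng.normal(0.0, cfg.wind_interannual_sd, size=n_years)

    # --- temperature: seasonal + diel + synoptic AR(1) anomaly ---
    seasonal = cfg.temp_mean + cfg.temp_seasonal_amplitude * np.sin(
        2.0 * np.pi * (doy - 105.0) / 365.25
    )
    diel = 0.5 * cfg.temp_diel_amplitude * np.sin(2.0 * np.pi * (hour - 9.0) / 24.0)
    synoptic_daily = _ar1(rng, n_days, phi=0.8, sd=cfg.temp_synoptic_sd)
    tair = seasonal + diel + synoptic_daily[day_index] + temp_year[year_index]

    # --- RH from a slowly varying dew point ---
    dep0 = _dewpoint_depression(cfg.rh_mean)
    dep_daily = np.maximum(0.5, dep0 + _ar1(rng, n_days, phi=0.7, sd=1.5))
    daily_mean_t = np.bincount(day_index, weights=tair) / np.bincount(day_index)
    dewpoint = (daily_mean_t - dep_daily)[day_index] - dep_year[year_index]
    rh = 100.0 * saturation_vapour_pressure(dewpoint) / saturation_vapour_pressure(tair)
    rh = np.clip(rh, 2.0, 100.0)

    # --- radiation: clear-sky PAR times cloud transmittance ---
    elev = solar_elevation(ts, cfg.latitude)
    sin_beta = np.sin(np.deg2rad(np.maximum(elev, 0.0)))
    cloud_daily = _ar1(rng, n_days, phi=0.6, sd=0.25)
    cloud = np.clip(
        cfg.cloud_fraction_mean + cloud_daily[day_index] + cloud_year[year_index], 0.0, 1.0
    )
    par = np.where(elev > 0, cfg.par_clear_sky * sin_beta * (1.0 - 0.75 * cloud), 0.0)
    dif_frac = np.clip(0.15 + 0.85 * cloud, 0.15, 1.0)
    par_dif = par * dif_frac
    par_dir = par - par_dif

    # --- wind: daily AR(1), daytime amplification, positive floor ---
    wind_daily = np.maximum(0.2, cfg.wind_mean + _ar1(rng, n_days, phi=0.7, sd=0.8))
    wind = np.maximum(
        0.1,
        (wind_daily[day_index] + wind_year[year_index])
        * (1.0 + 0.3 * np.sin(2.0 * np.pi * (hour - 9.0) / 24.0)),
    )

    # --- CO2: yearly values on the linear trend ---
    span = max(cfg.end_year - cfg.start_year, 1)
    co2 = cfg.co2_start + (cfg.co2_end - cfg.co2_start) * (years - cfg.start_year) / span

    return pd.DataFrame(
        {
            "timestamp": ts,
            "tair_c": tair,
            "rh_pct": rh,
            "par_dir_umol": par_dir,
            "par_dif_umol": par_dif,
            "wind_ms": wind,
            "pressure_kpa": np.full(n, cfg.pressure_kpa),
            "co2_ppm": co2,
            "solar_elev_deg": elev,
        }
    )


# ---------------------------------------------------------------------------
# stand generation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StandConfig:
    """Synthetic two-storied stand on a circular plot.

    ``species_ba_share`` apportions the pre-thinning basal-area target
    between species; ``dbh_mean``/``dbh_sd`` (cm) describe each species'
    stem-diameter distribution (dominant pine/birch, suppressed spruce).
    ``thinning_rule`` is ``"from_above"`` (remove the largest trees until
    the post target is reached, a selection harvest) or ``"none"``.
    """

    plot_area: float = 100.0
    basal_area_target: float = 32.0  # m2 ha-1, pre-thinning
    post_basal_area_target: float = 10.0  # m2 ha-1
    species_ba_share: Mapping[str, float] = field(
        default_factory=lambda: {"pine": 0.55, "birch": 0.13, "spruce": 0.32}
    )
    dbh_mean: Mapping[str, float] = field(
        default_factory=lambda: {"pine": 24.0, "birch": 20.0, "spruce": 10.0}
    )
    dbh_sd: Mapping[str, float] = field(
        default_factory=lambda: {"pine": 3.0, "birch": 4.0, "spruce": 2.0}
    )
    dbh_min: float = 5.0
    thinning_rule: str = "from_above"
    seed: int = 0

    def __post_init__(self):
        if self.plot_area <= 0:
            raise ValueError("plot area must be positive")
        if not self.species_ba_share:
            raise ValueError("species mix must not be empty")
        if self.thinning_rule not in ("from_above", "none"):
            raise ValueError("thinning_rule must be 'from_above' or 'none'")


def make_harvest_config(seed: int = 0, **kwargs) -> StandConfig:
    """Config of the harvested plot: basal area 32 → 10 m² ha⁻¹."""
    return StandConfig(seed=seed, **kwargs)


def make_control_config(seed: int = 0, **kwargs) -> StandConfig:
    """Config of the unthinned control plot (slightly denser, no removal)."""
    kwargs.setdefault("basal_area_target", 35.0)
    kwargs.setdefault("thinning_rule", "none")
    return StandConfig(seed=seed, **kwargs)


def _basal_area_m2(dbh_cm) -> np.ndarray:
    return np.pi / 4.0 * (np.asarray(dbh_cm, dtype=float) / 100.0) ** 2


def generate_stand(
    cfg: StandConfig = StandConfig(),
    allometry=DEFAULT_ALLOMETRY,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Generate (pre-thinning, post-thinning) inventory tables.

    Stems are drawn per species until each species' basal-area share of the
    pre-thinning target is met; the last stem of each species is shrunk so
    the plot hits the target exactly.  Thinning from above then removes the
    largest-DBH trees while doing so brings the plot basal area closer to
    the post-harvest target, mimicking a selection harvest that releases
    the spruce understorey.  Harvested trees carry a synthetic stump
    diameter consistent with the DBH regression.  The post table is a
    subset of the pre table (``removed_flag`` marks harvested stems).
    """
    rng = np.random.default_rng(cfg.seed)
    target_total = cfg.basal_area_target / 1e4 * cfg.plot_area  # m2 on the plot
    rows = []
    tree_id = 0
    for sp, share in cfg.species_ba_share.items():
        target_sp = share * target_total
        acc = 0.0
        dbhs = []
        while acc < target_sp:
            d = max(cfg.dbh_min, rng.normal(cfg.dbh_mean[sp], cfg.dbh_sd[sp]))
            dbhs.append(d)
            acc += float(_basal_area_m2(d))
        # trim the last stem to land exactly on the species target
        excess = acc - target_sp
        last_ba = float(_basal_area_m2(dbhs[-1]))
        if excess > 0 and last_ba > excess:
            dbhs[-1] = float(np.sqrt((last_ba - excess) * 4.0 / np.pi) * 100.0)
            if dbhs[-1] < cfg.dbh_min:
                dbhs.pop()
        for d in dbhs:
            height = float(impute_height(d, sp, allometry))
            rows.append(
                {
                    "tree_id": tree_id,
                    "species": sp,
                    "dbh_cm": d,
                    "stump_d_cm": d * 1.25 + 2.0,
                    "height_m": height,
                    "crown_base_m": float(impute_crown_base(height, sp, allometry)),
                    "removed_flag": 0,
                }
            )
            tree_id += 1

    pre = pd.DataFrame(rows).sort_values("dbh_cm", ascending=False).reset_index(drop=True)

    if cfg.thinning_rule == "none":
        post = pre.copy()
        return pre, post

    post_target = cfg.post_basal_area_target / 1e4 * cfg.plot_area
    ba = _basal_area_m2(pre["dbh_cm"])
    keep = np.ones(len(pre), dtype=bool)
    current = float(ba.sum())
    for i in range(len(pre)):  # pre is sorted largest first
        after = current - float(ba[i])
        if abs(after - post_target) < abs(current - post_target):
            keep[i] = False
            current = after
        if current <= post_target:
            break
    pre = pre.copy()
    pre["removed_flag"] = (~keep).astype(int)
    post = pre[keep].reset_index(drop=True)
    return pre, post


# ---------------------------------------------------------------------------
# synthetic tree-ring isotope series
# ---------------------------------------------------------------------------

def generate_isotope_series(true_series: pd.DataFrame, noise_sd: float, seed: int = 0) -> pd.DataFrame:
    """Add Gaussian measurement noise (‰) to an isotope series table.

    ``true_series`` needs a ``value_permil`` column; all other columns
    (timestamps, EW/LW labels, tree ids) are preserved.  The default noise
    magnitude in tests, 0.14‰, corresponds to replicate analytical
    precision of a mass-spectrometry quality-control material.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rng = np.random.default_rng(seed)
    out = true_series.copy()
    out["value_permil"] = out["value_permil"].to_numpy(dtype=float) + rng.normal(
        0.0, noise_sd, size=len(out)
    )
    return out
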