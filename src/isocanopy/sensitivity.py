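"""One-at-a-time (OAT) sensitivity of modeled Δ¹³C.

Two protocols, both operating on the single-leaf gas-exchange module with
the classical-with-g_m discrimination:

1. *Driver sweep*: hold every meteorological driver at its median over the
   modeled within-canopy states and sweep one driver (RH, PAR, needle
   temperature, wind or ambient CO2) from its simulated minimum to maximum.
2. *Parameter perturbation*: perturb one photosynthesis/water-use parameter
   (vcmax, jmax, g1, alpha, rd, gm) by ±10% across a sample of
   environmental states and report the distribution of
   Δ(Δ¹³C) = Δ¹³C(initial) − Δ¹³C(perturbed) — sign convention: a positive
   value means the perturbation lowered the discrimination.

The environmental state sample mirrors the conditions relevant for wood
formation: daytime, growing season, canopy layers where the target species
has foliage.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import isotopes as iso
from .leaf_gas_exchange import PhotosynthesisParams, solve_leaf
from .microclimate import MicroclimateParams, profile_series, vapour_mole_fraction
from .pipeline import PhenologyConfig, phenology_windows
from .stand_structure import CanopyGrid

__all__ = [
    "DRIVERS",
    "PERTURBABLE",
    "SensitivityResult",
    "EnvironmentSummary",
    "sample_environmental_states",
    "summarize_environment",
    "leaf_delta13c",
    "oat_driver_sweep",
    "oat_parameter_perturbation",
    "gm_scenario_runs",
]

DRIVERS = ("rh", "par", "tneedle", "wind", "co2")
PERTURBABLE = ("vcmax", "jmax", "g1", "alpha", "rd", "gm")

_PARAM_FIELD = {
    "vcmax": "vcmax25",
    "jmax": "jmax25",
    "g1": "g1",
    "alpha": "alpha",
    "rd": "rd25",
    "gm": "gm",
}


@dataclass
class SensitivityResult:
    """Distribution of Δ(Δ¹³C) (‰) for one perturbed parameter."""

    name: str
    fraction: float
    delta_decrease: np.ndarray  # Δ(Δ13C) for the −fraction perturbation
    delta_increase: np.ndarray  # Δ(Δ13C) for the +fraction perturbation
    n_skipped: int = 0
    environment: str = "sampled states"


@dataclass
class EnvironmentSummary:
    """Median / min / max per driver over the sampled states."""

    median: Mapping[str, float]
    minimum: Mapping[str, float]
    maximum: Mapping[str, float]
    tair_median: float
    pressure_median: float


def sample_environmental_states(
    weather: pd.DataFrame,
    grid: CanopyGrid,
    target_lad: np.ndarray,
    micro_params: MicroclimateParams = MicroclimateParams(),
    phenology: PhenologyConfig = PhenologyConfig(),
    n: int = 5000,
    seed: int = 0,
) -> pd.DataFrame:
    """Sample within-canopy environmental states relevant to wood formation.

    States are (timestep × layer) combinations restricted to daytime,
    growing-season timesteps and to layers where ``target_lad`` (the target
    species' leaf-area density) is positive; a uniform random subsample of
    at most ``n`` states is returned with columns
    ``par, tneedle, tair, rh, wind, co2, pressure, w_a`` (sunlit and shaded
    leaf classes both contribute, through their distinct PAR and needle
    temperature).
    """
    windows = phenology_windows(weather, phenology)
    ts = pd.DatetimeIndex(weather["timestamp"])
    in_season = np.zeros(len(ts), dtype=bool)
    for win in windows.values():
        in_season |= (ts >= win.start) & (ts < win.end)
    day = weather["solar_elev_deg"].to_numpy(dtype=float) > 0
    sel = in_season & day
    if not sel.any():
        raise ValueError("no daytime growing-season states in the weather series")

    prof = profile_series(weather.loc[sel], grid, micro_params)
    mask = np.asarray(target_lad, dtype=float) > 0
    rows = {}
    for cls, par2d, tn2d in (
        ("sunlit", prof.par_sunlit, prof.tneedle_sunlit),
        ("shaded", prof.par_shaded, prof.tneedle_shaded),
    ):
        rows.setdefault("par", []).append(par2d[:, mask].ravel())
        rows.setdefault("tneedle", []).append(tn2d[:, mask].ravel())
        for name, arr in (
            ("tair", prof.tair), ("rh", prof.rh), ("wind", prof.wind),
            ("co2", prof.co2), ("pressure", prof.pressure), ("w_a", prof.w_a),
        ):
            rows.setdefault(name, []).append(arr[:, mask].ravel())
    states = pd.DataFrame({k: np.concatenate(v) for k, v in rows.items()})
    if len(states) > n:
        rng = np.random.default_rng(seed)
        states = states.iloc[np.sort(rng.choice(len(states), size=n, replace=False))]
    return states.reset_index(drop=True)


def summarize_environment(states: pd.DataFrame) -> EnvironmentSummary:
    """Median and range per driver, the sweep anchors of protocol 1."""
    med = {d: float(states[d].median()) for d in DRIVERS}
    return EnvironmentSummary(
        median=med,
        minimum={d: float(states[d].min()) for d in DRIVERS},
        maximum={d: float(states[d].max()) for d in DRIVERS},
        tair_median=float(states["tair"].median()),
        pressure_median=float(states["pressure"].median()),
    )


def leaf_delta13c(
    par, tneedle, rh, wind, co2, tair, pressure,
    p: PhotosynthesisParams = PhotosynthesisParams(),
    c13: iso.Carbon13Constants = iso.Carbon13Constants(),
):
    """Classical-with-g_m Δ¹³C (‰) of a single leaf under the given drivers.

    The atmospheric vapour content follows from RH at the *air*
    temperature, so needle temperature can be perturbed as an independent
    driver (it then only shifts the leaf-side saturation and kinetics).
    States where the leaf fixes no carbon (A_n ≤ 0) record no isotope
    signal and return NaN — the respiration term of the discrimination
    model diverges there.
    """
    w_a = vapour_mole_fraction(rh, tair, pressure)
    leaf = solve_leaf(par, tneedle, wind, co2, w_a, pressure, p)
    delta = np.asarray(iso.discrimination_classical(leaf, c13, use_gm=True))
    delta = np.where(np.asarray(leaf.an) > 0, delta, np.nan)
    return delta if delta.ndim else float(delta)


def oat_driver_sweep(
    driver: str,
    env: EnvironmentSummary,
    n_grid: int = 41,
    p: PhotosynthesisParams = PhotosynthesisParams(),
    c13: iso.Carbon13Constants = iso.Carbon13Constants(),
) -> pd.DataFrame:
    """Sweep one driver from its simulated min to max, others at median.

    Returns a DataFrame ``driver_value, delta13c_permil``; a degenerate
    (min == max) driver yields a single-point curve.
    """
    if driver not in DRIVERS:
        raise ValueError(f"driver must be one of {DRIVERS}")
    lo, hi = env.minimum[driver], env.maximum[driver]
    grid = np.linspace(lo, hi, 1 if np.isclose(lo, hi) else n_grid)
    vals = {d: np.full(len(grid), env.median[d]) for d in DRIVERS}
    vals[driver] = grid
    delta = leaf_delta13c(
        vals["par"], vals["tneedle"], vals["rh"], vals["wind"], vals["co2"],
        env.tair_median, env.pressure_median, p, c13,
    )
    return pd.DataFrame({"driver_value": grid, "delta13c_permil": np.asarray(delta)})


def oat_parameter_perturbation(
    states: pd.DataFrame,
    parameters: Sequence[str] = PERTURBABLE,
    fraction: float = 0.10,
    p: PhotosynthesisParams = PhotosynthesisParams(),
    c13: iso.Carbon13Constants = iso.Carbon13Constants(),
) -> dict:
    """±``fraction`` perturbation of each parameter across sampled states.

    Returns {parameter: SensitivityResult} with the full Δ(Δ¹³C)
    distributions (initial minus perturbed) for the decreased and increased
    parameter; states where a perturbed parameter would become
    non-physical (≤ 0) are skipped and counted.
    """
    args = (
        states["par"].to_numpy(), states["tneedle"].to_numpy(), states["rh"].to_numpy(),
        states["wind"].to_numpy(), states["co2"].to_numpy(), states["tair"].to_numpy(),
        states["pressure"].to_numpy(),
    )
    base = np.asarray(leaf_delta13c(*args, p, c13))
    out = {}
    for name in parameters:
        field_name = _PARAM_FIELD[name]
        value = getattr(p, field_name)
        deltas = []
        n_skipped = 0
        for sign in (-1.0, +1.0):
            perturbed_value = value * (1.0 + sign * fraction)
            if perturbed_value <= 0 and np.isfinite(perturbed_value):
                deltas.append(np.full_like(base, np.nan))
                n_skipped += base.size
                continue
            perturbed = np.asarray(
                leaf_delta13c(*args, replace(p, **{field_name: perturbed_value}), c13)
            )
            deltas.append(base - perturbed)
        out[name] = SensitivityResult(
            name=name, fraction=fraction,
            delta_decrease=deltas[0], delta_increase=deltas[1],
            n_skipped=n_skipped,
        )
    return out


def gm_scenario_runs(
    gm_values: Sequence[float],
    run_experiment,
    p: PhotosynthesisParams = PhotosynthesisParams(),
) -> dict:
    """Re-run a full virtual-harvest experiment per mesophyll conductance.

    ``run_experiment`` is a callable taking a PhotosynthesisParams and
    returning the experiment's harvest response (‰); it is invoked once per
    g_m value with only g_m changed.  Lower g_m strengthens the mesophyll
    CO2 drawdown and hence the modeled harvest response.
    """
    return {float(gm): run_experiment(replace(p, gm=float(gm))) for gm in gm_values}
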