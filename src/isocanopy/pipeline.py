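"""End-to-end pipeline: forcing → microclimate → leaf states → tree rings.

Runs the leaf gas-exchange and isotope models across every canopy layer
occupied by a target tree, aggregates leaf values to tree level with
assimilation weighting

    Δ_tree = Σ_i Λ_i Σ_j Δ_ij f_ij max(0, A_n,ij) / Σ_i Λ_i Σ_j f_ij max(0, A_n,ij)

over the layers i and sunlit/shaded classes j, applies temperature-threshold
phenology windows with a cell-maturation lag, 24-day assimilation-weighted
rolling means and earlywood/latewood (EW/LW) period means, and computes
harvest-response statistics and model–measurement comparison at EW/LW
resolution.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import isotopes as iso
from .leaf_gas_exchange import PhotosynthesisParams, solve_leaf
from .microclimate import MicroclimateParams, profile_series
from .stand_structure import CanopyGrid, TreeRecord, _crown_layer_fractions, DEFAULT_ALLOMETRY

__all__ = [
    "TargetTree",
    "PhenologyConfig",
    "PhenologyWindow",
    "HarvestResponse",
    "target_tree_from_record",
    "aggregate_tree",
    "simulate_isotopes",
    "phenology_windows",
    "rolling_assimilation_mean",
    "ew_lw_means",
    "harvest_response",
    "ks_statistic",
    "compare_to_measurements",
    "partition_equal_time",
    "virtual_harvest_experiment",
    "grid_search_g1_gm",
    "QUANTITIES",
]

QUANTITIES = (
    "d13c_simple",
    "d13c_classical",
    "d13c_classical_gm",
    "d18o_cg",
    "d18o_peclet",
)


@dataclass
class TargetTree:
    """A cored target tree: its per-layer leaf area on the canopy grid."""

    tree_id: int
    species: str
    leaf_area_layers: np.ndarray  # m2 per canopy layer
    treatment: str = "control"

    def __post_init__(self):
        la = np.asarray(self.leaf_area_layers, dtype=float)
        if np.any(la < 0) or la.sum() <= 0:
            raise ValueError("target tree needs non-negative layer leaf areas with a positive total")
        self.leaf_area_layers = la


def target_tree_from_record(
    tree: TreeRecord,
    grid: CanopyGrid,
    treatment: str = "control",
    allometry=DEFAULT_ALLOMETRY,
) -> TargetTree:
    """Distribute a tree's leaf area over the grid layers (beta crown shape)."""
    edges = np.concatenate([grid.z - grid.dz / 2.0, [grid.z[-1] + grid.dz / 2.0]])
    frac = _crown_layer_fractions(tree, edges, allometry[tree.species].crown_shape)
    return TargetTree(
        tree_id=tree.tree_id,
        species=tree.species,
        leaf_area_layers=tree.leaf_area * frac,
        treatment=treatment,
    )


def aggregate_tree(delta, an, f_sunlit, leaf_area_layers):
    """Assimilation-weighted tree-level mean of leaf isotope values (‰).

    ``delta`` and ``an`` have shape (..., n_layers, 2) for the sunlit and
    shaded classes, ``f_sunlit`` shape (..., n_layers) and
    ``leaf_area_layers`` shape (n_layers,).  Weights are
    Λ_i · f_ij · max(0, A_n); layers respiring (A_n ≤ 0) carry no weight
    and NaN leaf values are excluded.  Returns (value, total_weight); the
    value is NaN where the total weight vanishes (e.g. at night).
    """
    delta = np.asarray(delta, dtype=float)
    an = np.asarray(an, dtype=float)
    f_sl = np.asarray(f_sunlit, dtype=float)
    la = np.asarray(leaf_area_layers, dtype=float)
    if delta.shape != an.shape or delta.shape[-1] != 2 or f_sl.shape != delta.shape[:-1]:
        raise ValueError("shape mismatch between leaf values, assimilation and sunlit fraction")
    if la.shape != delta.shape[-2:-1]:
        raise ValueError("leaf-area vector does not match the layer dimension")
    f = np.stack([f_sl, 1.0 - f_sl], axis=-1)
    w = la[:, None] * f * np.maximum(an, 0.0)
    w = np.where(np.isnan(delta), 0.0, w)
    wsum = w.sum(axis=(-2, -1))
    with np.errstate(invalid="ignore", divide="ignore"):
        value = np.nansum(w * delta, axis=(-2, -1)) / wsum
    value = np.where(wsum > 0, value, np.nan)
    if value.ndim == 0:
        return float(value), float(wsum)
    return value, wsum


def simulate_isotopes(
    weather: pd.DataFrame,
    grid: CanopyGrid,
    target: TargetTree,
    leaf_params: PhotosynthesisParams = PhotosynthesisParams(),
    micro_params: MicroclimateParams = MicroclimateParams(),
    c13: iso.Carbon13Constants = iso.Carbon13Constants(),
    o18: iso.Oxygen18Constants = iso.Oxygen18Constants(),
) -> pd.DataFrame:
    """Half-hourly tree-level isotope series for one target tree.

    Solves sunlit and shaded leaves of the target tree's species in every
    canopy layer it occupies, for every daytime timestep, then aggregates
    with assimilation weighting.  Returns a DataFrame indexed by timestamp
    with the five model quantities (three 13C-discrimination variants, two
    leaf-water 18O models, all ‰) and the aggregation ``weight`` (the
    denominator of the tree-level mean); night values are NaN with zero
    weight, never zeros.

    The three 13C variants share one gas-exchange solution (with the
    configured mesophyll conductance): they differ only in the CO2 mole
    fraction at which carboxylation is taken to occur — Ci/Ca alone
    (simple), Cc = Ci (classical) or the mesophyll-drawn-down Cc
    (classical with g_m).
    """
    mask = target.leaf_area_layers > 0
    la = target.leaf_area_layers[mask]
    day = (weather["solar_elev_deg"].to_numpy(dtype=float) > 0) & (
        (weather["par_dir_umol"] + weather["par_dif_umol"]).to_numpy(dtype=float) > 0
    )
    out = pd.DataFrame(
        index=pd.DatetimeIndex(weather["timestamp"]),
        columns=list(QUANTITIES) + ["weight"],
        dtype=float,
    )
    out["weight"] = 0.0
    if not day.any():
        return out

    prof = profile_series(weather.loc[day], grid, micro_params)
    nt, m = int(day.sum()), int(mask.sum())

    def stack(sl, sh):
        return np.stack([sl[:, mask], sh[:, mask]], axis=-1)  # (nt, m, 2)

    par = stack(prof.par_sunlit, prof.par_shaded)
    tleaf = stack(prof.tneedle_sunlit, prof.tneedle_shaded)
    w_a = np.repeat(prof.w_a[:, mask, None], 2, axis=-1)
    wind = np.repeat(prof.wind[:, mask, None], 2, axis=-1)
    co2 = np.repeat(prof.co2[:, mask, None], 2, axis=-1)
    press = np.repeat(prof.pressure[:, mask, None], 2, axis=-1)
    f_sl = prof.f_sunlit[:, mask]

    leaf = solve_leaf(
        par.ravel(), tleaf.ravel(), wind.ravel(), co2.ravel(), w_a.ravel(),
        press.ravel(), leaf_params,
    )

    shape = (nt, m, 2)
    an = leaf.an.reshape(shape)
    values = {
        "d13c_simple": iso.discrimination_simple(
            (leaf.ci / leaf.ca).reshape(shape), c13
        ),
        "d13c_classical": np.asarray(
            iso.discrimination_classical(leaf, c13, use_gm=False)
        ).reshape(shape),
        "d13c_classical_gm": np.asarray(
            iso.discrimination_classical(leaf, c13, use_gm=True)
        ).reshape(shape),
        "d18o_cg": np.asarray(
            iso.leafwater_enrichment(leaf, w_a.ravel(), "craig_gordon", o18)
        ).reshape(shape),
        "d18o_peclet": np.asarray(
            iso.leafwater_enrichment(leaf, w_a.ravel(), "peclet", o18)
        ).reshape(shape),
    }
    weight = None
    for name, val in values.items():
        agg, wsum = aggregate_tree(val, an, f_sl, la)
        out.loc[day, name] = agg
        weight = wsum if weight is None else weight
    out.loc[day, "weight"] = weight
    return out


# ---------------------------------------------------------------------------
# phenology
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PhenologyConfig:
    """Temperature-threshold growth phenology.

    The season (tracheid-maturation period) starts ``maturation_lag_days``
    after the first date whose trailing ``rolling_days``-day mean air
    temperature reaches ``temp_threshold_c`` and stays there for
    ``sustain_days`` days; it ends on the last date the rolling mean is
    still at the threshold.  Earlywood formation occupies the first
    ``ew_fraction`` of the season, latewood the remainder.
    """

    temp_threshold_c: float = 5.0
    rolling_days: int = 5
    sustain_days: int = 5
    maturation_lag_days: int = 24
    ew_fraction: float = 0.6


@dataclass(frozen=True)
class PhenologyWindow:
    start: pd.Timestamp
    split: pd.Timestamp
    end: pd.Timestamp

    def __post_init__(self):
        if not (self.start < self.split < self.end):
            raise ValueError("need start < split < end")


def phenology_windows(weather: pd.DataFrame, config: PhenologyConfig = PhenologyConfig()) -> dict:
    """Per-year growing-season windows {year: PhenologyWindow}.

    Years in which the temperature threshold is never sustained, or whose
    derived window degenerates, are silently absent from the result (the
    caller can compare against the weather's year range to flag them).
    """
    daily = (
        weather.set_index("timestamp")["tair_c"].resample("1D").mean()
    )
    out = {}
    for year, t in daily.groupby(daily.index.year):
        roll = t.rolling(config.rolling_days).mean()
        ok = (roll >= config.temp_threshold_c).to_numpy()
        # sustained onset: threshold met today and for the next sustain_days-1 days
        sustained = np.array(
            [ok[i : i + config.sustain_days].all() for i in range(len(ok))]
        )
        if not sustained.any() or not ok.any():
            continue
        onset = roll.index[np.argmax(sustained)]
        end = roll.index[len(ok) - 1 - np.argmax(ok[::-1])]
        start = onset + pd.Timedelta(days=config.maturation_lag_days)
        split = start + config.ew_fraction * (end - start)
        try:
            out[int(year)] = PhenologyWindow(start=start, split=split, end=end)
        except ValueError:
            continue
    return out


def rolling_assimilation_mean(series: pd.DataFrame, window_days: int = 24) -> pd.Series:
    """Trailing assimilation-weighted rolling mean of an isotope series.

    ``series`` needs a DatetimeIndex and columns ``value`` and ``weight``
    (the tree-level aggregation denominator per timestep); the mean over
    the trailing window reflects the wood-cell maturation period.  Windows
    with zero total weight yield NaN.
    """
    if window_days <= 0:
        raise ValueError("window must be positive")
    df = series[["value", "weight"]].astype(float).copy()
    df["wv"] = (df["value"] * df["weight"]).fillna(0.0)
    df["w"] = df["weight"].where(df["value"].notna(), 0.0)
    roll = df[["wv", "w"]].rolling(f"{window_days}D").sum()
    with np.errstate(invalid="ignore", divide="ignore"):
        out = roll["wv"] / roll["w"]
    return out.where(roll["w"] > 0)


def ew_lw_means(
    sim: pd.DataFrame,
    windows: Mapping[int, PhenologyWindow],
    quantities: Sequence[str] = QUANTITIES,
) -> pd.DataFrame:
    """Assimilation-weighted means per year and formation period (EW/LW).

    Returns a tidy frame ``year, period, quantity, value_permil, weight``;
    windows with no weighted data are missing rather than zero.
    """
    rows = []
    for year, win in windows.items():
        for period, lo, hi in (("EW", win.start, win.split), ("LW", win.split, win.end)):
            chunk = sim.loc[(sim.index >= lo) & (sim.index < hi)]
            for q in quantities:
                w = chunk["weight"].where(chunk[q].notna(), 0.0)
                wsum = float(w.sum())
                if wsum <= 0:
                    continue
                rows.append(
                    {
                        "year": year,
                        "period": period,
                        "quantity": q,
                        "value_permil": float((chunk[q] * w).sum() / wsum),
                        "weight": wsum,
                    }
                )
    return pd.DataFrame(rows, columns=["year", "period", "quantity", "value_permil", "weight"])


# ---------------------------------------------------------------------------
# harvest-response statistics and model evaluation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HarvestResponse:
    """Difference of mean pre- and post-harvest isotope levels (‰)."""

    pre_mean: float
    post_mean: float
    difference: float  # post_mean - pre_mean
    sd: float
    n_pre: int
    n_post: int


def harvest_response(
    yearly: pd.DataFrame,
    pre_years: Iterable[int],
    post_years: Iterable[int],
    quantity: Optional[str] = None,
    group_col: Optional[str] = None,
) -> HarvestResponse:
    """Harvest response from yearly EW/LW values.

    ``yearly`` is the output of :func:`ew_lw_means` (optionally filtered to
    one quantity, or pass ``quantity=``).  The response is the difference
    post-period mean minus pre-period mean of the yearly formation-period
    values.  When ``group_col`` names a replicate dimension (trees or
    stands), the spread is the standard deviation of per-group differences;
    otherwise it is the standard error of the difference of period means.
    """
    df = yearly if quantity is None else yearly[yearly["quantity"] == quantity]
    pre = df[df["year"].isin(list(pre_years))]["value_permil"]
    post = df[df["year"].isin(list(post_years))]["value_permil"]
    if pre.empty or post.empty:
        raise ValueError("both pre- and post-harvest periods need data")
    if group_col is not None and df[group_col].nunique() > 1:
        diffs = []
        for _, g in df.groupby(group_col):
            gpre = g[g["year"].isin(list(pre_years))]["value_permil"]
            gpost = g[g["year"].isin(list(post_years))]["value_permil"]
            if not gpre.empty and not gpost.empty:
                diffs.append(gpost.mean() - gpre.mean())
        sd = float(np.std(diffs, ddof=1)) if len(diffs) > 1 else float("nan")
    else:
        sd = float(np.sqrt(pre.var(ddof=1) / len(pre) + post.var(ddof=1) / len(post)))
    return HarvestResponse(
        pre_mean=float(pre.mean()),
        post_mean=float(post.mean()),
        difference=float(post.mean() - pre.mean()),
        sd=sd,
        n_pre=len(pre),
        n_post=len(post),
    )


def ks_statistic(sample_a, sample_b):
    """Two-sample Kolmogorov–Smirnov statistic and p-value."""
    res = sps.ks_2samp(np.asarray(sample_a, dtype=float), np.asarray(sample_b, dtype=float))
    return float(res.statistic), float(res.pvalue)


def compare_to_measurements(model: pd.DataFrame, measured: pd.DataFrame) -> dict:
    """R² and residuals of model vs measured values at EW/LW resolution.

    Both frames need ``year, period, value_permil``; pairs missing on
    either side are dropped and counted.  R² is the standard coefficient of
    determination 1 − SS_res/SS_tot of the modeled values against the
    measured ones; results from fewer than 3 pairs are flagged ``low_n``.
    """
    merged = model.merge(
        measured, on=["year", "period"], suffixes=("_model", "_measured")
    ).dropna(subset=["value_permil_model", "value_permil_measured"])
    n_dropped = max(len(model), len(measured)) - len(merged)
    y = merged["value_permil_measured"].to_numpy(dtype=float)
    yhat = merged["value_permil_model"].to_numpy(dtype=float)
    residuals = y - yhat
    ss_tot = float(np.sum((y - y.mean()) ** 2)) if len(y) else float("nan")
    r2 = 1.0 - float(np.sum(residuals**2)) / ss_tot if len(y) and ss_tot > 0 else float("nan")
    return {
        "r2": r2,
        "residuals": residuals,
        "n": len(merged),
        "n_dropped": n_dropped,
        "low_n": len(merged) < 3,
    }


def partition_equal_time(start: pd.Timestamp, end: pd.Timestamp, n: int) -> pd.DatetimeIndex:
    """Assign n intra-ring datapoints equal-time formation dates.

    Divides [start, end) into n equal bins and returns the bin midpoints —
    the dating convention for evenly spaced intra-ring measurements within
    an EW or LW window.
    """
    if n <= 0:
        raise ValueError("need at least one datapoint")
    edges = pd.date_range(start, end, periods=n + 1)
    return pd.DatetimeIndex(edges[:-1] + (edges[1] - edges[0]) / 2)


# ---------------------------------------------------------------------------
# virtual harvest experiment and parameter recovery
# ---------------------------------------------------------------------------

def virtual_harvest_experiment(
    weather: pd.DataFrame,
    grid_pre: CanopyGrid,
    grid_post: CanopyGrid,
    target: TargetTree,
    leaf_params: PhotosynthesisParams = PhotosynthesisParams(),
    micro_params: MicroclimateParams = MicroclimateParams(),
    phenology: PhenologyConfig = PhenologyConfig(),
    c13: iso.Carbon13Constants = iso.Carbon13Constants(),
    o18: iso.Oxygen18Constants = iso.Oxygen18Constants(),
) -> pd.DataFrame:
    """Paired pre-/post-thinning runs of the same tree under identical weather.

    The same target tree and the same forcing stream are run under the
    dense (pre-thinning) and the thinned (post-thinning) canopy, so any
    difference in the tree-level isotope series isolates the change in
    canopy structure.  Returns the tidy yearly EW/LW means with a
    ``treatment`` column (``pre``/``post``).
    """
    windows = phenology_windows(weather, phenology)
    frames = []
    for treatment, grid in (("pre", grid_pre), ("post", grid_post)):
        sim = simulate_isotopes(weather, grid, target, leaf_params, micro_params, c13, o18)
        yearly = ew_lw_means(sim, windows)
        yearly["treatment"] = treatment
        frames.append(yearly)
    return pd.concat(frames, ignore_index=True)


def grid_search_g1_gm(
    observed_delta13c,
    g1_grid,
    gm_grid,
    predict,
    leaf_params: PhotosynthesisParams = PhotosynthesisParams(),
) -> dict:
    """Recover (g1, gm) by grid search against observed Δ¹³C values (‰).

    ``predict`` is a callable taking a :class:`PhotosynthesisParams` and
    returning the model's classical-with-g_m Δ¹³C aligned with
    ``observed_delta13c`` — typically a closure over
    :func:`simulate_isotopes` for tree-level series, or over
    :func:`~isocanopy.leaf_gas_exchange.solve_leaf` for leaf-level states.
    Every (g1, gm) pair on the grid is evaluated by sum of squared errors
    (NaN pairs ignored).  Returns the best pair and the SSE surface.
    """
    obs = np.asarray(observed_delta13c, dtype=float)
    sse = np.full((len(g1_grid), len(gm_grid)), np.inf)
    for i, g1 in enumerate(g1_grid):
        for j, gm in enumerate(gm_grid):
            pred = np.asarray(
                predict(replace(leaf_params, g1=float(g1), gm=float(gm))),
                dtype=float,
            )
            sse[i, j] = float(np.nansum((pred - obs) ** 2))
    i, j = np.unravel_index(np.argmin(sse), sse.shape)
    return {"g1": float(g1_grid[i]), "gm": float(gm_grid[j]), "sse": sse}
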