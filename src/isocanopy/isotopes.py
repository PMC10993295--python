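"""Stable-isotope fractionation models for leaf gas exchange and tree rings.

Carbon: photosynthetic discrimination against 13C (``Delta13C``) predicted
from leaf CO2 mole fractions in three nested variants —

* *simple*:    Delta = a_s + (b' - a_s) * Ci/Ca
* *classical*: full boundary-layer/stomata/mesophyll/carboxylation/
  photorespiration/respiration decomposition with Cc = Ci
* *classical with g_m*: same, with Cc = Ci - An/g_m from a finite mesophyll
  conductance

Oxygen: steady-state leaf-water 18O enrichment above source water from the
Craig–Gordon model, optionally damped by a Péclet factor, plus the
conversions between measured wood delta values and leaf-water enrichment.

All public interfaces use per-mil (‰) units; the 1/1000 bookkeeping is
internal.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

__all__ = [
    "Carbon13Constants",
    "Oxygen18Constants",
    "delta13c_to_discrimination",
    "discrimination_to_delta13c",
    "delta18o_wood_to_leafwater",
    "discrimination_simple",
    "discrimination_classical",
    "kinetic_fractionation",
    "equilibrium_fractionation",
    "peclet_number",
    "peclet_damping",
    "leafwater_enrichment",
    "epsilon_wc",
]


@dataclass(frozen=True)
class Carbon13Constants:
    """Fractionation factors (‰) of the 13C discrimination model.

    a_b, a_s, a_m: diffusional fractionations through the leaf boundary
    layer, the stomata and the mesophyll; b: carboxylation fractionation;
    b_prime: effective carboxylation fractionation of the simple linear
    model; f: photorespiratory fractionation; e: fractionation during
    mitochondrial (dark) respiration.
    """

    a_b: float = 2.9
    a_s: float = 4.4
    a_m: float = 1.8
    b: float = 29.0
    b_prime: float = 27.0
    f: float = 8.0
    e: float = -6.0


@dataclass(frozen=True)
class Oxygen18Constants:
    """Constants of the leaf-water / wood 18O model.

    eps_ks / eps_kb (‰): kinetic fractionation of vapour diffusion through
    stomata / boundary layer.  eps_cp (‰): enrichment offset between whole
    wood and cellulose.  pex_px: proportion of cellulose oxygen exchanged
    with (unenriched) source water.  d18o_source (‰): isotopic composition
    of source (xylem) water.  L (m): effective Péclet mixing length on a
    one-sided leaf-area basis.  C (mol m-3): molar density of liquid water.
    D (m2 s-1): diffusivity of H2(18)O in liquid water.  eps_wc_ref /
    eps_wc_slope: linear temperature response of the biochemical
    water–carbonyl fractionation, eps_wc(T) = ref + slope*(T - 20 °C).
    """

    eps_ks: float = 28.0
    eps_kb: float = 19.0
    eps_cp: float = 3.5
    pex_px: float = 0.4
    d18o_source: float = -10.0
    L: float = 0.015
    C: float = 55.5e3
    D: float = 2.66e-9
    eps_wc_ref: float = 27.0
    eps_wc_slope: float = -0.2


# ---------------------------------------------------------------------------
# delta <-> Delta conversions
# ---------------------------------------------------------------------------

def delta13c_to_discrimination(d13c_wood, d13c_atm):
    """Convert wood and atmospheric delta13C (‰) to discrimination (‰).

    Delta = (delta_atm - delta_wood) / (1 + delta_wood/1000); the
    denominator uses the absolute-fraction form of the wood delta.
    No offset for resin-extracted wood is applied.
    """
    d13c_wood = np.asarray(d13c_wood, dtype=float)
    if np.any(d13c_wood <= -1000.0):
        raise ValueError("delta13C_wood <= -1000 permil is unphysical")
    out = (np.asarray(d13c_atm, dtype=float) - d13c_wood) / (1.0 + d13c_wood / 1000.0)
    return out if out.ndim else float(out)


def discrimination_to_delta13c(delta13c, d13c_atm):
    """Exact inverse of :func:`delta13c_to_discrimination` (all ‰)."""
    delta13c = np.asarray(delta13c, dtype=float)
    d13c_atm = np.asarray(d13c_atm, dtype=float)
    out = (d13c_atm - delta13c) / (1.0 + delta13c / 1000.0)
    return out if out.ndim else float(out)


def epsilon_wc(tair_c, k: Oxygen18Constants = Oxygen18Constants()):
    """Biochemical water–carbonyl 18O fractionation (‰), linear in T (°C)."""
    return k.eps_wc_ref + k.eps_wc_slope * (np.asarray(tair_c, dtype=float) - 20.0)


def delta18o_wood_to_leafwater(
    d18o_wood,
    tair_formation_c,
    k: Oxygen18Constants = Oxygen18Constants(),
    d18o_source=None,
):
    """Back-calculate leaf-water 18O enrichment (‰) from wood delta18O (‰).

    Delta_wood = (delta_wood - delta_s) / (1 + delta_s/1000), then
    Delta_lw = (Delta_wood - eps_wc(T) - eps_cp) / (1 - pex_px), where T is
    the air temperature during wood formation.
    """
    if k.pex_px >= 1.0:
        raise ValueError("pex_px = 1 makes the back-calculation singular")
    ds = k.d18o_source if d18o_source is None else d18o_source
    d18o_wood = np.asarray(d18o_wood, dtype=float)
    delta_wood = (d18o_wood - ds) / (1.0 + ds / 1000.0)
    out = (delta_wood - epsilon_wc(tair_formation_c, k) - k.eps_cp) / (1.0 - k.pex_px)
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# 13C discrimination
# ---------------------------------------------------------------------------

def discrimination_simple(ci_over_ca, k: Carbon13Constants = Carbon13Constants()):
    """Simple linear discrimination model: a_s + (b' - a_s) * Ci/Ca (‰)."""
    x = np.asarray(ci_over_ca, dtype=float)
    out = k.a_s + (k.b_prime - k.a_s) * x
    return out if out.ndim else float(out)


def discrimination_classical(
    leaf,
    k: Carbon13Constants = Carbon13Constants(),
    use_gm: bool = True,
):
    """Full 13C discrimination (‰) from a converged leaf gas-exchange state.

    Evaluates the six-term decomposition

        Delta = a_b (Ca-Cs)/Ca + a_s (Cs-Ci)/Ca + a_m (Ci-Cc)/Ca
                + b Cc/Ca - f Gamma*/Ca - e r_d/(kc Ca)

    with carboxylation efficiency kc = (An + r_d)/(Cc - Gamma*).  With
    ``use_gm=False`` the mesophyll drawdown is neglected (Cc := Ci, the
    classical variant); otherwise the solver-provided Cc = Ci - An/g_m is
    used.  States with Cc <= Gamma* (kc undefined) yield NaN so that the
    aggregation stage can drop them; the sign convention keeps the
    respiration term positive for e = -6‰.
    """
    ca = np.asarray(leaf.ca, dtype=float)
    cs = np.asarray(leaf.cs, dtype=float)
    ci = np.asarray(leaf.ci, dtype=float)
    cc = np.asarray(leaf.cc if use_gm else leaf.ci, dtype=float)
    gamma_star = np.asarray(leaf.gamma_star, dtype=float)
    an = np.asarray(leaf.an, dtype=float)
    rd = np.asarray(leaf.rd, dtype=float)

    with np.errstate(divide="ignore", invalid="ignore"):
        kc = (an + rd) / (cc - gamma_star)
        delta = (
            k.a_b * (ca - cs) / ca
            + k.a_s * (cs - ci) / ca
            + k.a_m * (ci - cc) / ca
            + k.b * cc / ca
            - k.f * gamma_star / ca
            - k.e * rd / (kc * ca)
        )
        delta = np.where((cc > gamma_star) & (kc > 0), delta, np.nan)
    return delta if delta.ndim else float(delta)


# ---------------------------------------------------------------------------
# 18O enrichment
# ---------------------------------------------------------------------------

def kinetic_fractionation(gs_h2o, gb_h2o, k: Oxygen18Constants = Oxygen18Constants()):
    """Kinetic 18O fractionation (‰) of vapour diffusing out of the leaf.

    Conductance-weighted mixture eps_k = (g_b eps_ks + g_s eps_kb) /
    (g_b + g_s): a leaf limited by stomata (g_b >> g_s) expresses the
    stomatal value, a leaf limited by its boundary layer the laminar value.
    """
    gs = np.asarray(gs_h2o, dtype=float)
    gb = np.asarray(gb_h2o, dtype=float)
    tot = gs + gb
    if np.any(tot <= 0):
        raise ValueError("gs + gb must be positive")
    out = (gb * k.eps_ks + gs * k.eps_kb) / tot
    return out if out.ndim else float(out)


def equilibrium_fractionation(tleaf_c):
    """Equilibrium liquid–vapour 18O fractionation eps+ (‰).

    Closed form in inverse absolute temperature,
    eps+ = 2.644 - 3.206 (10^3/T) + 1.534 (10^6/T^2); ~9.6‰ at 20 °C,
    decreasing with temperature.
    """
    t_k = np.asarray(tleaf_c, dtype=float) + 273.15
    out = 2.644 - 3.206 * (1.0e3 / t_k) + 1.534 * (1.0e6 / t_k**2)
    return out if out.ndim else float(out)


def peclet_number(e_mol, k: Oxygen18Constants = Oxygen18Constants()):
    """Péclet number EL/(CD) for transpiration E (mol m-2 s-1)."""
    out = np.asarray(e_mol, dtype=float) * k.L / (k.C * k.D)
    return out if out.ndim else float(out)


def peclet_damping(peclet):
    """Damping factor f1 = (1 - exp(-P))/P, with the P -> 0 limit f1 = 1."""
    p = np.asarray(peclet, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        f1 = np.where(p > 1e-12, -np.expm1(-p) / np.where(p > 1e-12, p, 1.0), 1.0)
    return f1 if f1.ndim else float(f1)


def leafwater_enrichment(
    leaf,
    w_a,
    model: Literal["craig_gordon", "peclet"] = "peclet",
    k: Oxygen18Constants = Oxygen18Constants(),
):
    """Steady-state leaf-water 18O enrichment above source water (‰).

    Delta18O_lw = f1 [eps+ + eps_k] (1 - w_a/w_i), assuming the ambient
    vapour is in isotopic equilibrium with source water
    (Delta18O_vapour = -eps+).  ``model`` selects f1 = 1 (Craig–Gordon) or
    the Péclet damping f1 = (1-exp(-P))/P with P = E L/(C D); the Péclet
    value never exceeds the Craig–Gordon value and converges to it as the
    transpiration rate E -> 0.
    """
    w_i = np.asarray(leaf.w_i, dtype=float)
    if np.any(w_i <= 0):
        raise ValueError("leaf-internal vapour mole fraction must be positive")
    eps_plus = equilibrium_fractionation(leaf.tleaf)
    eps_k = kinetic_fractionation(leaf.gs_h2o, leaf.gb_h2o, k)
    cg = (eps_plus + eps_k) * (1.0 - np.asarray(w_a, dtype=float) / w_i)
    if model == "craig_gordon":
        out = cg
    elif model == "peclet":
        out = peclet_damping(peclet_number(np.maximum(leaf.e, 0.0), k)) * cg
    else:
        raise ValueError(f"unknown leaf-water model {model!r}")
    return out if np.ndim(out) else float(out)
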