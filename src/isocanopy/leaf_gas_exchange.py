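"""Coupled leaf gas exchange: FvCB photosynthesis, Medlyn stomata, diffusion.

Net assimilation follows the Farquhar–von Caemmerer–Berry (FvCB) model with
smooth co-limitation of the Rubisco- and RuBP-regeneration-limited rates,
Arrhenius/peaked-Arrhenius temperature adjustment of the kinetic constants
and temperature-dependent mitochondrial respiration.  Stomatal conductance
for CO2 follows the unified (Medlyn) optimal model

    g_s = g0 + (1 + g1/sqrt(D_l)) * A_n / C_s

and CO2 supply runs through the boundary-layer / stomatal / (optional)
mesophyll conductance chain

    A_n = g_b (C_a - C_s) = g_s (C_s - C_i) = g_m (C_i - C_c).

The coupled system is closed by a bisection on A_n (the residual
``FvCB(C_c(A_n)) - A_n`` is strictly decreasing in A_n, so the root is
unique); all functions accept scalars or numpy arrays and solve every
element simultaneously.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np

from .microclimate import saturation_vapour_pressure

__all__ = [
    "PhotosynthesisParams",
    "LeafState",
    "fvcb_assimilation",
    "medlyn_gs",
    "boundary_layer_conductance",
    "solve_leaf",
]

R_GAS = 8.314  # J mol-1 K-1
T_REF = 298.15  # K

# g_s(H2O)/g_s(CO2) and g_b(H2O)/g_b(CO2) diffusivity ratios
GSW_OVER_GSC = 1.6
GBW_OVER_GBC = 1.37


@dataclass(frozen=True)
class PhotosynthesisParams:
    """Photosynthesis and water-use parameters of a (conifer) leaf.

    Capacity defaults are typical of boreal Norway spruce shade foliage and
    are configurable, not calibrated quantities.  ``gm`` may be ``inf`` to
    disable the mesophyll resistance.  Temperature-response constants
    (activation energies Ha, deactivation Hd and entropy dS) follow widely
    used tabulations for C3 leaves; all are exposed so a user can substitute
    species-specific values.
    """

    vcmax25: float = 60.0   # µmol m-2 s-1, maximum carboxylation rate at 25 °C
    jmax25: float = 114.0   # µmol m-2 s-1, maximum electron transport at 25 °C
    alpha: float = 0.24     # mol e- (mol photons)-1, quantum yield
    theta: float = 0.7      # curvature of the light response (0, 1]
    colim_theta: float = 0.98  # curvature of Ac/Aj co-limitation (0, 1]
    rd25: float = 1.0       # µmol m-2 s-1, dark respiration at 25 °C
    g0: float = 1e-3        # mol m-2 s-1, residual stomatal conductance (CO2)
    g1: float = 2.3         # kPa^0.5, Medlyn slope ~ marginal water-use efficiency
    gm: float = 0.1         # mol m-2 s-1, mesophyll conductance (inf allowed)
    dl_floor: float = 0.05  # kPa, floor on leaf-to-air VPD (g1/sqrt(Dl) singularity)
    # kinetic constants at 25 °C
    kc25: float = 404.9     # µmol mol-1, Michaelis constant for CO2
    ko25: float = 278.4     # mmol mol-1, Michaelis constant for O2
    gamma_star25: float = 42.75  # µmol mol-1, photorespiratory compensation point
    o2: float = 210.0       # mmol mol-1, atmospheric O2
    # activation energies (J mol-1)
    ha_vcmax: float = 72000.0
    ha_jmax: float = 50000.0
    ha_kc: float = 79430.0
    ha_ko: float = 36380.0
    ha_gamma_star: float = 37830.0
    ha_rd: float = 46390.0
    # peaked-response deactivation for Vcmax/Jmax
    hd: float = 200000.0    # J mol-1
    ds_vcmax: float = 649.0  # J mol-1 K-1
    ds_jmax: float = 646.0   # J mol-1 K-1
    # boundary layer
    gb_coeff: float = 0.223  # mol m-2 s-1 per sqrt(m s-1 / m)
    leaf_dimension: float = 0.01  # m, characteristic needle/shoot dimension
    wind_floor: float = 0.2  # m s-1, free-convection floor on wind speed

    def __post_init__(self):
        if not (0.0 < self.theta <= 1.0) or not (0.0 < self.colim_theta <= 1.0):
            raise ValueError("curvature parameters must lie in (0, 1]")
        if self.gm <= 0:
            raise ValueError("gm must be positive (use inf for no mesophyll resistance)")


@dataclass
class LeafState:
    """Converged gas-exchange state of one leaf class (scalars or arrays)."""

    an: np.ndarray          # µmol m-2 s-1, net assimilation
    rd: np.ndarray          # µmol m-2 s-1, dark respiration
    gamma_star: np.ndarray  # µmol mol-1
    gs_co2: np.ndarray      # mol m-2 s-1
    gs_h2o: np.ndarray
    gb_co2: np.ndarray
    gb_h2o: np.ndarray
    ca: np.ndarray          # µmol mol-1, canopy-air CO2
    cs: np.ndarray          # µmol mol-1, leaf surface
    ci: np.ndarray          # µmol mol-1, intercellular
    cc: np.ndarray          # µmol mol-1, chloroplast
    dl: np.ndarray          # kPa, leaf-to-air vapour pressure deficit
    tleaf: np.ndarray       # °C
    e: np.ndarray           # mol m-2 s-1, transpiration
    w_i: np.ndarray         # mol mol-1, leaf-internal vapour mole fraction
    converged: np.ndarray   # bool, demand/supply residual below tolerance

    @property
    def k_carbox(self):
        """Carboxylation efficiency (A_n + r_d)/(C_c - Gamma*)."""
        with np.errstate(divide="ignore", invalid="ignore"):
            return (self.an + self.rd) / (self.cc - self.gamma_star)


def _arrhenius(k25, ha, t_k):
    return k25 * np.exp(ha / R_GAS * (1.0 / T_REF - 1.0 / t_k))


def _peaked(k25, ha, hd, ds, t_k):
    num = 1.0 + np.exp((ds * T_REF - hd) / (R_GAS * T_REF))
    den = 1.0 + np.exp((ds * t_k - hd) / (R_GAS * t_k))
    return _arrhenius(k25, ha, t_k) * num / den


def _smaller_root(a, b, c):
    """Smaller root of a x^2 - b x + c = 0 (a in (0,1], b,c >= 0)."""
    disc = np.maximum(b * b - 4.0 * a * c, 0.0)
    return (b - np.sqrt(disc)) / (2.0 * a)


def fvcb_assimilation(cc, par, tleaf, p: PhotosynthesisParams) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """FvCB net assimilation at chloroplast CO2 ``cc`` (µmol mol-1).

    Returns ``(an, rd, gamma_star)`` (µmol m-2 s-1, ‰-free).  The gross rate
    is the smaller root of the co-limitation quadratic of the
    Rubisco-limited rate Ac = Vcmax (Cc - Γ*)/(Cc + Kc(1 + O/Ko)) and the
    RuBP-regeneration-limited rate Aj = J (Cc - Γ*)/(4 Cc + 8 Γ*), with J
    itself the smaller root of the θ-quadratic light response of electron
    transport.  Vcmax and Jmax use a peaked Arrhenius temperature response,
    Kc, Ko, Γ* and r_d a plain Arrhenius one.
    """
    cc = np.asarray(cc, dtype=float)
    par = np.asarray(par, dtype=float)
    if np.any(cc <= 0):
        raise ValueError("chloroplast CO2 must be positive")
    t_k = np.asarray(tleaf, dtype=float) + 273.15

    vcmax = _peaked(p.vcmax25, p.ha_vcmax, p.hd, p.ds_vcmax, t_k)
    jmax = _peaked(p.jmax25, p.ha_jmax, p.hd, p.ds_jmax, t_k)
    kc = _arrhenius(p.kc25, p.ha_kc, t_k)
    ko = _arrhenius(p.ko25, p.ha_ko, t_k)
    gamma_star = _arrhenius(p.gamma_star25, p.ha_gamma_star, t_k)
    rd = _arrhenius(p.rd25, p.ha_rd, t_k)

    km = kc * (1.0 + p.o2 / ko)
    ac = vcmax * (cc - gamma_star) / (cc + km)
    j = _smaller_root(p.theta, p.alpha * par + jmax, p.alpha * par * jmax)
    aj = j * (cc - gamma_star) / (4.0 * cc + 8.0 * gamma_star)
    # co-limitation: smooth minimum of Ac and Aj; exact at par = 0 (Aj = 0)
    gross = np.where(
        (ac > 0) & (aj > 0),
        _smaller_root(p.colim_theta, ac + aj, ac * aj),
        np.minimum(ac, aj),
    )
    an = gross - rd
    return an, rd * np.ones_like(an), gamma_star * np.ones_like(an)


def medlyn_gs(an, cs, dl, g0, g1, dl_floor: float = 0.05):
    """Unified stomatal model conductance for CO2 (mol m-2 s-1).

    g_s = g0 + (1 + g1/sqrt(D_l)) A_n/C_s for A_n > 0, else the residual
    conductance g0; D_l (kPa) is floored to avoid the square-root
    singularity at vapour saturation.
    """
    cs = np.asarray(cs, dtype=float)
    if np.any(cs <= 0):
        raise ValueError("leaf-surface CO2 must be positive")
    an = np.asarray(an, dtype=float)
    dl = np.maximum(np.asarray(dl, dtype=float), dl_floor)
    gs = g0 + (1.0 + g1 / np.sqrt(dl)) * an / cs
    out = np.where(an > 0, np.maximum(gs, g0), g0)
    return out if out.ndim else float(out)


def boundary_layer_conductance(wind, p: PhotosynthesisParams) -> Tuple[np.ndarray, np.ndarray]:
    """Leaf boundary-layer conductance for H2O and CO2 (mol m-2 s-1).

    Forced-convection square-root law gb = a sqrt(u/d) for characteristic
    dimension d, with a floor on wind speed standing in for free
    convection in still air.
    """
    if p.leaf_dimension <= 0:
        raise ValueError("leaf dimension must be positive")
    u = np.maximum(np.asarray(wind, dtype=float), p.wind_floor)
    gb_h2o = p.gb_coeff * np.sqrt(u / p.leaf_dimension)
    return gb_h2o, gb_h2o / GBW_OVER_GBC


def _demand_an(an, ca, dl, gb_co2, par, tleaf, p: PhotosynthesisParams):
    """FvCB assimilation implied by trial net assimilation ``an``.

    Walks the diffusion chain Cs, gs, Ci, Cc for the trial ``an`` and
    re-evaluates FvCB at the resulting Cc.  Returns (an_new, cs, gs, ci, cc,
    rd, gamma_star).
    """
    cs = np.maximum(ca - an / gb_co2, 1.0)
    gs = medlyn_gs(an, cs, dl, p.g0, p.g1, p.dl_floor)
    ci = np.maximum(cs - an / gs, 1e-3)
    if np.isfinite(p.gm):
        cc = np.maximum(ci - an / p.gm, 1e-3)
    else:
        cc = ci
    an_new, rd, gamma_star = fvcb_assimilation(cc, par, tleaf, p)
    return an_new, cs, gs, ci, cc, rd, gamma_star


def solve_leaf(
    par,
    tleaf,
    wind,
    co2_ppm,
    w_a,
    pressure_kpa,
    p: PhotosynthesisParams = PhotosynthesisParams(),
    tol: float = 1e-9,
    max_iter: int = 80,
) -> LeafState:
    """Solve the coupled leaf for scalar or array drivers.

    Drivers: absorbed PAR (µmol m-2 s-1), leaf temperature (°C), wind speed
    (m s-1), canopy-air CO2 (µmol mol-1), atmospheric vapour mole fraction
    w_a (mol mol-1) and pressure (kPa); all broadcast together.

    The solution is a bracketed bisection on A_n — the residual
    demand(A_n) - A_n is strictly decreasing, so the fixed point is unique
    and every converged element satisfies the supply/demand flux identities
    exactly by construction (Cs, Ci, Cc are derived from the final A_n).
    In darkness the root is A_n = -r_d and Ci rises above Ca, the leaf
    acting as a respiratory CO2 source.
    """
    par, tleaf, wind, ca, w_a, press = np.broadcast_arrays(
        *(np.asarray(x, dtype=float) for x in (par, tleaf, wind, co2_ppm, w_a, pressure_kpa))
    )
    scalar = par.ndim == 0
    par, tleaf, wind, ca, w_a, press = (
        np.atleast_1d(a).astype(float) for a in (par, tleaf, wind, ca, w_a, press)
    )

    w_i = saturation_vapour_pressure(tleaf) / press
    dl = np.maximum(saturation_vapour_pressure(tleaf) - w_a * press, p.dl_floor)
    gb_h2o, gb_co2 = boundary_layer_conductance(wind, p)

    # respiration at leaf temperature bounds the bracket from below,
    # Vcmax at leaf temperature from above
    t_k = tleaf + 273.15
    rd_t = _arrhenius(p.rd25, p.ha_rd, t_k)
    vcmax_t = _peaked(p.vcmax25, p.ha_vcmax, p.hd, p.ds_vcmax, t_k)
    lo = -rd_t - 1.0
    hi = vcmax_t + 1.0

    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        an_new, *_ = _demand_an(mid, ca, dl, gb_co2, par, tleaf, p)
        high = an_new > mid  # residual positive -> root is above mid
        lo = np.where(high, mid, lo)
        hi = np.where(high, hi, mid)

    an = 0.5 * (lo + hi)
    an_new, cs, gs_co2, ci, cc, rd, gamma_star = _demand_an(
        an, ca, dl, gb_co2, par, tleaf, p
    )
    # keep the supply-side an: Cs, Ci, Cc derive from it, so the diffusion
    # identities hold exactly; the FvCB side agrees to within the bracket width
    converged = np.abs(an_new - an) <= tol * np.maximum(1.0, np.abs(an))

    gs_h2o = GSW_OVER_GSC * gs_co2
    g_tot_h2o = 1.0 / (1.0 / gs_h2o + 1.0 / gb_h2o)
    e = g_tot_h2o * (w_i - w_a)

    def _maybe_scalar(x):
        return x[0] if scalar else x

    return LeafState(
        an=_maybe_scalar(an),
        rd=_maybe_scalar(rd),
        gamma_star=_maybe_scalar(gamma_star),
        gs_co2=_maybe_scalar(gs_co2),
        gs_h2o=_maybe_scalar(gs_h2o),
        gb_co2=_maybe_scalar(gb_co2 * np.ones_like(an)),
        gb_h2o=_maybe_scalar(gb_h2o * np.ones_like(an)),
        ca=_maybe_scalar(ca),
        cs=_maybe_scalar(cs),
        ci=_maybe_scalar(ci),
        cc=_maybe_scalar(cc),
        dl=_maybe_scalar(dl),
        tleaf=_maybe_scalar(tleaf),
        e=_maybe_scalar(e),
        w_i=_maybe_scalar(w_i),
        converged=_maybe_scalar(converged),
    )
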