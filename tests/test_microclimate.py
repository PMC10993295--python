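"""Canopy microclimate: attenuation oracles, profile shapes, thinning response."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from isocanopy import microclimate as mc
from isocanopy.stand_structure import CanopyGrid, SPECIES


def uniform_grid(lai_total: float, n_layers: int = 100, top: float = 27.0) -> CanopyGrid:
    edges = np.linspace(0.0, top, n_layers + 1)
    dz = edges[1] - edges[0]
    lad = np.zeros((n_layers, len(SPECIES)))
    lad[:, 1] = lai_total / top  # all spruce, uniform
    return CanopyGrid(z=0.5 * (edges[:-1] + edges[1:]), dz=dz, lad=lad)


def met_record(**kw):
    rec = dict(
        timestamp=pd.Timestamp("2012-07-01 12:00"),
        tair_c=20.0, rh_pct=50.0, par_dir_umol=900.0, par_dif_umol=300.0,
        wind_ms=3.0, pressure_kpa=101.3, co2_ppm=400.0, solar_elev_deg=45.0,
    )
    rec.update(kw)
    return rec


class TestSaturationVapour:
    def test_magnus_reference_point(self):
        # ~2.33 kPa at 20 °C
        assert mc.saturation_vapour_pressure(20.0) == pytest.approx(2.33, abs=0.01)

    def test_vapour_mole_fraction_oracle(self):
        w_a = mc.vapour_mole_fraction(50.0, 20.0, 101.3)
        assert w_a == pytest.approx(0.5 * mc.saturation_vapour_pressure(20.0) / 101.3,
                                    rel=1e-12)
        assert w_a == pytest.approx(0.0115, abs=2e-4)


class TestSolarElevation:
    def test_midsummer_noon_boreal(self):
        elev = mc.solar_elevation(pd.Timestamp("2012-06-21 12:00"), 60.6)
        assert elev == pytest.approx(90.0 - 60.6 + 23.45, abs=1.0)

    def test_midnight_below_horizon(self):
        assert mc.solar_elevation(pd.Timestamp("2012-03-21 00:00"), 60.6) < 0

    def test_invalid_latitude(self):
        with pytest.raises(ValueError):
            mc.solar_elevation(pd.Timestamp("2012-06-21 12:00"), 95.0)


class TestAttenuation:
    def test_top_of_canopy_unattenuated(self):
        grid = uniform_grid(0.0)
        par_sl, par_sh, f_sl = mc.attenuate_radiation(met_record(), grid)
        assert np.all(f_sl == pytest.approx(1.0))
        assert np.all(par_sh == pytest.approx(300.0))

    def test_beer_lambert_oracle_overhead_sun(self):
        """f_sunlit = exp(−0.5·4/sin 90°) = e⁻² under LAI 4 of overlying leaf."""
        grid = uniform_grid(8.0)  # LAI above the mid-canopy layer ≈ 4
        met = met_record(solar_elev_deg=90.0)
        _, _, f_sl = mc.attenuate_radiation(met, grid)
        lai_above = mc._lai_above(grid)
        idx = int(np.argmin(np.abs(lai_above - 4.0)))
        assert f_sl[idx] == pytest.approx(np.exp(-0.5 * lai_above[idx]), rel=1e-9)
        assert f_sl[idx] == pytest.approx(np.exp(-2.0), abs=5e-3)

    def test_night_is_dark(self):
        grid = uniform_grid(5.0)
        par_sl, par_sh, f_sl = mc.attenuate_radiation(
            met_record(solar_elev_deg=-5.0), grid
        )
        assert np.all(par_sl == 0) and np.all(par_sh == 0) and np.all(f_sl == 0)

    def test_negative_extinction_rejected(self):
        with pytest.raises(ValueError):
            mc.MicroclimateParams(k_beam=-0.1)

    def test_absorbed_never_exceeds_incident(self):
        grid = uniform_grid(6.0)
        for elev in (5.0, 25.0, 60.0):
            met = met_record(solar_elev_deg=elev)
            absorbed = mc.absorbed_par_total(met, grid)
            assert 0.0 < absorbed <= met["par_dir_umol"] + met["par_dif_umol"]


class TestProfiles:
    def test_transparent_canopy_equals_forcing(self):
        grid = uniform_grid(0.0)
        prof = mc.profile_state(met_record(), grid)
        assert np.allclose(prof.wind, 3.0)
        assert np.allclose(prof.rh, 50.0)
        assert np.allclose(prof.tair, 20.0)

    def test_zero_gamma_keeps_needles_at_air_temperature(self):
        grid = uniform_grid(5.0)
        params = mc.MicroclimateParams(needle_dt_max=0.0)
        prof = mc.profile_state(met_record(), grid, params)
        assert np.allclose(prof.tneedle_sunlit, prof.tair)
        assert np.allclose(prof.tneedle_shaded, prof.tair)

    def test_profile_shape_invariants(self):
        grid = uniform_grid(5.3)
        prof = mc.profile_state(met_record(), grid)
        assert np.all(prof.par_shaded <= prof.par_sunlit + 1e-12)
        assert np.all((prof.f_sunlit >= 0) & (prof.f_sunlit <= 1))
        # z increases upward: sunlit fraction and wind decrease downward
        assert np.all(np.diff(prof.f_sunlit) >= 0)
        assert np.all(np.diff(prof.wind) >= 0)
        assert np.all(np.diff(prof.rh) <= 1e-12)

    def test_thinning_brightens_and_dries_bottom(self):
        met = met_record()
        dense = mc.profile_state(met, uniform_grid(5.3))
        thinned = mc.profile_state(met, uniform_grid(2.6))
        assert thinned.f_sunlit[0] > dense.f_sunlit[0]
        assert thinned.par_sunlit[0] > dense.par_sunlit[0]
        assert thinned.wind[0] > dense.wind[0]
        assert thinned.rh[0] <= dense.rh[0]
        # formerly shaded bottom needles warm by about a degree
        mean_dense = (
            dense.f_sunlit[0] * dense.tneedle_sunlit[0]
            + (1 - dense.f_sunlit[0]) * dense.tneedle_shaded[0]
        )
        mean_thin = (
            thinned.f_sunlit[0] * thinned.tneedle_sunlit[0]
            + (1 - thinned.f_sunlit[0]) * thinned.tneedle_shaded[0]
        )
        assert 0.3 < mean_thin - mean_dense < 1.7

    def test_deterministic(self):
        grid = uniform_grid(4.0)
        a = mc.profile_state(met_record(), grid)
        b = mc.profile_state(met_record(), grid)
        assert np.array_equal(a.par_sunlit, b.par_sunlit)
        assert np.array_equal(a.w_a, b.w_a)
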