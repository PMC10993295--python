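"""Leaf gas exchange: component oracles, solver consistency, monotonicity."""

import dataclasses

import numpy as np
import pytest

from isocanopy import leaf_gas_exchange as lg


class TestFvCB:
    def test_dark_respiration_only(self, leaf_params):
        an, rd, _ = lg.fvcb_assimilation(300.0, 0.0, 20.0, leaf_params)
        assert an == pytest.approx(-rd, abs=1e-12)

    def test_compensation_point_zero_gross(self, leaf_params):
        _, rd, gamma_star = lg.fvcb_assimilation(300.0, 2000.0, 25.0, leaf_params)
        an, rd2, _ = lg.fvcb_assimilation(float(gamma_star), 2000.0, 25.0, leaf_params)
        assert an == pytest.approx(-rd2, abs=1e-9)

    def test_rubisco_limited_branch_hand_oracle(self):
        """Ac = Vcmax (Cc − Γ*)/(Cc + Km) = 60·260/1000 = 15.6 with the
        co-limitation collapsing to Ac when Aj is far larger."""
        p = lg.PhotosynthesisParams(
            vcmax25=60.0, jmax25=1e5, rd25=1.0,
            kc25=404.9, ko25=278.4, gamma_star25=42.75,
            ha_vcmax=0.0, ha_jmax=0.0, ha_kc=0.0, ha_ko=0.0,
            ha_gamma_star=0.0, ha_rd=0.0, ds_vcmax=0.0, ds_jmax=0.0, hd=1e9,
        )
        # force Km = 700 and Γ* = 40 by picking kc/ko/gamma at 25 °C
        p = dataclasses.replace(p, kc25=700.0 / (1.0 + 210.0 / 278.4), gamma_star25=40.0)
        an, rd, _ = lg.fvcb_assimilation(300.0, 1e6, 25.0, p)
        assert an == pytest.approx(15.6 - 1.0, abs=0.01)

    def test_nonpositive_cc_rejected(self, leaf_params):
        with pytest.raises(ValueError):
            lg.fvcb_assimilation(0.0, 500.0, 20.0, leaf_params)


class TestMedlyn:
    def test_zero_assimilation_returns_residual(self):
        assert lg.medlyn_gs(0.0, 400.0, 1.0, g0=1e-3, g1=2.3) == pytest.approx(1e-3)

    def test_worked_value(self):
        # 0.001 + (1 + 2.3/1)·10/400
        got = lg.medlyn_gs(10.0, 400.0, 1.0, g0=1e-3, g1=2.3)
        assert got == pytest.approx(0.001 + 3.3 * 10.0 / 400.0, abs=1e-12)

    def test_decreasing_in_vpd(self):
        lo = lg.medlyn_gs(10.0, 400.0, 0.5, 1e-3, 2.3)
        hi = lg.medlyn_gs(10.0, 400.0, 2.0, 1e-3, 2.3)
        assert hi < lo

    def test_nonpositive_cs_rejected(self):
        with pytest.raises(ValueError):
            lg.medlyn_gs(10.0, 0.0, 1.0, 1e-3, 2.3)


class TestBoundaryLayer:
    def test_square_root_law(self, leaf_params):
        g1, _ = lg.boundary_layer_conductance(1.0, leaf_params)
        g4, _ = lg.boundary_layer_conductance(4.0, leaf_params)
        assert g4 == pytest.approx(2.0 * g1, rel=1e-12)

    def test_worked_value(self):
        p = lg.PhotosynthesisParams(gb_coeff=0.223, leaf_dimension=0.01)
        gb_h2o, gb_co2 = lg.boundary_layer_conductance(2.0, p)
        assert gb_h2o == pytest.approx(0.223 * np.sqrt(200.0), rel=1e-12)
        assert gb_co2 == pytest.approx(gb_h2o / 1.37, rel=1e-12)

    def test_still_air_floor(self, leaf_params):
        g0, _ = lg.boundary_layer_conductance(0.0, leaf_params)
        gfloor, _ = lg.boundary_layer_conductance(leaf_params.wind_floor, leaf_params)
        assert g0 == pytest.approx(gfloor)


class TestSolveLeaf:
    def args(self, **kw):
        base = dict(par=800.0, tleaf=20.0, wind=2.0, co2_ppm=400.0,
                    w_a=0.012, pressure_kpa=101.3)
        base.update(kw)
        return base

    def test_flux_consistency_at_solution(self, leaf_params):
        st = lg.solve_leaf(**self.args(), p=leaf_params)
        assert bool(st.converged)
        assert abs(st.gb_co2 * (st.ca - st.cs) - st.gs_co2 * (st.cs - st.ci)) < 1e-9 * abs(st.an)
        assert abs(st.gs_co2 * (st.cs - st.ci) - st.an) < 1e-9 * abs(st.an)
        assert abs(leaf_params.gm * (st.ci - st.cc) - st.an) < 1e-9 * abs(st.an)

    def test_ordering_of_co2_levels_in_light(self, leaf_params):
        st = lg.solve_leaf(**self.args(), p=leaf_params)
        assert st.an > 0
        assert st.cc < st.ci < st.cs < st.ca
        assert st.gs_h2o == pytest.approx(1.6 * st.gs_co2, rel=1e-12)

    def test_dark_leaf_is_co2_source(self, leaf_params):
        st = lg.solve_leaf(**self.args(par=0.0), p=leaf_params)
        assert st.an == pytest.approx(-st.rd, abs=1e-6)
        assert st.ci > st.ca

    def test_infinite_gm_collapses_cc_to_ci(self, leaf_params):
        p = dataclasses.replace(leaf_params, gm=np.inf)
        st = lg.solve_leaf(**self.args(), p=p)
        assert st.cc == pytest.approx(st.ci, abs=1e-12)

    def test_monotone_in_par_and_humidity(self, leaf_params):
        pars = np.array([100.0, 300.0, 600.0, 1200.0])
        st = lg.solve_leaf(**self.args(par=pars), p=leaf_params)
        assert np.all(np.diff(st.an) > 0)
        assert np.all(np.diff(st.ci / st.ca) < 0)
        # moister air (higher w_a → lower Dl) raises ci/ca
        was = np.array([0.006, 0.010, 0.014, 0.018])
        st2 = lg.solve_leaf(**self.args(w_a=was), p=leaf_params)
        assert np.all(np.diff(st2.ci / st2.ca) > 0)

    def test_matches_dense_ci_scan(self, leaf_params):
        """The bisection solution agrees with a brute-force 1-D scan over Ci
        minimizing |supply − demand| on a coarse driver grid."""
        from isocanopy.microclimate import saturation_vapour_pressure

        for par in (50.0, 400.0, 1500.0):
            for w_a in (0.008, 0.015):
                for tleaf in (10.0, 25.0):
                    st = lg.solve_leaf(**self.args(par=par, w_a=w_a, tleaf=tleaf),
                                       p=leaf_params)
                    ci_grid = np.linspace(1.0, 1200.0, 24001)
                    dl = max(saturation_vapour_pressure(tleaf) - w_a * 101.3,
                             leaf_params.dl_floor)
                    gb_h2o, gb_co2 = lg.boundary_layer_conductance(2.0, leaf_params)
                    # demand side at each trial ci
                    cc = ci_grid.copy()
                    for _ in range(200):
                        an_d, _, _ = lg.fvcb_assimilation(np.maximum(cc, 1e-3), par,
                                                          tleaf, leaf_params)
                        cc = ci_grid - an_d / leaf_params.gm
                    an_d, _, _ = lg.fvcb_assimilation(np.maximum(cc, 1e-3), par,
                                                      tleaf, leaf_params)
                    cs = 400.0 - an_d / gb_co2
                    gs = lg.medlyn_gs(an_d, cs, dl, leaf_params.g0, leaf_params.g1,
                                      leaf_params.dl_floor)
                    supply = gs * (cs - ci_grid)
                    best = ci_grid[np.argmin(np.abs(supply - an_d))]
                    assert st.ci == pytest.approx(best, abs=2 * (ci_grid[1] - ci_grid[0]))

    def test_scalar_and_array_paths_agree(self, leaf_params):
        scalar = lg.solve_leaf(**self.args(), p=leaf_params)
        arr = lg.solve_leaf(**self.args(par=np.array([800.0])), p=leaf_params)
        assert arr.an[0] == pytest.approx(float(scalar.an), abs=1e-12)
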