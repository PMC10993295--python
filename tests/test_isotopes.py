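"""Fractionation mathematics: worked values, limits, round trips, bounds."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from isocanopy import isotopes as iso


class TestDeltaConversions:
    def test_equal_deltas_give_zero_discrimination(self):
        assert iso.delta13c_to_discrimination(-8.5, -8.5) == pytest.approx(0.0)

    def test_worked_conversion(self):
        # (−8.5 + 28)/(1 − 0.028) = 19.5/0.972
        assert iso.delta13c_to_discrimination(-28.0, -8.5) == pytest.approx(
            19.5 / 0.972, abs=1e-9
        )

    def test_unphysical_wood_delta_rejected(self):
        with pytest.raises(ValueError):
            iso.delta13c_to_discrimination(-1000.0, -8.5)

    @given(
        delta=st.floats(-50.0, 50.0),
        atm=st.floats(-12.0, -6.0),
    )
    @settings(deadline=None, max_examples=200)
    def test_round_trip_exact(self, delta, atm):
        wood = iso.discrimination_to_delta13c(delta, atm)
        back = iso.delta13c_to_discrimination(wood, atm)
        assert back == pytest.approx(delta, abs=1e-12)

    def test_wood_to_leafwater_worked_values(self):
        k = iso.Oxygen18Constants()
        # Delta_wood = (25 − (−10))/(1 − 0.010) = 35/0.99
        # at 20 °C eps_wc = 27 → (35.354 − 30.5)/0.6
        expected_wood = 35.0 / 0.99
        out = iso.delta18o_wood_to_leafwater(25.0, tair_formation_c=20.0, k=k)
        assert out == pytest.approx((expected_wood - 27.0 - 3.5) / 0.6, abs=1e-9)

    def test_wood_to_leafwater_degenerate_constants(self):
        k = iso.Oxygen18Constants(pex_px=0.0, eps_cp=0.0, eps_wc_ref=0.0, eps_wc_slope=0.0)
        out = iso.delta18o_wood_to_leafwater(25.0, 20.0, k=k)
        assert out == pytest.approx(35.0 / 0.99, abs=1e-9)

    def test_pexpx_unity_is_singular(self):
        with pytest.raises(ValueError):
            iso.delta18o_wood_to_leafwater(
                25.0, 20.0, k=iso.Oxygen18Constants(pex_px=1.0)
            )


class TestCarbonDiscrimination:
    @pytest.mark.parametrize(
        "ratio, expected",
        [(1.0, 27.0), (0.0, 4.4), (0.8, 4.4 + 22.6 * 0.8)],
    )
    def test_simple_model_anchor_points(self, ratio, expected):
        assert iso.discrimination_simple(ratio) == pytest.approx(expected, abs=1e-12)

    def test_classical_term_by_term(self, fixed_leaf_state):
        k = iso.Carbon13Constants()
        # independent spreadsheet-style evaluation on the fixed state
        ca, cs, ci, cc, gs, rd, an = 400.0, 380.0, 300.0, 250.0, 40.0, 1.0, 10.0
        kc = (an + rd) / (cc - gs)
        expected = (
            2.9 * (ca - cs) / ca
            + 4.4 * (cs - ci) / ca
            + 1.8 * (ci - cc) / ca
            + 29.0 * cc / ca
            - 8.0 * gs / ca
            - (-6.0) * rd / (kc * ca)
        )
        got = iso.discrimination_classical(fixed_leaf_state, k, use_gm=True)
        assert got == pytest.approx(expected, abs=1e-12)
        # the respiration term is positive for e = −6‰
        assert -k.e * rd / (kc * ca) > 0

    def test_classical_without_gm_uses_ci(self, fixed_leaf_state):
        got = iso.discrimination_classical(fixed_leaf_state, use_gm=False)
        # recompute with cc replaced by ci
        ca, cs, ci, rd, an, gstar = 400.0, 380.0, 300.0, 1.0, 10.0, 40.0
        kc = (an + rd) / (ci - gstar)
        expected = (
            2.9 * (ca - cs) / ca
            + 4.4 * (cs - ci) / ca
            + 29.0 * ci / ca
            - 8.0 * gstar / ca
            + 6.0 * rd / (kc * ca)
        )
        assert got == pytest.approx(expected, abs=1e-12)

    def test_algebraic_collapse_to_simple(self, fixed_leaf_state):
        """With a_b=a_s=a_m, f=e=0 and all CO2 levels equal to x·Ca the
        classical model reduces to the simple linear form with b'=b."""
        import dataclasses

        x = 0.75
        leaf = dataclasses.replace(
            fixed_leaf_state,
            cs=np.asarray(400.0 * x),
            ci=np.asarray(400.0 * x),
            cc=np.asarray(400.0 * x),
        )
        k = iso.Carbon13Constants(a_b=4.4, a_s=4.4, a_m=4.4, f=0.0, e=0.0)
        got = iso.discrimination_classical(leaf, k, use_gm=True)
        assert got == pytest.approx(4.4 + (29.0 - 4.4) * x, abs=1e-10)

    def test_cc_below_compensation_flagged_as_nan(self, fixed_leaf_state):
        import dataclasses

        leaf = dataclasses.replace(fixed_leaf_state, cc=np.asarray(30.0))
        assert np.isnan(iso.discrimination_classical(leaf, use_gm=True))

    def test_monotone_in_ci_over_ca(self):
        ratios = np.linspace(0.1, 1.2, 30)
        vals = iso.discrimination_simple(ratios)
        assert np.all(np.diff(vals) > 0)


class TestOxygenEnrichment:
    def test_kinetic_limits_and_midpoint(self):
        assert iso.kinetic_fractionation(1e-9, 1.0) == pytest.approx(28.0, abs=1e-6)
        assert iso.kinetic_fractionation(1.0, 1e-9) == pytest.approx(19.0, abs=1e-6)
        assert iso.kinetic_fractionation(0.2, 0.2) == pytest.approx(23.5, abs=1e-12)

    def test_kinetic_bounds_property(self):
        rng = np.random.default_rng(0)
        gs = rng.uniform(1e-4, 2.0, 500)
        gb = rng.uniform(1e-4, 5.0, 500)
        ek = iso.kinetic_fractionation(gs, gb)
        assert np.all((ek >= 19.0) & (ek <= 28.0))

    def test_peclet_damping_values(self):
        assert iso.peclet_damping(1.0) == pytest.approx(1.0 - np.exp(-1.0), abs=1e-12)
        assert iso.peclet_damping(1e-15) == pytest.approx(1.0)
        p = iso.peclet_number(0.002)  # E = 2 mmol m-2 s-1, default L, C, D
        assert p == pytest.approx(0.002 * 0.015 / (55.5e3 * 2.66e-9), rel=1e-12)
        assert iso.peclet_damping(p) == pytest.approx(0.905, abs=2e-3)

    def test_enrichment_zero_at_saturation(self, fixed_leaf_state):
        out = iso.leafwater_enrichment(fixed_leaf_state, w_a=fixed_leaf_state.w_i)
        assert out == pytest.approx(0.0, abs=1e-12)

    def test_peclet_below_craig_gordon_and_limit(self, fixed_leaf_state):
        import dataclasses

        cg = iso.leafwater_enrichment(fixed_leaf_state, 0.012, "craig_gordon")
        pe = iso.leafwater_enrichment(fixed_leaf_state, 0.012, "peclet")
        assert 0.0 < pe < cg
        no_e = dataclasses.replace(fixed_leaf_state, e=np.asarray(0.0))
        assert iso.leafwater_enrichment(no_e, 0.012, "peclet") == pytest.approx(
            cg, abs=1e-12
        )

    def test_enrichment_decreasing_in_wa_over_wi(self, fixed_leaf_state):
        w_as = np.linspace(0.001, 0.02, 20)
        vals = [iso.leafwater_enrichment(fixed_leaf_state, w, "peclet") for w in w_as]
        assert np.all(np.diff(vals) < 0)

    def test_equilibrium_fractionation_magnitude(self):
        # ~9.6‰ at 20 °C, decreasing with temperature
        assert iso.equilibrium_fractionation(20.0) == pytest.approx(9.6, abs=0.3)
        assert iso.equilibrium_fractionation(30.0) < iso.equilibrium_fractionation(10.0)
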