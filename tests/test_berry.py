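"""Mean-berry water/sugar balance, turgor, and growth."""

import math
from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vinesim.berry import (
    BerryParams,
    BerryState,
    GAS_CONSTANT,
    active_sugar_uptake,
    berry_demand_function,
    berry_sugar_demand,
    berry_transpiration,
    initial_berry_state,
    osmotic_pressure,
    phloem_conductance,
    solve_turgor,
    step_berry,
    sugar_concentration,
    water_fluxes,
)

BP = BerryParams()
STATE = initial_berry_state(0.70, 0.14, 80.0)


class TestPhloemConductance:
    def test_midpoint(self):
        assert phloem_conductance(BP.fm_star, BP) == pytest.approx(
            (BP.lp_max + BP.lp_min) / 2.0, rel=1e-12
        )

    def test_limits(self):
        bp = replace(BP, k_lp=12.0, fm_star=1.0)
        assert phloem_conductance(0.0, bp) == pytest.approx(bp.lp_max, rel=1e-4)
        assert phloem_conductance(100.0, bp) == pytest.approx(bp.lp_min, rel=1e-9)

    @settings(max_examples=40, deadline=None)
    @given(fm=st.floats(0.0, 10.0), k=st.floats(0.5, 15.0), fms=st.floats(0.3, 3.0))
    def test_bounded(self, fm, k, fms):
        bp = replace(BP, k_lp=k, fm_star=fms)
        lp = phloem_conductance(fm, bp)
        assert BP.lp_min <= lp <= BP.lp_max


class TestActiveUptake:
    def test_zero_and_half_saturation(self):
        assert active_sugar_uptake(0.2, 0.0, BP) == 0.0
        assert active_sugar_uptake(0.2, BP.km_berry, BP) == pytest.approx(
            BP.vmax_berry * 0.2 / 2.0, rel=1e-12
        )

    def test_saturation(self):
        assert active_sugar_uptake(0.2, 1e9, BP) == pytest.approx(
            BP.vmax_berry * 0.2, rel=1e-6
        )

    def test_monotone_in_concentration(self):
        vals = [active_sugar_uptake(0.2, c, BP) for c in np.linspace(0, 2000, 50)]
        assert all(b >= a for a, b in zip(vals, vals[1:]))


class TestOsmoticPressure:
    def test_zero(self):
        assert osmotic_pressure(0.0, 1.0, 0.0, 25.0) == 0.0

    def test_linear_in_sugar(self):
        p1 = osmotic_pressure(0.1, 1.0, 0.0, 25.0)
        p2 = osmotic_pressure(0.2, 1.0, 0.0, 25.0)
        assert p2 == pytest.approx(2 * p1, rel=1e-12)

    def test_spot_value(self):
        # 0.15 g sucrose in 1 g water at 25 degC
        assert osmotic_pressure(0.15, 1.0, 0.0, 25.0) == pytest.approx(1.086, abs=1e-3)

    def test_no_water(self):
        with pytest.raises(ValueError):
            osmotic_pressure(0.1, 0.0, 0.0, 25.0)


class TestTranspiration:
    def test_saturated_air(self):
        assert berry_transpiration(10.0, 25.0, 100.0, 0.1) == 0.0

    def test_linear_in_area(self):
        t1 = berry_transpiration(5.0, 25.0, 50.0, 0.1)
        t2 = berry_transpiration(10.0, 25.0, 50.0, 0.1)
        assert t2 == pytest.approx(2 * t1, rel=1e-12)

    def test_spot_value(self):
        esat = 0.6108 * math.exp(17.27 * 25.0 / 262.3)
        rho_v = esat * 0.5 * 1000.0 * 18.015 / (GAS_CONSTANT * 298.15) * 1e-6
        assert berry_transpiration(10.0, 25.0, 50.0, 0.1) == pytest.approx(
            0.1 * 10.0 * rho_v, rel=1e-9
        )


class TestWaterFluxes:
    def test_equilibrium_is_fluxless(self):
        """Equal total potentials and matched osmotica give zero influxes."""
        pi_b = osmotic_pressure(STATE.s_sugar, STATE.w_water, BP.c_other, 25.0)
        c_match = pi_b / (GAS_CONSTANT * 298.15 * 1e-6)
        psi_b = STATE.p_turgor - pi_b
        u_p, u_x, t_f = water_fluxes(STATE, psi_b, c_match, 25.0, 100.0, BP)
        assert u_p == pytest.approx(0.0, abs=1e-12)
        assert u_x == pytest.approx(0.0, abs=1e-12)
        assert t_f == 0.0

    def test_linear_in_xylem_potential(self):
        u_p0, u_x0, _ = water_fluxes(STATE, -0.8, 300.0, 25.0, 60.0, BP)
        u_p1, u_x1, _ = water_fluxes(STATE, -0.6, 300.0, 25.0, 60.0, BP)
        u_p2, u_x2, _ = water_fluxes(STATE, -0.4, 300.0, 25.0, 60.0, BP)
        assert u_p2 - u_p1 == pytest.approx(u_p1 - u_p0, rel=1e-9)
        assert u_x2 - u_x1 == pytest.approx(u_x1 - u_x0, rel=1e-9)

    def test_turgid_berry_backflow(self):
        turgid = replace(STATE, p_turgor=2.5)
        _, u_x, _ = water_fluxes(turgid, -1.5, 300.0, 25.0, 60.0, BP)
        assert u_x < 0.0


class TestSolveTurgor:
    def test_yield_threshold_fixed_point(self):
        """Zero net influx exactly at the yield turgor returns the threshold."""
        pi_b = osmotic_pressure(STATE.s_sugar, STATE.w_water, BP.c_other, 25.0)
        c_match = pi_b / (GAS_CONSTANT * 298.15 * 1e-6)
        psi_x = BP.y_thresh - pi_b  # net(P) = beta (psi_x - P + pi_b) = 0 at P=Y
        p = solve_turgor(STATE, psi_x, c_match, 25.0, 100.0, BP)
        assert p == pytest.approx(BP.y_thresh, abs=1e-9)

    def test_matches_grid_scan(self):
        """Closed form equals a fine scan of the scalar balance."""
        for psi_x, c in [(-0.5, 100.0), (-1.0, 400.0), (-1.4, 50.0)]:
            p_star = solve_turgor(STATE, psi_x, c, 26.0, 55.0, BP)
            grid = np.arange(0.0, 5.0, 1e-4)
            best, best_res = None, np.inf
            for p in grid:
                st_p = replace(STATE, p_turgor=p)
                u_p, u_x, t_f = water_fluxes(st_p, psi_x, c, 26.0, 55.0, BP)
                growth = STATE.volume * BP.phi_ext * max(0.0, p - BP.y_thresh)
                res = abs(u_p + u_x - t_f - growth)
                if res < best_res:
                    best, best_res = p, res
            if 0.0 < p_star < 5.0 - 1e-4:
                assert p_star == pytest.approx(best, abs=2e-4)

    def test_residual_contract(self):
        """Interior solutions close the balance; at the P = 0 floor the berry
        is losing water (no admissible turgor can balance the efflux)."""
        for psi_x, c, rh in [(-0.5, 300.0, 90.0), (-0.9, 150.0, 85.0), (-1.4, 300.0, 40.0)]:
            p_star = solve_turgor(STATE, psi_x, c, 25.0, rh, BP)
            st_p = replace(STATE, p_turgor=p_star)
            u_p, u_x, t_f = water_fluxes(st_p, psi_x, c, 25.0, rh, BP)
            growth = STATE.volume * BP.phi_ext * max(0.0, p_star - BP.y_thresh)
            if p_star > 0.0:
                assert abs(u_p + u_x - t_f - growth) < 1e-6
            else:
                assert u_p + u_x - t_f < 0.0

    def test_demand_closure_consistency(self):
        """The fast demand closure equals the composed module functions."""
        dem = berry_demand_function(STATE, -0.9, 27.0, 55.0, BP)
        for c in (0.0, 50.0, 300.0, 900.0):
            assert dem(c) == pytest.approx(
                berry_sugar_demand(STATE, -0.9, c, 27.0, 55.0, BP), rel=1e-9, abs=1e-15
            )
        # and against the long-hand composition
        for c in (120.0, 480.0):
            p = solve_turgor(STATE, -0.9, c, 27.0, 55.0, BP)
            st_p = replace(STATE, p_turgor=p)
            u_p, _, _ = water_fluxes(st_p, -0.9, c, 27.0, 55.0, BP)
            expected = active_sugar_uptake(STATE.dw, c, BP) + max(u_p, 0.0) * c * 342.3e-6
            assert dem(c) == pytest.approx(expected, rel=1e-9)


class TestStepBerry:
    def test_fluxless_environment_preserves_state(self):
        bp = replace(BP, sigma_p=0.0, resp_m=0.0, k_struct=0.0)
        pi_b = osmotic_pressure(STATE.s_sugar, STATE.w_water, bp.c_other, 25.0)
        # below-threshold equilibrium: P = psi_x + pi_b, no growth, no fluxes
        psi_x = 0.1 - pi_b
        out = step_berry(STATE, psi_x, 0.0, 25.0, 100.0, bp)
        assert out.w_water == pytest.approx(STATE.w_water, abs=1e-12)
        assert out.s_sugar == pytest.approx(STATE.s_sugar, abs=1e-12)
        assert out.dw_struct == pytest.approx(STATE.dw_struct, abs=1e-12)

    def test_mass_balance_closure(self):
        """One step conserves water and sugar to 1e-9 g."""
        psi_x, c, tair, rh = -0.9, 250.0, 26.0, 55.0
        out = step_berry(STATE, psi_x, c, tair, rh, BP, dt=1.0)
        p = solve_turgor(STATE, psi_x, c, tair, rh, BP)
        st_p = replace(STATE, p_turgor=p)
        u_p, u_x, t_f = water_fluxes(st_p, psi_x, c, tair, rh, BP)
        active = active_sugar_uptake(STATE.dw, c, BP)
        passive = max(u_p, 0.0) * c * 342.3e-6
        resp = BP.resp_m * STATE.dw * BP.q10 ** ((tair - 25.0) / 10.0)
        conv = BP.k_struct * STATE.s_sugar
        assert out.w_water - STATE.w_water == pytest.approx(u_p + u_x - t_f, abs=1e-9)
        assert out.s_sugar - STATE.s_sugar == pytest.approx(
            active + passive - resp - conv, abs=1e-9
        )
        assert out.dw_struct - STATE.dw_struct == pytest.approx(
            conv * (1.0 - BP.resp_g), abs=1e-9
        )
        dfw = out.fw - STATE.fw
        assert dfw == pytest.approx(
            (u_p + u_x - t_f) + (active + passive - resp - conv) + conv * (1 - BP.resp_g),
            abs=1e-9,
        )

    def test_constant_drivers_approach_sugar_plateau(self):
        """Under constant drivers d[Sugar]/dt decays toward a slow drift.

        The concentration approaches the level where active import balances
        growth dilution; the approach is asymptotic, so the check is on the
        decay of the accumulation rate rather than on exact stationarity.
        """
        state = STATE
        daily_rates = []
        prev_conc = state.sugar_conc
        for day in range(90):
            for _ in range(24):
                state = step_berry(state, -0.6, 250.0, 22.0, 80.0, BP)
            daily_rates.append(state.sugar_conc - prev_conc)
            prev_conc = state.sugar_conc
        assert abs(daily_rates[-1]) < 0.2 * abs(daily_rates[0])
        assert abs(daily_rates[-1]) < 1.0  # g/L per day, near-stationary

    def test_drier_xylem_smaller_sweeter(self):
        """Drier xylem forcing: lower final FW, higher final concentration."""
        def run(psi_x):
            state = STATE
            for _ in range(24 * 30):
                state = step_berry(state, psi_x, 300.0, 24.0, 65.0, BP)
            return state

        wet = run(-0.5)
        dry = run(-1.3)
        assert dry.fw < wet.fw
        assert dry.sugar_conc > wet.sugar_conc

    def test_uptake_monotone_in_concentration_operating_range(self):
        dem = berry_demand_function(STATE, -0.9, 26.0, 60.0, BP)
        cs = np.linspace(0.0, 300.0, 40)
        vals = [dem(c) for c in cs]
        assert all(b >= a - 1e-15 for a, b in zip(vals, vals[1:]))


class TestSugarConcentration:
    def test_division(self):
        # 0.2 g sugar in a state whose volume is exactly 1 cm3
        state = BerryState(w_water=0.875, dw_struct=0.0, s_sugar=0.2)
        assert state.volume == pytest.approx(1.0, rel=1e-12)
        assert sugar_concentration(state) == pytest.approx(200.0, rel=1e-12)

    def test_zero_sugar(self):
        state = BerryState(w_water=1.0, dw_struct=0.1, s_sugar=0.0)
        assert sugar_concentration(state) == 0.0

    def test_initial_state_roundtrip(self):
        st0 = initial_berry_state(0.8, 0.16, 90.0)
        assert st0.fw == pytest.approx(0.8, abs=1e-12)
        assert st0.dw == pytest.approx(0.16, abs=1e-12)
        assert st0.sugar_conc == pytest.approx(90.0, rel=1e-9)
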