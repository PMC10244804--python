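"""Whole-plant hydraulic network and season driver."""

import math

import numpy as np
import pandas as pd
import pytest

import vinesim as vs
from vinesim.canopy import CanopyConfig, build_canopy
from vinesim.environment import soil_root_resistance
from vinesim.leaf import (
    leaf_energy_balance,
    leaf_vulnerability,
    td_stomatal_conductance,
)
from vinesim.plant import (
    MG_PER_MMOL_H2O,
    extract_midday,
    match_observations,
    simulate_season,
    solve_hour,
)

from conftest import constant_weather_inputs


def two_leaf_params():
    params = vs.PlantParams()
    canopy_cfg = CanopyConfig(leaves_per_shoot=2, leaf_area_per_shoot=0.05)
    from dataclasses import replace

    return replace(params, canopy=canopy_cfg)


class TestSolveHour:
    def test_no_flux_no_gradient(self, default_params, default_canopy):
        """Saturated air at night: no transpiration, xylem tracks soil."""
        hs = solve_hour(default_canopy, 20.0, 100.0, 0.0, -0.5, default_params)
        assert hs.e_total == pytest.approx(0.0, abs=1e-9)
        assert hs.psi_xylem == pytest.approx(-0.5, abs=1e-9)

    def test_network_identity_exact(self, default_params, default_canopy):
        hs = solve_hour(default_canopy, 28.0, 45.0, 700.0, -0.6, default_params)
        rsp = soil_root_resistance(default_params.soil, -0.6)
        r_tot = rsp + default_params.hydraulics.r_ax
        assert hs.psi_xylem == pytest.approx(-0.6 - hs.e_total * r_tot, abs=1e-12)

    def test_flux_conservation(self, default_params, default_canopy):
        hs = solve_hour(default_canopy, 28.0, 45.0, 700.0, -0.6, default_params)
        e_leaves = sum(
            s.e * MG_PER_MMOL_H2O * l.area
            for s, l in zip(hs.leaf_states, default_canopy.leaves)
        )
        assert abs(hs.e_total - e_leaves) <= 1e-9 * max(hs.e_total, 1e-9)

    def test_potential_ordering(self, default_params, default_canopy):
        for psi_soil in (-0.1, -0.5, -0.9):
            hs = solve_hour(default_canopy, 30.0, 40.0, 800.0, psi_soil, default_params)
            assert hs.psi_soil >= hs.psi_xylem
            assert all(hs.psi_xylem >= s.psi_leaf for s in hs.leaf_states)

    def test_monotone_stress_response(self, default_params, default_canopy):
        prev_e, prev_psi = math.inf, math.inf
        for psi_soil in (-0.1, -0.3, -0.5, -0.7, -0.9, -1.1):
            hs = solve_hour(default_canopy, 28.0, 45.0, 750.0, psi_soil, default_params)
            assert hs.e_total <= prev_e + 1e-9
            assert hs.psi_xylem <= prev_psi + 1e-9
            prev_e, prev_psi = hs.e_total, hs.psi_xylem

    def test_two_leaf_toy_matches_grid_oracle(self):
        """Exhaustive xylem-potential grid search (1e-4 MPa) on a 2-leaf toy.

        The oracle scans candidate xylem potentials, solves each leaf by an
        independent fine scan of the supply/demand balance (with the leaf
        temperature iterated to consistency), and minimizes the network
        residual |psi_soil - E_total (Rsp + r_ax) - psi_x|.
        """
        params = two_leaf_params()
        canopy = build_canopy(params.canopy)
        tair, rh, rad, psi_soil = 27.0, 50.0, 650.0, -0.5
        hs = solve_hour(canopy, tair, rh, rad, psi_soil, params)

        gx, hyd = params.gx, params.hydraulics
        rsp = soil_root_resistance(params.soil, psi_soil)
        r_tot = rsp + hyd.r_ax
        ppfd0 = rad * params.c_par
        k_ext = params.canopy.k_ext
        ppfds = [ppfd0 * math.exp(-k_ext * l.lai_above) for l in canopy.leaves]
        rns = [q / params.c_par * params.canopy.alpha_leaf for q in ppfds]
        ea = 0.6108 * math.exp(17.27 * tair / (tair + 237.3)) * rh / 100.0

        def leaf_e(psi_x, aba, i):
            """Leaf transpiration (mg/s) at the shallowest balance root."""
            area = canopy.leaves[i].area
            t_leaf = tair
            e_mmol = 0.0
            for _ in range(4):  # settle the t_leaf lag
                esat_t = 0.6108 * math.exp(17.27 * t_leaf / (t_leaf + 237.3))
                c_vap = max(esat_t - ea, 0.0) / 101.325 * 1000.0 * MG_PER_MMOL_H2O * area

                def bal(psi):
                    f = leaf_vulnerability(psi, gx.psi50_leaf, gx.s_vuln)
                    gs = td_stomatal_conductance(aba, psi, ppfds[i], gx)
                    return hyd.k_leaf_max * area * f * (psi_x - psi) - c_vap / (
                        1.0 / gs + 1.0 / gx.gb
                    )

                # downward scan for the first crossing, then bisect
                psi_root = None
                psi = psi_x - 0.05
                while psi > psi_x - 5.0:
                    if bal(psi) > 0.0:
                        lo, hi = psi, psi + 0.05
                        for _ in range(40):
                            mid = 0.5 * (lo + hi)
                            if bal(mid) > 0.0:
                                lo = mid
                            else:
                                hi = mid
                        psi_root = 0.5 * (lo + hi)
                        break
                    psi -= 0.05
                assert psi_root is not None
                gs = td_stomatal_conductance(aba, psi_root, ppfds[i], gx)
                t_leaf, e_mmol = leaf_energy_balance(tair, rns[i], gs, gx.gb, rh)
            return e_mmol * MG_PER_MMOL_H2O * area

        def network_residual(psi_x):
            # self-consistent ABA signal for this candidate
            e_tot = 0.0
            for _ in range(4):
                aba = gx.a_aba * max(0.0, -psi_x) / (e_tot + gx.b_aba)
                e_tot = leaf_e(psi_x, aba, 0) + leaf_e(psi_x, aba, 1)
            return abs(psi_soil - e_tot * r_tot - psi_x)

        # hierarchical exhaustive search: coarse pass over the full range,
        # then a 1e-4 grid around the coarse minimum
        coarse = np.arange(psi_soil - 0.3, psi_soil, 2e-3)
        res_c = [network_residual(p) for p in coarse]
        center = coarse[int(np.argmin(res_c))]
        fine = np.arange(center - 2.5e-3, center + 2.5e-3, 1e-4)
        res_f = [network_residual(p) for p in fine]
        best_psi = fine[int(np.argmin(res_f))]
        assert abs(best_psi - hs.psi_xylem) < 5e-3

    def test_rejects_positive_soil_potential(self, default_params, default_canopy):
        with pytest.raises(ValueError):
            solve_hour(default_canopy, 20.0, 50.0, 0.0, 0.1, default_params)


class TestSimulateSeason:
    def test_deterministic(self, default_params):
        inputs = constant_weather_inputs(days=2)
        t1 = simulate_season(inputs, default_params)
        t2 = simulate_season(inputs, default_params)
        pd.testing.assert_frame_equal(t1.hourly, t2.hourly)

    def test_trajectory_length(self, short_trajectory, short_vintage_inputs):
        days = (short_vintage_inputs.harvest - short_vintage_inputs.veraison).days + 1
        assert len(short_trajectory.hourly) == 24 * days

    def test_steady_state_under_constant_forcing(self, default_params):
        """Identical forcing every day: the midday xylem potential repeats."""
        inputs = constant_weather_inputs(days=4)
        traj = simulate_season(inputs, default_params)
        midday = extract_midday(traj)
        assert midday.iloc[1] == pytest.approx(midday.iloc[2], abs=1e-6)
        assert midday.iloc[2] == pytest.approx(midday.iloc[3], abs=1e-6)

    def test_coverage_validated(self, default_params, short_vintage_inputs):
        from dataclasses import replace

        bad = replace(
            short_vintage_inputs,
            harvest=short_vintage_inputs.harvest + pd.Timedelta(days=400),
        )
        with pytest.raises(ValueError, match="cover"):
            simulate_season(bad, default_params)


class TestLeanReplay:
    def test_matches_full_replay(self, short_trajectory, short_vintage_inputs, default_params):
        """The array-only berry replay reproduces the full trajectory."""
        from vinesim.plant import replay_berry_arrays

        hydro = short_trajectory.hourly
        fw, dw, conc = replay_berry_arrays(
            hydro, default_params, short_vintage_inputs.berry_init
        )
        np.testing.assert_allclose(fw, hydro["berry_fw"].to_numpy(), rtol=1e-12)
        np.testing.assert_allclose(dw, hydro["berry_dw"].to_numpy(), rtol=1e-12)
        np.testing.assert_allclose(conc, hydro["berry_sugar_conc"].to_numpy(), rtol=1e-12)


class TestExtraction:
    def test_midday_series(self, short_trajectory):
        midday = extract_midday(short_trajectory, hour=15)
        df = short_trajectory.hourly
        days = df.index.normalize().unique()
        assert len(midday) == len(days)
        ts = days[2] + pd.Timedelta(hours=15)
        assert midday.iloc[2] == df.loc[ts, "psi_xylem"]

    def test_predawn_adjacent_hour(self, short_trajectory):
        early = extract_midday(short_trajectory, hour=4)
        df = short_trajectory.hourly
        ts = df.index.normalize().unique()[0] + pd.Timedelta(hours=4)
        assert early.iloc[0] == df.loc[ts, "psi_xylem"]

    def test_match_observations(self, short_trajectory, short_vintage_inputs):
        v = short_vintage_inputs.veraison
        obs = pd.DataFrame(
            {
                "date": [v + pd.Timedelta(days=3), v + pd.Timedelta(days=10),
                         v + pd.Timedelta(days=400)],
                "variable": ["psi_xylem_midday", "berry_fw_g", "psi_xylem_midday"],
                "value": [-0.8, 0.8, -1.0],
            }
        )
        paired, unmatched = match_observations(short_trajectory, obs)
        assert len(paired) == 2
        assert len(unmatched) == 1
        df = short_trajectory.hourly
        ts = (v + pd.Timedelta(days=3)).normalize() + pd.Timedelta(hours=15)
        assert paired.iloc[0]["simulated"] == df.loc[ts, "psi_xylem"]

    def test_unknown_variable_rejected(self, short_trajectory, short_vintage_inputs):
        obs = pd.DataFrame(
            {
                "date": [short_vintage_inputs.veraison],
                "variable": ["nonsense"],
                "value": [1.0],
            }
        )
        with pytest.raises(ValueError, match="unknown observation variable"):
            match_observations(short_trajectory, obs)
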