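"""Leaf gas exchange: FvCB, Tardieu-Davies stomata, vulnerability, energy
balance, and the coupled single-leaf solution."""

import math

import numpy as np
import pytest

from vinesim.leaf import (
    GasExchangeParams,
    LAMBDA_MOL,
    P_ATM,
    aba_concentration,
    arrhenius,
    electron_transport,
    fvcb_assimilation,
    leaf_energy_balance,
    leaf_vulnerability,
    solve_ci,
    solve_leaf,
    td_stomatal_conductance,
    vcmax25_from_nitrogen,
    CP_MOL,
    EMISSIVITY,
    SIGMA_SB,
)


P = GasExchangeParams()
VCMAX25 = vcmax25_from_nitrogen(1.7, P.slope_vcmax)  # default leaf nitrogen


def _esat(t):
    return 0.6108 * math.exp(17.27 * t / (t + 237.3))


class TestVcmaxNitrogen:
    def test_linear_zero_intercept(self):
        assert vcmax25_from_nitrogen(0.0, 47.0) == 0.0
        assert vcmax25_from_nitrogen(1.6, 50.0) == pytest.approx(80.0)
        assert vcmax25_from_nitrogen(3.2, 50.0) == pytest.approx(160.0)
        with pytest.raises(ValueError):
            vcmax25_from_nitrogen(-0.1, 47.0)


class TestFvcb:
    def test_compensation_point(self):
        """At Ci = Gamma* both carboxylation terms vanish: An = -Rd."""
        rd = VCMAX25 * P.rd_frac
        an, _ = fvcb_assimilation(P.gamma_star25, 25.0, 1200.0, P, VCMAX25)
        assert an == pytest.approx(-rd, abs=1e-10)

    def test_dark_respiration(self):
        rd = VCMAX25 * P.rd_frac
        an, flag = fvcb_assimilation(250.0, 25.0, 0.0, P, VCMAX25)
        assert an == pytest.approx(-rd, abs=1e-12)
        assert flag == "rubp"

    def test_limitation_flag_matches_bruteforce(self):
        """The reported branch equals the brute-force min over a (ci, ppfd) grid."""
        for ci in np.linspace(60.0, 500.0, 20):
            for ppfd in np.linspace(20.0, 1800.0, 20):
                an, flag = fvcb_assimilation(ci, 25.0, ppfd, P, VCMAX25)
                vc = VCMAX25
                jm = VCMAX25 * P.jmax_ratio
                rd = VCMAX25 * P.rd_frac
                km = P.kc25 * (1.0 + P.o2 / P.ko25)
                j = electron_transport(ppfd, jm, P.theta_j, P.phi_j)
                ac = vc * (ci - P.gamma_star25) / (ci + km)
                aj = j * (ci - P.gamma_star25) / (4 * ci + 8 * P.gamma_star25)
                assert an == pytest.approx(min(ac, aj) - rd, rel=1e-12)
                assert flag == ("rubisco" if ac <= aj else "rubp")

    def test_monotone_in_drivers(self):
        grid = np.linspace(80.0, 500.0, 15)
        ans = [fvcb_assimilation(ci, 25.0, 900.0, P, VCMAX25)[0] for ci in grid]
        assert all(b >= a - 1e-12 for a, b in zip(ans, ans[1:]))
        ppfds = np.linspace(0.0, 1800.0, 15)
        ans = [fvcb_assimilation(300.0, 25.0, q, P, VCMAX25)[0] for q in ppfds]
        assert all(b >= a - 1e-12 for a, b in zip(ans, ans[1:]))


class TestAba:
    def test_zero_at_nonnegative_collar(self):
        assert aba_concentration(0.0, 5.0, P) == 0.0
        assert aba_concentration(0.3, 5.0, P) == 0.0

    def test_dilution_by_flux(self):
        assert aba_concentration(-1.0, 10.0, P) < aba_concentration(-1.0, 1.0, P)

    def test_unit_example(self):
        p = GasExchangeParams(a_aba=1.0, b_aba=1.0)
        assert aba_concentration(-1.0, 0.0, p) == pytest.approx(1.0)


class TestTdConductance:
    def test_no_aba_saturating_light(self):
        gs = td_stomatal_conductance(0.0, -0.5, 1e7, P)
        assert gs == pytest.approx(P.gs_min + P.alpha_td, rel=1e-4)

    def test_infinite_aba_limit(self):
        gs = td_stomatal_conductance(1e6, -1.0, 1500.0, P)
        assert gs == pytest.approx(P.gs_min, abs=1e-12)

    def test_monotone_in_aba_and_potential(self):
        for aba1, aba2 in [(0.0, 0.1), (0.1, 0.5), (0.5, 2.0)]:
            assert td_stomatal_conductance(aba2, -1.0, 800.0, P) <= td_stomatal_conductance(
                aba1, -1.0, 800.0, P
            )
        for psi1, psi2 in [(-0.5, -1.0), (-1.0, -2.0)]:
            assert td_stomatal_conductance(0.2, psi2, 800.0, P) <= td_stomatal_conductance(
                0.2, psi1, 800.0, P
            )

    def test_sign_validation(self):
        with pytest.raises(ValueError):
            GasExchangeParams(beta_td=0.5)
        with pytest.raises(ValueError):
            GasExchangeParams(delta_td=0.5)


class TestVulnerability:
    def test_half_loss_at_midpoint(self):
        assert leaf_vulnerability(-1.80, -1.80, 5.0) == 0.5

    def test_near_full_conductance_when_hydrated(self):
        assert leaf_vulnerability(0.0, -1.80, 5.0) == pytest.approx(0.99988, abs=1e-5)

    def test_strictly_increasing(self):
        psis = np.linspace(-3.0, -0.1, 30)
        vals = [leaf_vulnerability(p, -1.80, 5.0) for p in psis]
        assert all(b > a for a, b in zip(vals, vals[1:]))
        assert leaf_vulnerability(-2.5, -1.8, 5.0) < leaf_vulnerability(-1.0, -1.8, 5.0)


class TestEnergyBalance:
    def test_equilibrium_at_zero_forcing(self):
        t_leaf, e = leaf_energy_balance(25.0, 0.0, 0.2, 1.0, 100.0)
        assert t_leaf == pytest.approx(25.0, abs=1e-6)
        assert e == pytest.approx(0.0, abs=1e-9)

    def test_warming_under_load_without_evaporation(self):
        t_leaf, _ = leaf_energy_balance(25.0, 300.0, 0.2, 1.0, 100.0)
        assert t_leaf > 25.0

    def test_residual_contract(self):
        """The returned temperature closes the balance to < 1e-6 W m-2."""
        for rn, gs, rh in [(400.0, 0.25, 40.0), (100.0, 0.05, 70.0), (0.0, 0.02, 90.0)]:
            t_leaf, e = leaf_energy_balance(28.0, rn, gs, 1.0, rh)
            g_tv = 1.0 / (1.0 / gs + 1.0)
            ea = _esat(28.0) * rh / 100.0
            e_mol = g_tv * (_esat(t_leaf) - ea) / P_ATM
            h_coef = CP_MOL * 0.924 * 2.0 + 4.0 * EMISSIVITY * SIGMA_SB * (28.0 + 273.15) ** 3
            resid = rn - h_coef * (t_leaf - 28.0) - LAMBDA_MOL * e_mol
            assert abs(resid) < 1e-6

    def test_invalid_conductance(self):
        with pytest.raises(ValueError):
            leaf_energy_balance(25.0, 100.0, 0.0, 1.0, 50.0)


class TestSolveLeaf:
    def test_diffusion_residual(self):
        state = solve_leaf(28.0, 45.0, 1200.0, 450.0, 0.05, -1.0, P, 1.7)
        gc = 1.0 / (1.6 / state.gs + 1.37 / P.gb)
        assert abs(state.an - gc * (P.ca - state.ci)) < 1e-3

    def test_dark_state(self):
        state = solve_leaf(18.0, 85.0, 0.0, 0.0, 0.05, -0.4, P, 1.7)
        rd = arrhenius(vcmax25_from_nitrogen(1.7, P.slope_vcmax) * P.rd_frac, P.ea_rd, state.t_leaf)
        assert state.gs == pytest.approx(P.gs_min, abs=1e-12)
        assert state.an == pytest.approx(-rd, rel=1e-9)
        assert state.ci > P.ca  # outward CO2 diffusion under net respiration

    def test_matches_2d_grid_oracle(self):
        """Exhaustive (ci x t_leaf) grid search at 0.05 resolution."""
        tair, rh, ppfd, rn, aba, psi_leaf = 27.0, 50.0, 900.0, 380.0, 0.08, -1.2
        state = solve_leaf(tair, rh, ppfd, rn, aba, psi_leaf, P, 1.7)
        gs = state.gs
        vcmax25 = vcmax25_from_nitrogen(1.7, P.slope_vcmax)
        t_grid = np.arange(tair - 10.0, tair + 10.0, 0.05)
        ci_grid = np.arange(50.0, 500.0, 0.05)

        # energy-balance residual over the t grid (gs is explicit)
        g_tv = 1.0 / (1.0 / gs + 1.0 / P.gb)
        ea = _esat(tair) * rh / 100.0
        esat_t = 0.6108 * np.exp(17.27 * t_grid / (t_grid + 237.3))
        h_coef = CP_MOL * 0.924 * 2.0 + 4.0 * EMISSIVITY * SIGMA_SB * (tair + 273.15) ** 3
        resid_t = np.abs(rn - h_coef * (t_grid - tair) - LAMBDA_MOL * g_tv * (esat_t - ea) / P_ATM)
        t_star = t_grid[np.argmin(resid_t)]
        assert abs(t_star - state.t_leaf) <= 0.05

        # diffusion/biochemistry residual over the ci grid at t_star
        vc = arrhenius(vcmax25, P.ea_vcmax, t_star)
        jm = arrhenius(vcmax25 * P.jmax_ratio, P.ea_jmax, t_star)
        rd = arrhenius(vcmax25 * P.rd_frac, P.ea_rd, t_star)
        kc = arrhenius(P.kc25, P.ea_kc, t_star)
        ko = arrhenius(P.ko25, P.ea_ko, t_star)
        gstar = arrhenius(P.gamma_star25, P.ea_gamma_star, t_star)
        km = kc * (1.0 + P.o2 / ko)
        j = electron_transport(ppfd, jm, P.theta_j, P.phi_j)
        ac = vc * (ci_grid - gstar) / (ci_grid + km)
        aj = j * (ci_grid - gstar) / (4.0 * ci_grid + 8.0 * gstar)
        an = np.minimum(ac, aj) - rd
        gc = 1.0 / (1.6 / gs + 1.37 / P.gb)
        resid_ci = np.abs(an - gc * (P.ca - ci_grid))
        ci_star = ci_grid[np.argmin(resid_ci)]
        assert abs(ci_star - state.ci) <= 0.05
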