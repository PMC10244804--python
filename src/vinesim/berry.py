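"""Biophysical mean-berry model.

Hourly water balance (phloem and xylem influx minus skin transpiration),
sugar balance (active Michaelis-Menten uptake plus advective phloem import,
minus respiration and conversion to structural dry mass), and turgor-gated
growth in the Lockhart sense. The berry is a mean berry; whole-plant berry
demand is the mean berry times the number of berries per shoot.

With the flux laws used here, the quasi-steady turgor balance is piecewise
linear in the turgor pressure P, so the hourly turgor has a closed-form
root (the bisection/grid-scan formulation is kept in the test suite as an
independent oracle).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

__all__ = [
    "BerryParams",
    "BerryState",
    "initial_berry_state",
    "phloem_conductance",
    "active_sugar_uptake",
    "osmotic_pressure",
    "berry_transpiration",
    "water_fluxes",
    "solve_turgor",
    "berry_demand_function",
    "berry_sugar_demand",
    "step_berry",
    "sugar_concentration",
]

GAS_CONSTANT = 8.314  # J mol-1 K-1
M_SUCROSE = 342.3  # g mol-1
RHO_WATER = 1.0  # g cm-3
RHO_SOLID = 1.6  # g cm-3
M_WATER = 18.015  # g mol-1
CARBON_PER_SUGAR = 12 * 12.011 / M_SUCROSE  # g C per g sucrose
SPHERE_A_GEO = (36.0 * math.pi) ** (1.0 / 3.0)  # area = a_geo * V^(2/3)


def _esat(t: float) -> float:
    return 0.6108 * math.exp(17.27 * t / (t + 237.3))


@dataclass(frozen=True)
class BerryParams:
    """Berry water/sugar balance coefficients.

    The six calibrated quantities are ``vmax_berry`` and ``km_berry``
    (active sugar import) and ``lp_max``, ``lp_min``, ``fm_star``, ``k_lp``
    (the sigmoid decline of phloem hydraulic conductance with berry fresh
    mass). The remainder are documented fixed defaults: xylem path
    conductance ``lx``, skin vapor conductance ``rho_f``, phloem reflection
    coefficient ``sigma_p``, cell-wall extensibility ``phi_ext`` above the
    yield turgor ``y_thresh``, non-sugar osmolytes ``c_other``, respiration
    coefficients and the sphere surface shape factor.
    """

    vmax_berry: float = 1.45e-3  # g sugar g-1 DW h-1
    km_berry: float = 160.0  # mol m-3
    lp_max: float = 1.9e-4  # g H2O cm-2 MPa-1 h-1
    lp_min: float = 3.8e-5
    fm_star: float = 1.0  # g
    k_lp: float = 6.0  # g-1
    lx: float = 9.0e-5  # g H2O cm-2 MPa-1 h-1
    rho_f: float = 90.0  # cm h-1 skin conductance to vapor
    sigma_p: float = 0.15
    phi_ext: float = 1.0e-2  # MPa-1 h-1
    y_thresh: float = 0.30  # MPa
    eps_elastic: float = 10.0  # MPa (elastic modulus; hook, quasi-steady model)
    c_other: float = 250.0  # mol m-3 non-sugar osmolytes
    resp_g: float = 0.15  # growth respiration fraction of converted sugar
    resp_m: float = 1.0e-4  # g sugar g-1 DW h-1 maintenance at 25 degC
    q10: float = 2.0
    k_struct: float = 2.0e-4  # h-1 first-order sugar -> structure conversion
    a_geo: float = SPHERE_A_GEO

    def __post_init__(self) -> None:
        if not (self.lp_max >= self.lp_min > 0):
            raise ValueError("require lp_max >= lp_min > 0")
        if self.vmax_berry <= 0 or self.km_berry <= 0:
            raise ValueError("vmax_berry and km_berry must be > 0")
        if not 0.0 <= self.sigma_p <= 1.0:
            raise ValueError("sigma_p must lie in [0, 1]")
        if self.y_thresh < 0:
            raise ValueError("y_thresh must be >= 0")


@dataclass(frozen=True)
class BerryState:
    """Mean-berry state: water, structural dry mass, sugar (g), turgor (MPa)."""

    w_water: float
    dw_struct: float
    s_sugar: float
    p_turgor: float = 0.2
    floored: bool = False

    def __post_init__(self) -> None:
        for name in ("w_water", "dw_struct", "s_sugar"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def fw(self) -> float:
        """Fresh weight (g) = water + structural dry mass + sugar."""
        return self.w_water + self.dw_struct + self.s_sugar

    @property
    def dw(self) -> float:
        """Total dry weight (g) = structural + soluble sugar."""
        return self.dw_struct + self.s_sugar

    @property
    def volume(self) -> float:
        """Berry volume (cm3) from component densities."""
        return self.w_water / RHO_WATER + (self.dw_struct + self.s_sugar) / RHO_SOLID

    @property
    def sugar_conc(self) -> float:
        """Sugar concentration (g L-1)."""
        return sugar_concentration(self)

    @property
    def area(self) -> float:
        """Surface area (cm2), sphere-equivalent by default shape factor."""
        return SPHERE_A_GEO * self.volume ** (2.0 / 3.0)


def initial_berry_state(fw: float, dw_total: float, sugar_conc_gl: float) -> BerryState:
    """Berry state from the observables reported at veraison.

    Splits total dry weight into soluble sugar (from the concentration and
    the volume implied by the densities) and structural dry mass.
    """
    if not 0 < dw_total < fw:
        raise ValueError("require 0 < DW < FW")
    w = fw - dw_total
    volume = w / RHO_WATER + dw_total / RHO_SOLID
    s = sugar_conc_gl * volume / 1000.0
    if s > dw_total:
        raise ValueError("sugar concentration inconsistent with DW")
    return BerryState(w_water=w, dw_struct=dw_total - s, s_sugar=s)


def phloem_conductance(fm: float, bp: BerryParams) -> float:
    """Phloem hydraulic conductance Lp(FM), sigmoid in berry fresh mass.

    Lp = lp_min + (lp_max - lp_min) / (1 + exp(k_lp (FM - FM*))): equal to
    the midpoint at FM*, approaching lp_max for small berries and lp_min for
    large ones (k_lp > 0).
    """
    if fm < 0:
        raise ValueError("fresh mass must be >= 0")
    x = bp.k_lp * (fm - bp.fm_star)
    if x > 700.0:
        return bp.lp_min
    return bp.lp_min + (bp.lp_max - bp.lp_min) / (1.0 + math.exp(x))


def active_sugar_uptake(dw: float, c_phloem: float, bp: BerryParams) -> float:
    """Active sugar import (g sugar h-1): Vmax * DW * C / (Km + C)."""
    if c_phloem < 0:
        raise ValueError("c_phloem must be >= 0")
    return bp.vmax_berry * dw * c_phloem / (bp.km_berry + c_phloem)


def osmotic_pressure(s_sugar: float, w_water: float, c_other: float, t: float) -> float:
    """van 't Hoff osmotic pressure (MPa) of the berry sap.

    Sugar molarity is computed on the water volume; ``c_other`` (mol m-3)
    lumps non-sugar osmolytes (organic acids, ions).
    """
    if w_water <= 0:
        raise ValueError("water mass must be > 0")
    c_sugar = s_sugar / M_SUCROSE / (w_water / RHO_WATER * 1e-6)  # mol m-3
    return GAS_CONSTANT * (t + 273.15) * (c_sugar + c_other) * 1e-6


def _vapor_density(e_kpa: float, t: float) -> float:
    """Vapor density (g cm-3) at partial pressure e (kPa) and temperature t."""
    return e_kpa * 1000.0 * M_WATER / (GAS_CONSTANT * (t + 273.15)) * 1e-6


def berry_transpiration(area: float, tair: float, rh: float, rho_f: float) -> float:
    """Skin transpiration (g H2O h-1), fruit assumed at air temperature.

    rho_f * area * (vapor density at saturation minus ambient).
    """
    if area < 0 or rho_f < 0:
        raise ValueError("area and rho_f must be >= 0")
    delta_w = _vapor_density(_esat(tair) * (1.0 - rh / 100.0), tair)
    return rho_f * area * delta_w


def water_fluxes(
    state: BerryState,
    psi_xylem: float,
    c_phloem: float,
    tair: float,
    rh: float,
    bp: BerryParams,
) -> tuple[float, float, float]:
    """Hourly water fluxes (g h-1): (phloem influx, xylem influx, transpiration).

    Psi_berry = P - pi(berry);
    u_phloem = A Lp(FW) (Psi_xylem - Psi_berry - sigma_p (pi_phloem - pi));
    u_xylem  = A lx (Psi_xylem - Psi_berry). Either influx may be negative
    (backflow) for a turgid berry against a dry xylem.
    """
    area = bp.a_geo * state.volume ** (2.0 / 3.0)
    pi_b = osmotic_pressure(state.s_sugar, state.w_water, bp.c_other, tair)
    psi_b = state.p_turgor - pi_b
    pi_p = GAS_CONSTANT * (tair + 273.15) * c_phloem * 1e-6
    u_p = area * phloem_conductance(state.fw, bp) * (
        psi_xylem - psi_b - bp.sigma_p * (pi_p - pi_b)
    )
    u_x = area * bp.lx * (psi_xylem - psi_b)
    t_f = berry_transpiration(area, tair, rh, bp.rho_f)
    return u_p, u_x, t_f


def solve_turgor(
    state: BerryState,
    psi_xylem: float,
    c_phloem: float,
    tair: float,
    rh: float,
    bp: BerryParams,
) -> float:
    """Quasi-steady turgor P (MPa) balancing net water influx and growth.

    Solves net_influx(P) = V * phi_ext * max(0, P - Y). Both sides are
    piecewise linear in P (the influx terms are linear through Psi_berry),
    so the balance point is exact: on the growth branch
    P = (alpha + V phi Y) / (beta + V phi); below the yield threshold the
    berry neither grows nor shrinks irreversibly and P = alpha/beta, bounded
    at zero when water leaves even at full relaxation.
    """
    area = bp.a_geo * state.volume ** (2.0 / 3.0)
    pi_b = osmotic_pressure(state.s_sugar, state.w_water, bp.c_other, tair)
    pi_p = GAS_CONSTANT * (tair + 273.15) * c_phloem * 1e-6
    lp = phloem_conductance(state.fw, bp)
    t_f = berry_transpiration(area, tair, rh, bp.rho_f)
    # net(P) = alpha - beta * P
    alpha = (
        area * lp * (psi_xylem + pi_b - bp.sigma_p * (pi_p - pi_b))
        + area * bp.lx * (psi_xylem + pi_b)
        - t_f
    )
    beta = area * (lp + bp.lx)
    gamma = state.volume * bp.phi_ext
    if alpha - beta * bp.y_thresh > 0.0:
        return (alpha + gamma * bp.y_thresh) / (beta + gamma)
    return max(0.0, alpha / beta)


def berry_demand_function(
    state: BerryState,
    psi_xylem: float,
    tair: float,
    rh: float,
    bp: BerryParams,
):
    """Fast mean-berry sugar-demand closure over the phloem concentration.

    Precomputes every c-independent quantity (surface area, berry osmotic
    pressure, conductances, transpiration, the turgor-balance coefficients)
    and returns demand(c) in g sugar h-1: active Michaelis-Menten uptake
    plus the sugar advected by a positive phloem water influx evaluated at
    the quasi-steady turgor for that concentration. Algebraically identical
    to combining :func:`solve_turgor`, :func:`water_fluxes` and
    :func:`active_sugar_uptake` (asserted in the tests); used inside the
    hourly phloem balance where it is evaluated tens of times per hour.
    """
    v = state.volume
    area = bp.a_geo * v ** (2.0 / 3.0)
    pi_b = osmotic_pressure(state.s_sugar, state.w_water, bp.c_other, tair)
    lp = phloem_conductance(state.fw, bp)
    t_f = berry_transpiration(area, tair, rh, bp.rho_f)
    a_lp = area * lp
    beta = area * (lp + bp.lx)
    gamma = v * bp.phi_ext
    kappa = GAS_CONSTANT * (tair + 273.15) * 1e-6  # MPa per (mol m-3)
    a0 = (
        a_lp * (psi_xylem + pi_b + bp.sigma_p * pi_b)
        + area * bp.lx * (psi_xylem + pi_b)
        - t_f
    )
    dw = state.dw
    vmax, km, sig = bp.vmax_berry * dw, bp.km_berry, bp.sigma_p
    y, conv = bp.y_thresh, M_SUCROSE * 1e-6

    def demand(c: float) -> float:
        alpha = a0 - a_lp * sig * kappa * c
        if alpha - beta * y > 0.0:
            p = (alpha + gamma * y) / (beta + gamma)
        else:
            p = max(alpha / beta, 0.0)
        u_p = a_lp * (psi_xylem - (p - pi_b) - sig * (kappa * c - pi_b))
        passive = u_p * c * conv if u_p > 0.0 else 0.0
        return vmax * c / (km + c) + passive

    return demand


def berry_sugar_demand(
    state: BerryState,
    psi_xylem: float,
    c_phloem: float,
    tair: float,
    rh: float,
    bp: BerryParams,
) -> float:
    """Phloem sugar withdrawal (g sugar h-1) of one mean berry at a candidate
    phloem concentration: active uptake plus the sugar advected by a positive
    phloem water influx (no diffusive term)."""
    return berry_demand_function(state, psi_xylem, tair, rh, bp)(c_phloem)


def step_berry(
    state: BerryState,
    psi_xylem: float,
    c_phloem: float,
    tair: float,
    rh: float,
    bp: BerryParams,
    dt: float = 1.0,
) -> BerryState:
    """Advance the berry one time step (explicit Euler, default 1 h).

    Sub-steps (4x) whenever any mass pool would change by more than 5% in a
    single step. Masses are floored at zero with a flag. The returned state
    carries the quasi-steady turgor of the last sub-step.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")

    def one(st: BerryState, h: float) -> BerryState:
        p = solve_turgor(st, psi_xylem, c_phloem, tair, rh, bp)
        st = replace(st, p_turgor=p)
        u_p, u_x, t_f = water_fluxes(st, psi_xylem, c_phloem, tair, rh, bp)
        active = active_sugar_uptake(st.dw, c_phloem, bp)
        passive = max(u_p, 0.0) * c_phloem * M_SUCROSE * 1e-6
        resp = bp.resp_m * st.dw * bp.q10 ** ((tair - 25.0) / 10.0)
        conv = bp.k_struct * st.s_sugar
        w = st.w_water + (u_p + u_x - t_f) * h
        s = st.s_sugar + (active + passive - resp - conv) * h
        d = st.dw_struct + conv * (1.0 - bp.resp_g) * h
        floored = st.floored or w < 0 or s < 0 or d < 0
        return BerryState(
            w_water=max(w, 0.0),
            dw_struct=max(d, 0.0),
            s_sugar=max(s, 0.0),
            p_turgor=p,
            floored=floored,
        )

    # probe the full step for the largest relative pool change
    probe = one(state, dt)
    rel = 0.0
    for a, b in (
        (state.w_water, probe.w_water),
        (state.dw_struct, probe.dw_struct),
        (state.s_sugar, probe.s_sugar),
    ):
        if a > 0:
            rel = max(rel, abs(b - a) / a)
    if rel <= 0.05:
        return probe
    st = state
    for _ in range(4):
        st = one(st, dt / 4.0)
    return st


def sugar_concentration(state: BerryState) -> float:
    """Sugar concentration (g L-1) on the density-based berry volume."""
    v = state.volume
    if v <= 0:
        raise ValueError("berry volume must be > 0")
    return state.s_sugar / v * 1000.0
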