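"""Whole-plant water transport and the hourly/seasonal simulation driver.

The plant is a soil -> root surface -> stem xylem -> leaves resistance
network for one single-shoot plant (shoots are independent replicas). Each
hour the network is solved to a steady state (no capacitance): the xylem
potential satisfies

    Psi_xylem = Psi_soil - E_total * (Rsp(Psi_soil) + r_ax)

while each leaf water potential balances the hydraulic supply through the
vulnerable leaf blade, area * k_leaf_max * f_vuln(Psi_leaf) *
(Psi_xylem - Psi_leaf), against the transpiration demand of the leaf's gas
exchange state at that potential. The ABA signal produced at the collar
couples all leaves through the Tardieu-Davies conductance.

The season driver chains the hourly network with the carbon balance and the
berry model from veraison to harvest and returns a trajectory with the
extraction helpers used for calibration and evaluation (3 p.m. midday
xylem potential, observation-date matching).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .berry import BerryParams, BerryState, berry_demand_function, step_berry
from .canopy import Canopy, CanopyConfig, build_canopy, leaf_net_radiation
from .carbon import (
    CARBON_PER_UMOL_CO2,
    CarbonParams,
    OrganBiomass,
    hourly_supply,
    solve_phloem,
)
from .berry import CARBON_PER_SUGAR
from .environment import (
    DEFAULT_C_PAR,
    HourlyWeather,
    PredawnSeries,
    SoilParams,
    interpolate_predawn,
    rad_to_ppfd,
    soil_root_resistance,
)
from .leaf import (
    GasExchangeParams,
    LeafState,
    P_ATM,
    aba_concentration,
    leaf_vulnerability,
    solve_ci,
    td_stomatal_conductance,
    vcmax25_from_nitrogen,
)

__all__ = [
    "HydraulicParams",
    "PlantParams",
    "SeasonInputs",
    "HourState",
    "SeasonTrajectory",
    "solve_hour",
    "simulate_hours",
    "simulate_hydraulics",
    "run_carbon_berry",
    "replay_berry_arrays",
    "simulate_season",
    "extract_midday",
    "match_observations",
]

MG_PER_MMOL_H2O = 18.015


def _esat(t: float) -> float:
    return 0.6108 * math.exp(17.27 * t / (t + 237.3))


@dataclass(frozen=True)
class HydraulicParams:
    """Lumped axial resistance (MPa s mg-1) and maximal leaf-blade hydraulic
    conductance (mg s-1 MPa-1 m-2)."""

    r_ax: float = 0.008
    k_leaf_max: float = 150.0

    def __post_init__(self) -> None:
        if self.r_ax < 0:
            raise ValueError("r_ax must be >= 0")
        if self.k_leaf_max <= 0:
            raise ValueError("k_leaf_max must be > 0")


@dataclass(frozen=True)
class PlantParams:
    """All parameters of one simulated single-shoot plant.

    Groups the five soil-root quantities, the canopy (carrying the
    calibrated leaf nitrogen content), the gas-exchange block (with the
    calibrated Vcmax-nitrogen slope and the leaf vulnerability midpoint),
    the hydraulic network constants, the carbon-balance block, the six
    calibrated berry coefficients, and the organ biomasses.
    """

    soil: SoilParams = field(default_factory=SoilParams)
    canopy: CanopyConfig = field(default_factory=CanopyConfig)
    gx: GasExchangeParams = field(default_factory=GasExchangeParams)
    hydraulics: HydraulicParams = field(default_factory=HydraulicParams)
    carbon: CarbonParams = field(default_factory=CarbonParams)
    berry: BerryParams = field(default_factory=BerryParams)
    biomass: OrganBiomass = field(default_factory=OrganBiomass)
    berries_per_shoot: float = 80.0
    c_par: float = DEFAULT_C_PAR


@dataclass(frozen=True)
class SeasonInputs:
    """One vintage's forcing: weather, predawn series, phenology window, and
    the berry state observed at veraison."""

    weather: HourlyWeather
    predawn: PredawnSeries
    veraison: pd.Timestamp
    harvest: pd.Timestamp
    berry_init: BerryState
    label: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "veraison", pd.Timestamp(self.veraison).normalize())
        object.__setattr__(self, "harvest", pd.Timestamp(self.harvest).normalize())
        if self.harvest <= self.veraison:
            raise ValueError("harvest must follow veraison")

    def validate_coverage(self) -> None:
        start = self.veraison
        end = self.harvest + pd.Timedelta(hours=23)
        if not self.weather.covers(start, end):
            raise ValueError(
                f"weather does not cover [{start}, {end}] for vintage {self.label!r}"
            )
        if self.predawn.dates[0] > start or self.predawn.dates[-1] < end:
            raise ValueError(
                f"predawn series does not cover [{start}, {end}] for vintage {self.label!r}"
            )


@dataclass(frozen=True)
class HourState:
    """Converged hourly network solution."""

    psi_soil: float
    psi_xylem: float
    e_total: float  # mg s-1 plant-1
    aba: float
    leaf_states: tuple[LeafState, ...]
    c_phloem: float = float("nan")  # filled by the carbon balance


class ConvergenceError(RuntimeError):
    """Hourly network iteration failed; carries the residual trace."""

    def __init__(self, message: str, trace: list[float]):
        super().__init__(message)
        self.trace = trace


def solve_hour(
    canopy: Canopy,
    tair: float,
    rh: float,
    rad: float,
    psi_soil: float,
    params: PlantParams,
    warm: HourState | None = None,
    damping: float = 0.5,
    tol: float = 1e-5,
    max_iter: int = 200,
) -> HourState:
    """Solve the soil-plant network for one hour.

    Damped fixed-point iteration on Psi_xylem; inside each sweep every leaf
    water potential is re-solved by bisection (tolerance 1e-4 MPa) of the
    supply/demand balance, after which the leaf temperature is refreshed
    from the energy balance at the converged stomatal conductance. On
    convergence Psi_xylem is assigned exactly from the flux sum so the
    network identity holds to rounding.
    """
    if psi_soil > 0:
        raise ValueError("psi_soil must be <= 0")
    gx = params.gx
    hyd = params.hydraulics
    rsp = soil_root_resistance(params.soil, psi_soil)
    r_tot = rsp + hyd.r_ax
    leaves = canopy.leaves
    nl = len(leaves)
    ppfd0 = rad_to_ppfd(rad, params.c_par)
    k_ext = canopy.config.k_ext
    alpha_leaf = canopy.config.alpha_leaf
    ppfd = [ppfd0 * math.exp(-k_ext * l.lai_above) for l in leaves]
    rn = [leaf_net_radiation(q, tair, rad, params.c_par, alpha_leaf) for q in ppfd]
    vcmax25 = vcmax25_from_nitrogen(canopy.config.leafN_content, gx.slope_vcmax)
    ea = _esat(tair) * rh / 100.0

    from .leaf import leaf_energy_balance  # local: hot path

    if warm is not None and len(warm.leaf_states) == nl:
        psi_x = warm.psi_xylem
        psi_l = [s.psi_leaf for s in warm.leaf_states]
        t_l = [s.t_leaf for s in warm.leaf_states]
        e_mg = [
            s.e * MG_PER_MMOL_H2O * leaves[i].area for i, s in enumerate(warm.leaf_states)
        ]
    else:
        psi_x = psi_soil - 0.05
        psi_l = [psi_x - 0.1] * nl
        t_l = [tair] * nl
        e_mg = [0.0] * nl

    gs_l = [gx.gs_min] * nl
    dpsi_l = [0.3] * nl  # last per-leaf root movement, sizes the warm window
    trace: list[float] = []
    converged = False
    # hot-loop locals: the leaf balance below inlines the TD conductance and
    # the vulnerability logistic (same expressions as in vinesim.leaf)
    mexp = math.exp
    gs_min, gb = gx.gs_min, gx.gb
    beta_td, delta_td, i50 = gx.beta_td, gx.delta_td, gx.i50
    psi50, s_vuln = gx.psi50_leaf, gx.s_vuln
    k_leaf_max = hyd.k_leaf_max
    for it in range(max_iter):
        if it and it % 50 == 0:
            # persistent limit cycle: stabilize by halving the damping
            damping *= 0.5
        e_total = sum(e_mg)
        aba = aba_concentration(psi_x, e_total, gx)
        target = psi_soil - e_total * r_tot
        new_psi_x = psi_x + damping * (target - psi_x)
        delta = abs(new_psi_x - psi_x)
        trace.append(delta)
        psi_x = new_psi_x
        b_aba = beta_td * aba
        for i in range(nl):
            area = leaves[i].area
            k_blade = k_leaf_max * area
            # vapor gradient at lagged leaf temperature, g_tv applied later
            c_vap = max(_esat(t_l[i]) - ea, 0.0) / P_ATM * 1000.0 * MG_PER_MMOL_H2O * area
            f_i = ppfd[i] / (ppfd[i] + i50) if ppfd[i] > 0 else 0.0
            a_td = gx.alpha_td * f_i

            # Leaf water-potential balance, inlined for the hot path (same
            # expressions as leaf.td_stomatal_conductance/leaf_vulnerability):
            #   balance(psi) = k_blade * f_vuln(psi) * (psi_x - psi)
            #                  - c_vap / (1/gs(psi) + 1/gb)
            # Supply is single-humped in psi (logistic vulnerability) and
            # demand is monotone, so the balance is positive on at most ONE
            # interval; its upper edge is the shallow (hydraulically stable)
            # root. balance(psi_x) <= 0 since supply vanishes there. The
            # canonical root is therefore found either by walking UP from a
            # point known to be inside the positive interval (warm start) or
            # by scanning DOWN from psi_x for the first crossing.
            def balance(psi: float) -> float:
                x = s_vuln * (psi50 - psi)
                f = 0.0 if x > 700.0 else 1.0 / (1.0 + mexp(x))
                gs_b = gs_min + a_td * mexp(max(b_aba * mexp(min(delta_td * psi, 50.0)), -700.0))
                return k_blade * f * (psi_x - psi) - c_vap / (1.0 / gs_b + 1.0 / gb)

            lo = None
            hi = psi_x
            start = psi_l[i] - 0.04
            if start < psi_x - 1e-9 and balance(start) > 0.0:
                lo = start
                hi = min(start + 0.08, psi_x)
                while hi < psi_x and balance(hi) > 0.0:
                    lo = hi
                    hi = min(hi + 0.08, psi_x)
            if lo is None:
                best_psi, best_bal = psi_x, -float("inf")
                probe = psi_x - 0.08
                for _ in range(140):
                    b = balance(probe)
                    if b > 0.0:
                        lo = probe
                        break
                    if b > best_bal:
                        best_psi, best_bal = probe, b
                    hi = probe
                    probe -= 0.08
            if lo is None:
                # demand exceeds the maximal vulnerable supply everywhere:
                # pin the leaf at the least-deficit potential and cap its
                # flux at the supply there. Using the SUPPLY value keeps the
                # network map continuous across the root-existence boundary
                # (at the boundary supply and demand are tangent).
                psi_leaf = best_psi
                gs = td_stomatal_conductance(aba, psi_leaf, ppfd[i], gx)
                dpsi_l[i] = abs(psi_leaf - psi_l[i]) + 1e-3
                psi_l[i] = psi_leaf
                x = s_vuln * (psi50 - psi_leaf)
                f_v = 0.0 if x > 700.0 else 1.0 / (1.0 + mexp(x))
                t_leaf, _ = leaf_energy_balance(
                    tair, rn[i], gs, gx.gb, rh, t_init=t_l[i]
                )
                t_l[i] = t_leaf
                e_new = max(k_blade * f_v * (psi_x - psi_leaf), 0.0)
                e_mg[i] += 0.6 * (e_new - e_mg[i])
                gs_l[i] = gs
                continue
            while hi - lo >= 1e-6:
                mid = 0.5 * (lo + hi)
                if balance(mid) > 0.0:
                    lo = mid
                else:
                    hi = mid
            psi_leaf = 0.5 * (lo + hi)
            gs = td_stomatal_conductance(aba, psi_leaf, ppfd[i], gx)
            dpsi_l[i] = abs(psi_leaf - psi_l[i]) + 1e-3
            psi_l[i] = psi_leaf
            # energy balance depends on the hour's forcing and gs only:
            # skip the re-solve once gs has stopped moving
            if it == 0 or abs(gs - gs_l[i]) > 1e-8 * (gs + 1e-3):
                t_leaf, e_mmol = leaf_energy_balance(
                    tair, rn[i], gs, gx.gb, rh, t_init=t_l[i]
                )
                t_l[i] = t_leaf
                # relax the flux update: stabilizes the coupled iteration
                # near branch boundaries without moving the fixed point
                e_new = e_mmol * MG_PER_MMOL_H2O * area
                e_mg[i] += 0.6 * (e_new - e_mg[i])
            gs_l[i] = gs
        if it >= 2 and delta < tol:
            converged = True
            break
    if not converged:
        # a residual limit cycle within a small multiple of the tolerance is
        # accepted (the exact flux-sum assignment below closes the network
        # identity regardless); anything larger is a genuine failure
        if min(trace[-10:]) >= 20.0 * tol:
            raise ConvergenceError(
                f"hourly network did not converge in {max_iter} iterations "
                f"(last step {trace[-1]:.3e} MPa); psi_soil={psi_soil}, tair={tair}",
                trace,
            )
    e_total = sum(e_mg)
    psi_x = psi_soil - e_total * r_tot  # exact network identity
    aba = aba_concentration(psi_x, e_total, gx)
    states = []
    for i, leaf in enumerate(leaves):
        ci, an, lim = solve_ci(gs_l[i], t_l[i], ppfd[i], gx, vcmax25)
        states.append(
            LeafState(
                ci=ci,
                gs=gs_l[i],
                an=an,
                e=e_mg[i] / (MG_PER_MMOL_H2O * leaf.area),
                t_leaf=t_l[i],
                psi_leaf=psi_l[i],
                limitation=lim,
            )
        )
    return HourState(
        psi_soil=psi_soil,
        psi_xylem=psi_x,
        e_total=e_total,
        aba=aba,
        leaf_states=tuple(states),
    )


def simulate_hours(
    inputs: SeasonInputs,
    params: PlantParams,
    timestamps: pd.DatetimeIndex,
    warm_starts: dict[pd.Timestamp, HourState] | None = None,
    tol: float = 1e-5,
) -> list[HourState]:
    """Solve the hydraulic network at selected hours only.

    The steady-state network has no memory, so hours can be solved
    independently; used by the calibration stages whose likelihood needs
    only the observation hours. ``warm_starts`` may carry solutions from a
    previous parameter vector to cut iterations.
    """
    canopy = build_canopy(params.canopy)
    wx = inputs.weather.frame
    out = []
    for ts in timestamps:
        row = wx.loc[ts]
        psi_soil = interpolate_predawn(inputs.predawn, ts)
        warm = warm_starts.get(ts) if warm_starts is not None else None
        hs = solve_hour(
            canopy, float(row["tair"]), float(row["rh"]), float(row["rad"]),
            psi_soil, params, warm, tol=tol,
        )
        if warm_starts is not None:
            warm_starts[ts] = hs
        out.append(hs)
    return out


@dataclass
class SeasonTrajectory:
    """Hourly simulation output with extraction helpers.

    ``hourly`` holds one row per hour (plant water status, carbon balance,
    berry state); ``leaf_hourly`` summarizes the top-of-canopy leaf used for
    gas-exchange comparisons.
    """

    hourly: pd.DataFrame
    inputs: SeasonInputs
    params: PlantParams

    def extract_midday(self, hour: int = 15) -> pd.Series:
        return extract_midday(self, hour)

    def match_observations(self, obs: pd.DataFrame):
        return match_observations(self, obs)

    def daily_summary(self) -> pd.DataFrame:
        """Wide daily table: midday xylem potential, daily assimilation and
        transpiration integrals, end-of-day berry state."""
        df = self.hourly
        day = df.index.normalize()
        g = df.groupby(day)
        midday = self.extract_midday()
        out = pd.DataFrame(
            {
                "psi_xylem_midday_mpa": midday,
                "an_total_mol_day": g["an_total"].sum() * 3600e-6,
                "e_total_g_day": g["e_total"].sum() * 3600e-3,
                "berry_fw_g": g["berry_fw"].last(),
                "berry_dw_g": g["berry_dw"].last(),
                "sugar_g_per_l": g["berry_sugar_conc"].last(),
            }
        )
        return out


def extract_midday(traj: SeasonTrajectory, hour: int = 15) -> pd.Series:
    """Daily series of the simulated xylem potential at the given hour
    (default 15:00, the 3 p.m. extraction convention)."""
    df = traj.hourly
    sel = df[df.index.hour == hour]
    if sel.empty:
        raise ValueError(f"trajectory has no hour == {hour}")
    days = pd.DatetimeIndex(df.index.normalize().unique())
    if len(sel) != len(days):
        raise ValueError(f"hour {hour} missing on some simulated days")
    out = sel["psi_xylem"].copy()
    out.index = sel.index.normalize()
    return out


VALID_OBS_VARIABLES = {
    "psi_xylem_midday": ("psi_xylem", 15),
    "berry_fw_g": ("berry_fw", 23),
    "berry_dw_g": ("berry_dw", 23),
    "sugar_g_per_l": ("berry_sugar_conc", 23),
}


def match_observations(
    traj: SeasonTrajectory, obs: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pair observations with simulated values.

    ``obs`` needs columns date/variable/value. Midday xylem potential pairs
    at 15:00; berry variables pair at the end-of-day state. Returns
    (paired, unmatched); unmatched dates are reported, not fatal.
    """
    required = {"date", "variable", "value"}
    if not required <= set(obs.columns):
        raise ValueError(f"observation table needs columns {sorted(required)}")
    df = traj.hourly
    rows, missed = [], []
    for _, r in obs.iterrows():
        var = r["variable"]
        if var not in VALID_OBS_VARIABLES:
            raise ValueError(f"unknown observation variable {var!r}")
        col, hour = VALID_OBS_VARIABLES[var]
        ts = pd.Timestamp(r["date"]).normalize() + pd.Timedelta(hours=hour)
        if ts in df.index:
            rows.append(
                {
                    "date": pd.Timestamp(r["date"]).normalize(),
                    "variable": var,
                    "observed": float(r["value"]),
                    "simulated": float(df.loc[ts, col]),
                }
            )
        else:
            missed.append({"date": r["date"], "variable": var, "value": r["value"]})
    return pd.DataFrame(rows), pd.DataFrame(missed)


def simulate_hydraulics(inputs: SeasonInputs, params: PlantParams) -> pd.DataFrame:
    """Hourly hydraulic/gas-exchange pass from veraison 00:00 to harvest 23:00.

    The steady-state network does not depend on the carbon or berry state,
    so this pass can be computed once and the carbon/berry chain replayed
    on top of it (used heavily by the berry calibration stages). Returns
    an hourly DataFrame with forcing, plant water status, and the carbon
    supply.
    """
    inputs.validate_coverage()
    canopy = build_canopy(params.canopy)
    areas = [l.area for l in canopy.leaves]
    wx = inputs.weather.frame
    index = pd.date_range(
        inputs.veraison, inputs.harvest + pd.Timedelta(hours=23), freq="h"
    )
    warm: HourState | None = None
    records = []
    for ts in index:
        row = wx.loc[ts]
        tair, rh, rad = float(row["tair"]), float(row["rh"]), float(row["rad"])
        psi_soil = interpolate_predawn(inputs.predawn, ts)
        hs = solve_hour(canopy, tair, rh, rad, psi_soil, params, warm)
        warm = hs
        an_rates = [s.an for s in hs.leaf_states]
        top = hs.leaf_states[0]
        records.append(
            {
                "timestamp": ts,
                "tair": tair,
                "rh": rh,
                "rad": rad,
                "psi_soil": psi_soil,
                "psi_xylem": hs.psi_xylem,
                "e_total": hs.e_total,
                "aba": hs.aba,
                "an_total": sum(a * ar for a, ar in zip(an_rates, areas)),
                "gs_top": top.gs,
                "an_top": top.an,
                "psi_leaf_top": top.psi_leaf,
                "psi_leaf_min": min(s.psi_leaf for s in hs.leaf_states),
                "t_leaf_top": top.t_leaf,
                "supply_gc": hourly_supply(an_rates, areas),
            }
        )
    return pd.DataFrame.from_records(records).set_index("timestamp")


def run_carbon_berry(
    hydro: pd.DataFrame,
    params: PlantParams,
    berry_init: BerryState,
) -> pd.DataFrame:
    """Replay the hourly carbon balance and berry model over a hydraulic pass.

    ``hydro`` must carry columns psi_xylem, tair, rh, supply_gc (as produced
    by :func:`simulate_hydraulics`). Returns an hourly DataFrame aligned to
    the same index with phloem, allocation, and berry-state columns.
    """
    biomass = params.biomass
    berry_state = berry_init
    bp = params.berry
    cp = params.carbon
    nb = params.berries_per_shoot
    psi_x = hydro["psi_xylem"].to_numpy()
    tair_a = hydro["tair"].to_numpy()
    rh_a = hydro["rh"].to_numpy()
    supply_a = hydro["supply_gc"].to_numpy()
    records = []
    for k in range(len(hydro)):
        psi_xylem, tair, rh, supply = psi_x[k], tair_a[k], rh_a[k], supply_a[k]
        per_berry = berry_demand_function(berry_state, psi_xylem, tair, rh, bp)
        scale = nb * CARBON_PER_SUGAR

        def demand_c(c: float) -> float:
            return per_berry(c) * scale

        sol = solve_phloem(supply, demand_c, biomass, tair, cp)
        biomass = replace(biomass, reserve=max(biomass.reserve + sol.d_reserve, 0.0))
        berry_state = step_berry(berry_state, psi_xylem, sol.c_phloem, tair, rh, bp)
        records.append(
            {
                "c_phloem": sol.c_phloem,
                "maintenance_gc": sol.maintenance,
                "alloc_berry_gc": sol.berry,
                "alloc_fine_root_gc": sol.fine_root,
                "d_reserve_gc": sol.d_reserve,
                "reserve_gc": biomass.reserve,
                "starvation": sol.starvation,
                "berry_fw": berry_state.fw,
                "berry_dw": berry_state.dw,
                "berry_w_water": berry_state.w_water,
                "berry_s_sugar": berry_state.s_sugar,
                "berry_sugar_conc": berry_state.sugar_conc,
                "berry_turgor": berry_state.p_turgor,
            }
        )
    return pd.DataFrame.from_records(records, index=hydro.index)


def replay_berry_arrays(
    hydro: pd.DataFrame,
    params: PlantParams,
    berry_init: BerryState,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Lean carbon/berry replay returning only (fw, dw, sugar_conc) arrays.

    Same hour chain as :func:`run_carbon_berry` (asserted equal in the
    tests) without the per-hour record assembly; used inside the berry
    calibration likelihoods where it runs thousands of times.
    """
    biomass = params.biomass
    reserve = biomass.reserve
    berry_state = berry_init
    bp = params.berry
    cp = params.carbon
    nb = params.berries_per_shoot
    psi_x = hydro["psi_xylem"].to_numpy()
    tair_a = hydro["tair"].to_numpy()
    rh_a = hydro["rh"].to_numpy()
    supply_a = hydro["supply_gc"].to_numpy()
    n = len(psi_x)
    fw = np.empty(n)
    dw = np.empty(n)
    conc = np.empty(n)
    scale = nb * CARBON_PER_SUGAR
    for k in range(n):
        psi_xylem, tair, rh, supply = psi_x[k], tair_a[k], rh_a[k], supply_a[k]
        per_berry = berry_demand_function(berry_state, psi_xylem, tair, rh, bp)
        sol = solve_phloem(
            supply, lambda c: per_berry(c) * scale, biomass, tair, cp, reserve=reserve
        )
        reserve = max(reserve + sol.d_reserve, 0.0)
        berry_state = step_berry(berry_state, psi_xylem, sol.c_phloem, tair, rh, bp)
        fw[k] = berry_state.fw
        dw[k] = berry_state.dw
        conc[k] = berry_state.sugar_conc
    return fw, dw, conc


def simulate_season(inputs: SeasonInputs, params: PlantParams) -> SeasonTrajectory:
    """Simulate one vintage hourly from veraison 00:00 to harvest 23:00.

    Each hour: interpolate the predawn-potential proxy for soil water
    status, solve the hydraulic/gas-exchange network, close the carbon
    balance for the phloem concentration, and advance the mean berry.
    Deterministic given inputs and parameters.
    """
    hydro = simulate_hydraulics(inputs, params)
    cb = run_carbon_berry(hydro, params, inputs.berry_init)
    hourly = pd.concat([hydro, cb], axis=1)
    return SeasonTrajectory(hourly=hourly, inputs=inputs, params=params)
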