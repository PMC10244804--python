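"""Whole-plant hourly carbon bookkeeping.

Photosynthetic supply, temperature-dependent maintenance respiration, a
mobilizable reserve pool, and the phloem sucrose concentration solved each
hour so that carbon loading equals unloading across sinks. Post-veraison
structural growth of leaves and internodes is zero (the canopy is fixed),
so the competing sinks are the berries, fine-root turnover, and reserve
deposition.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable

__all__ = [
    "OrganBiomass",
    "CarbonParams",
    "PhloemSolution",
    "maintenance_respiration",
    "hourly_supply",
    "solve_phloem",
    "CARBON_PER_UMOL_CO2",
]

CARBON_PER_UMOL_CO2 = 12.011e-6  # g C per umol CO2


@dataclass(frozen=True)
class OrganBiomass:
    """Dry mass of the organ compartments of one single-shoot plant (g).

    Structural roots are pooled with the trunk (they cycle carbohydrate the
    same way); ``reserve`` is the mobilizable carbohydrate pool in g C.
    """

    leaf: float = 20.8
    internode: float = 15.0
    trunk_plus_structural_root: float = 180.0
    fine_root: float = 5.0
    berry_total: float = 0.0
    reserve: float = 20.0

    def __post_init__(self) -> None:
        for name in (
            "leaf",
            "internode",
            "trunk_plus_structural_root",
            "fine_root",
            "berry_total",
            "reserve",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class CarbonParams:
    """Carbon balance coefficients.

    Maintenance coefficients ``m_*`` are g C per g DW per hour at 25 degC
    with Q10 temperature scaling. The berry class defaults to zero because
    berry respiration is charged inside the berry module against its own
    sugar pool. Non-berry sinks follow Michaelis-Menten kinetics in the
    phloem sucrose concentration (mol m-3); reserve mobilization declines
    with rising concentration and is capped by the pool and by
    ``mobilization_max``.
    """

    m_leaf: float = 3.0e-4
    m_internode: float = 6.0e-5
    m_trunk: float = 1.5e-5
    m_fine_root: float = 4.5e-4
    m_berry: float = 0.0
    q10: float = 2.0
    mobilization_max: float = 0.06  # g C h-1
    km_mobilization: float = 300.0  # mol m-3
    vmax_fine_root: float = 0.22  # g C h-1
    km_fine_root: float = 400.0
    vmax_reserve: float = 0.22  # g C h-1
    km_reserve: float = 500.0
    reserve_max: float = 60.0  # g C
    c_max: float = 1500.0  # mol m-3 upper bracket for the balance root

    def __post_init__(self) -> None:
        for name in (
            "q10",
            "mobilization_max",
            "km_mobilization",
            "vmax_fine_root",
            "km_fine_root",
            "vmax_reserve",
            "km_reserve",
            "reserve_max",
            "c_max",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


@dataclass(frozen=True)
class PhloemSolution:
    """Converged hourly carbon balance."""

    c_phloem: float  # mol m-3
    berry: float  # g C h-1 allocated to berries
    fine_root: float  # g C h-1
    d_reserve: float  # g C h-1 (deposition - mobilization)
    maintenance: float  # g C h-1 actually paid
    starvation: bool
    overflow: bool

    @property
    def allocations(self) -> dict[str, float]:
        return {"berry": self.berry, "fine_root": self.fine_root}


def maintenance_respiration(biomass: OrganBiomass, t: float, p: CarbonParams) -> float:
    """Maintenance respiration (g C h-1): sum over organs of m_k DW_k Q10^((T-25)/10)."""
    base = (
        p.m_leaf * biomass.leaf
        + p.m_internode * biomass.internode
        + p.m_trunk * biomass.trunk_plus_structural_root
        + p.m_fine_root * biomass.fine_root
        + p.m_berry * biomass.berry_total
    )
    return base * p.q10 ** ((t - 25.0) / 10.0)


def hourly_supply(an_rates: list[float], areas: list[float]) -> float:
    """Photosynthetic carbon supply (g C h-1) from per-leaf net assimilation.

    Sum of An_i (umol CO2 m-2 s-1) times leaf area times 3600 s, converted
    to grams of carbon; negative An (net respiration) contributes negatively.
    """
    if len(an_rates) != len(areas):
        raise ValueError("an_rates and areas lengths differ")
    return sum(an * area for an, area in zip(an_rates, areas)) * 3600.0 * CARBON_PER_UMOL_CO2


def solve_phloem(
    supply: float,
    berry_demand: Callable[[float], float],
    biomass: OrganBiomass,
    t: float,
    p: CarbonParams,
    n_scan: int = 64,
    reserve: float | None = None,
) -> PhloemSolution:
    """Phloem sucrose concentration closing the hourly carbon balance.

    Finds c in [0, c_max] such that

        supply + mobilization(c) = maintenance + berry(c) + fine_root(c)
                                 + deposition(c)

    ``berry_demand`` maps a candidate concentration to the whole-plant berry
    withdrawal (g C h-1) and must be continuous. Because the advective berry
    term is not guaranteed monotone at high concentrations, the solver scans
    upward from c = 0 and bisects the first sign change, which keeps the
    solution continuous through time and monotone in supply. If maintenance
    cannot be paid even with maximal mobilization the hour is flagged as
    carbon starvation (maintenance scaled to what is available, sinks idle);
    if the balance is still positive at c_max the excess is deposited to the
    reserve and flagged as overflow.
    """
    if supply < -1e-12:
        supply = supply  # negative night-time supply is legitimate
    maintenance = maintenance_respiration(biomass, t, p)
    if reserve is None:
        reserve = biomass.reserve
    room = max(p.reserve_max - reserve, 0.0)

    def mobilization(c: float) -> float:
        return min(
            p.mobilization_max * p.km_mobilization / (p.km_mobilization + c), reserve
        )

    def deposition(c: float) -> float:
        return min(p.vmax_reserve * c / (p.km_reserve + c), room)

    def fine_root(c: float) -> float:
        return p.vmax_fine_root * c / (p.km_fine_root + c)

    def residual(c: float) -> float:
        return (
            supply
            + mobilization(c)
            - maintenance
            - berry_demand(c)
            - fine_root(c)
            - deposition(c)
        )

    tol = 1e-9 * max(abs(supply), 1.0)
    r0 = residual(0.0)
    if r0 < 0.0:
        # cannot pay maintenance: starvation, sinks idle, reserve drained
        mob = mobilization(0.0)
        return PhloemSolution(
            c_phloem=0.0,
            berry=0.0,
            fine_root=0.0,
            d_reserve=-mob,
            maintenance=supply + mob,
            starvation=True,
            overflow=False,
        )
    lo, r_lo = 0.0, r0
    hi = None
    step = p.c_max / n_scan
    c = step
    while c <= p.c_max + 1e-12:
        r = residual(c)
        if r <= 0.0:
            hi = c
            break
        lo, r_lo = c, r
        c += step
    if hi is None:
        # sinks saturated below supply even at c_max: surplus to reserve
        c_star = p.c_max
        surplus = residual(c_star)
        mob = mobilization(c_star)
        dep = deposition(c_star) + surplus
        overflow = reserve + dep - mob > p.reserve_max + 1e-12
        return PhloemSolution(
            c_phloem=c_star,
            berry=berry_demand(c_star),
            fine_root=fine_root(c_star),
            d_reserve=dep - mob,
            maintenance=maintenance,
            starvation=False,
            overflow=overflow,
        )
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        r = residual(mid)
        if abs(r) < tol or (hi - lo) < 1e-12:
            lo = hi = mid
            break
        if r > 0.0:
            lo = mid
        else:
            hi = mid
    c_star = 0.5 * (lo + hi)
    return PhloemSolution(
        c_phloem=c_star,
        berry=berry_demand(c_star),
        fine_root=fine_root(c_star),
        d_reserve=deposition(c_star) - mobilization(c_star),
        maintenance=maintenance,
        starvation=False,
        overflow=False,
    )
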