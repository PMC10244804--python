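"""Leaf-scale coupled gas exchange.

FvCB biochemical photosynthesis (Rubisco- and electron-transport-limited),
Tardieu-Davies stomatal conductance combining a chemical (xylem ABA) and a
hydraulic (leaf water potential) signal, a logistic leaf hydraulic
vulnerability curve, and the leaf energy balance.

With the ABA signal and the leaf water potential prescribed, the TD
conductance is explicit, the energy balance is a 1-D root in leaf
temperature, and the CO2 diffusion / biochemistry coupling reduces to a
quadratic per limitation branch, so a single leaf state is solved by a
direct cascade gs -> T_leaf -> Ci rather than by damped iteration. The
whole-plant feedback (Ci/gs/T_leaf consistent with the hydraulic network)
lives in :mod:`vinesim.plant`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "GasExchangeParams",
    "LeafState",
    "vcmax25_from_nitrogen",
    "arrhenius",
    "electron_transport",
    "fvcb_assimilation",
    "aba_concentration",
    "td_stomatal_conductance",
    "leaf_vulnerability",
    "leaf_energy_balance",
    "solve_ci",
    "solve_leaf",
]

GAS_CONSTANT = 8.314  # J mol-1 K-1
T25_K = 298.15
CP_MOL = 29.3  # molar heat capacity of air, J mol-1 K-1
LAMBDA_MOL = 44100.0  # latent heat of vaporization, J mol-1
SIGMA_SB = 5.67e-8  # W m-2 K-4
P_ATM = 101.325  # kPa
EMISSIVITY = 0.97


def _esat(t: float) -> float:
    """Tetens saturation vapor pressure, kPa (unchecked range)."""
    return 0.6108 * math.exp(17.27 * t / (t + 237.3))


@dataclass(frozen=True)
class GasExchangeParams:
    """Leaf gas-exchange coefficients.

    Calibrated quantities: ``slope_vcmax`` (umol CO2 g-1 N s-1, slope of the
    Vcmax25-leaf nitrogen regression, zero intercept) and ``psi50_leaf``
    (MPa, water potential at 50% loss of leaf hydraulic conductance; field
    default -1.80). Everything else is a documented fixed default: FvCB
    kinetics at 25 degC with Arrhenius temperature scaling, the
    non-rectangular-hyperbola light response of electron transport, and the
    Tardieu-Davies coefficients (``beta_td``, ``delta_td`` both negative:
    ABA closes stomata more strongly at more negative leaf water potential).
    """

    slope_vcmax: float = 47.0
    jmax_ratio: float = 1.67
    rd_frac: float = 0.015
    kc25: float = 404.9  # umol mol-1
    ko25: float = 278.4  # mmol mol-1
    gamma_star25: float = 42.75  # umol mol-1
    o2: float = 210.0  # mmol mol-1
    ea_vcmax: float = 65330.0
    ea_jmax: float = 43540.0
    ea_rd: float = 46390.0
    ea_kc: float = 79430.0
    ea_ko: float = 36380.0
    ea_gamma_star: float = 37830.0
    theta_j: float = 0.7
    phi_j: float = 0.3  # mol e- per mol photon
    gs_min: float = 0.02  # mol H2O m-2 s-1
    alpha_td: float = 0.32
    beta_td: float = -2.0
    delta_td: float = -1.5
    i50: float = 250.0  # umol m-2 s-1, half-saturation of the light factor
    a_aba: float = 1.0
    b_aba: float = 10.0  # mg s-1
    psi50_leaf: float = -1.80
    s_vuln: float = 5.0  # MPa-1
    gb: float = 1.0  # mol m-2 s-1 boundary-layer conductance (per run)
    ca: float = 400.0  # umol mol-1

    def __post_init__(self) -> None:
        if self.psi50_leaf >= 0:
            raise ValueError("psi50_leaf must be < 0 MPa")
        if self.gs_min < 0:
            raise ValueError("gs_min must be >= 0")
        if not 0 < self.theta_j <= 1:
            raise ValueError("theta_j must lie in (0, 1]")
        if self.beta_td >= 0 or self.delta_td >= 0:
            raise ValueError("beta_td and delta_td must be negative")
        if self.b_aba <= 0:
            raise ValueError("b_aba must be > 0")
        if self.s_vuln <= 0:
            raise ValueError("s_vuln must be > 0")
        for name in ("kc25", "ko25", "gamma_star25", "gb"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


@dataclass(frozen=True)
class LeafState:
    """Converged leaf solution for one hour."""

    ci: float  # umol mol-1
    gs: float  # mol H2O m-2 s-1
    an: float  # umol CO2 m-2 s-1
    e: float  # mmol H2O m-2 s-1
    t_leaf: float  # degC
    psi_leaf: float  # MPa
    limitation: str = ""


def vcmax25_from_nitrogen(na: float, slope_vcmax: float) -> float:
    """Vcmax at 25 degC from leaf nitrogen per area (zero intercept)."""
    if na < 0:
        raise ValueError("leaf nitrogen per area must be >= 0")
    return slope_vcmax * na


def arrhenius(k25: float, ea: float, t_leaf: float) -> float:
    """Arrhenius scaling of a rate constant from 25 degC to ``t_leaf``."""
    tk = t_leaf + 273.15
    return k25 * math.exp(ea * (tk - T25_K) / (T25_K * GAS_CONSTANT * tk))


def electron_transport(ppfd: float, jmax: float, theta: float, phi: float) -> float:
    """Electron transport rate J: smaller root of the non-rectangular hyperbola

    theta*J^2 - (phi*PPFD + Jmax)*J + phi*PPFD*Jmax = 0.
    """
    if ppfd <= 0 or jmax <= 0:
        return 0.0
    b = phi * ppfd + jmax
    disc = b * b - 4.0 * theta * phi * ppfd * jmax
    return (b - math.sqrt(max(disc, 0.0))) / (2.0 * theta)


def fvcb_assimilation(
    ci: float, t_leaf: float, ppfd: float, p: GasExchangeParams, vcmax25: float
) -> tuple[float, str]:
    """Net assimilation An (umol m-2 s-1) at prescribed Ci and leaf temperature.

    An = min(Ac, Aj) - Rd with Ac = Vcmax (Ci - G*) / (Ci + Kc(1 + O/Ko)) and
    Aj = J (Ci - G*) / (4 Ci + 8 G*); all constants Arrhenius-scaled.
    Returns the rate and which branch limited ("rubisco" or "rubp").
    """
    if ci <= 0:
        raise ValueError("ci must be > 0")
    vcmax = arrhenius(vcmax25, p.ea_vcmax, t_leaf)
    jmax = arrhenius(vcmax25 * p.jmax_ratio, p.ea_jmax, t_leaf)
    rd = arrhenius(vcmax25 * p.rd_frac, p.ea_rd, t_leaf)
    kc = arrhenius(p.kc25, p.ea_kc, t_leaf)
    ko = arrhenius(p.ko25, p.ea_ko, t_leaf)
    gstar = arrhenius(p.gamma_star25, p.ea_gamma_star, t_leaf)
    km = kc * (1.0 + p.o2 / ko)
    j = electron_transport(ppfd, jmax, p.theta_j, p.phi_j)
    ac = vcmax * (ci - gstar) / (ci + km)
    aj = j * (ci - gstar) / (4.0 * ci + 8.0 * gstar)
    if ac <= aj:
        return ac - rd, "rubisco"
    return aj - rd, "rubp"


def aba_concentration(psi_collar: float, e_plant: float, p: GasExchangeParams) -> float:
    """Xylem ABA signal (relative units) from collar potential and plant flux.

    [ABA] = a_aba * max(0, -psi_collar) / (e_plant + b_aba): production scales
    with root water stress and is diluted by the transpiration stream.
    """
    if e_plant < 0:
        raise ValueError("plant water flux must be >= 0")
    return p.a_aba * max(0.0, -psi_collar) / (e_plant + p.b_aba)


def td_stomatal_conductance(
    aba: float, psi_leaf: float, ppfd: float, p: GasExchangeParams
) -> float:
    """Tardieu-Davies stomatal conductance (mol H2O m-2 s-1).

    gs = gs_min + alpha_td * f_I(PPFD) * exp(beta_td * ABA * exp(delta_td * psi_leaf))

    with f_I = PPFD/(PPFD + I50). Since beta_td < 0 and delta_td < 0, gs
    falls with ABA and falls further as psi_leaf becomes more negative,
    approaching gs_min under extreme stress.
    """
    if aba < 0:
        raise ValueError("ABA signal must be >= 0")
    f_i = ppfd / (ppfd + p.i50) if ppfd > 0 else 0.0
    inner = min(p.delta_td * psi_leaf, 50.0)
    expo = max(p.beta_td * aba * math.exp(inner), -700.0)
    return p.gs_min + p.alpha_td * f_i * math.exp(expo)


def leaf_vulnerability(psi_leaf: float, psi50_leaf: float, s_vuln: float) -> float:
    """Fraction of maximal leaf hydraulic conductance at ``psi_leaf``.

    Logistic curve f = 1 / (1 + exp(s_vuln * (psi50_leaf - psi_leaf))):
    f(psi50) = 0.5, f -> 1 toward zero potential, strictly increasing.
    """
    if s_vuln <= 0:
        raise ValueError("s_vuln must be > 0")
    x = s_vuln * (psi50_leaf - psi_leaf)
    if x > 700.0:
        return 0.0
    return 1.0 / (1.0 + math.exp(x))


def leaf_energy_balance(
    tair: float, rn_abs: float, gs: float, gb: float, rh: float,
    t_init: float | None = None,
) -> tuple[float, float]:
    """Leaf temperature and transpiration from the energy balance.

    Solves Rn = H + lambda*E for t_leaf in [tair-15, tair+15], where
    H = (cp*gbH + gR) (t_leaf - tair) includes two-sided sensible exchange
    and a longwave radiative conductance linearized around tair, and
    E = g_tv (esat(t_leaf) - ea) / P with the stomatal and boundary-layer
    conductances in series. Bisection bracketing followed by Newton polish
    to a residual below 1e-8 W m-2. Returns (t_leaf degC, E mmol m-2 s-1).
    """
    if gs <= 0 or gb <= 0:
        raise ValueError("gs and gb must be > 0")
    mexp = math.exp
    ea = 0.6108 * mexp(17.27 * tair / (tair + 237.3)) * rh / 100.0
    g_tv = 1.0 / (1.0 / gs + 1.0 / gb)
    g_bh = 0.924 * 2.0 * gb
    g_rad = 4.0 * EMISSIVITY * SIGMA_SB * (tair + 273.15) ** 3  # W m-2 K-1
    h_coef = CP_MOL * g_bh + g_rad
    lam_g = LAMBDA_MOL * g_tv / P_ATM
    lo_b, hi_b = tair - 15.0, tair + 15.0

    def newton(t0: float) -> float | None:
        # the residual rn - h(t - tair) - lam*(esat(t) - ea) is smooth and
        # strictly decreasing in t; plain Newton from a warm start
        tl = t0
        for _ in range(12):
            es = 0.6108 * mexp(17.27 * tl / (tl + 237.3))
            f = rn_abs - h_coef * (tl - tair) - lam_g * (es - ea)
            if -1e-9 < f < 1e-9:
                return tl
            df = -h_coef - lam_g * es * 17.27 * 237.3 / (tl + 237.3) ** 2
            tl -= f / df
            if tl < lo_b or tl > hi_b:
                return None
        return None

    tl = newton(t_init if t_init is not None else tair)
    if tl is None:
        # bisection bracketing fallback
        def resid(t: float) -> float:
            return rn_abs - h_coef * (t - tair) - lam_g * (_esat(t) - ea)

        lo, hi = lo_b, hi_b
        f_lo, f_hi = resid(lo), resid(hi)
        if f_lo * f_hi > 0:
            raise RuntimeError(
                "leaf energy balance: no sign change in bracket "
                f"[{lo}, {hi}] (resid {f_lo:.3g}, {f_hi:.3g}); "
                f"tair={tair}, rn={rn_abs}, gs={gs}, rh={rh}"
            )
        for _ in range(25):
            mid = 0.5 * (lo + hi)
            fm = resid(mid)
            if f_lo * fm <= 0:
                hi = mid
            else:
                lo, f_lo = mid, fm
            if hi - lo < 1e-3:
                break
        tl = newton(0.5 * (lo + hi))
        if tl is None:
            raise RuntimeError("leaf energy balance: Newton polish failed")
    e_mol = g_tv * (_esat(tl) - ea) / P_ATM
    return tl, max(e_mol, 0.0) * 1000.0


def solve_ci(
    gs: float, t_leaf: float, ppfd: float, p: GasExchangeParams, vcmax25: float
) -> tuple[float, float, str]:
    """Ci and An consistent with both biochemistry and CO2 diffusion.

    The diffusion constraint An = g_c (ca - Ci), with total CO2 conductance
    g_c = 1/(1.6/gs + 1.37/gb), combined with each FvCB branch
    An = a (Ci - G*) / (Ci + k) - Rd gives a quadratic in Ci per branch:

        g_c Ci^2 + (g_c (k - ca) + a - Rd) Ci - (g_c ca k + a G* + Rd k) = 0

    whose positive root is exact; the operative branch is the one with the
    smaller An. Under net respiration (An < 0) Ci exceeds ca, as CO2 then
    diffuses outward. Returns (ci, an, limitation).
    """
    gc = 1.0 / (1.6 / gs + 1.37 / p.gb)
    vcmax = arrhenius(vcmax25, p.ea_vcmax, t_leaf)
    jmax = arrhenius(vcmax25 * p.jmax_ratio, p.ea_jmax, t_leaf)
    rd = arrhenius(vcmax25 * p.rd_frac, p.ea_rd, t_leaf)
    kc = arrhenius(p.kc25, p.ea_kc, t_leaf)
    ko = arrhenius(p.ko25, p.ea_ko, t_leaf)
    gstar = arrhenius(p.gamma_star25, p.ea_gamma_star, t_leaf)
    km = kc * (1.0 + p.o2 / ko)
    j = electron_transport(ppfd, jmax, p.theta_j, p.phi_j)

    def branch(a_cap: float, k_eff: float) -> tuple[float, float]:
        b = gc * (k_eff - p.ca) + a_cap - rd
        c = gc * p.ca * k_eff + a_cap * gstar + rd * k_eff
        ci = (-b + math.sqrt(b * b + 4.0 * gc * c)) / (2.0 * gc)
        return ci, gc * (p.ca - ci)

    ci_c, an_c = branch(vcmax, km)
    ci_j, an_j = branch(j / 4.0, 2.0 * gstar)
    if an_c <= an_j:
        return ci_c, an_c, "rubisco"
    return ci_j, an_j, "rubp"


def solve_leaf(
    tair: float,
    rh: float,
    ppfd: float,
    rn_abs: float,
    aba: float,
    psi_leaf: float,
    p: GasExchangeParams,
    na: float,
) -> LeafState:
    """Consistent {Ci, gs, An, E, T_leaf} for one leaf, one hour.

    Given the ABA signal and leaf water potential, the state is fully
    determined: TD conductance is explicit, the energy balance fixes
    T_leaf and E at that gs, and the diffusion/FvCB quadratic fixes Ci and
    An at that T_leaf. The diffusion residual |An - g_c (ca - Ci)| is zero
    to rounding by construction.
    """
    vcmax25 = vcmax25_from_nitrogen(na, p.slope_vcmax)
    gs = td_stomatal_conductance(aba, psi_leaf, ppfd, p)
    t_leaf, e = leaf_energy_balance(tair, rn_abs, gs, p.gb, rh)
    ci, an, lim = solve_ci(gs, t_leaf, ppfd, p, vcmax25)
    return LeafState(ci=ci, gs=gs, an=an, e=e, t_leaf=t_leaf, psi_leaf=psi_leaf, limitation=lim)
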