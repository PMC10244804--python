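"""Static post-veraison canopy and within-canopy light distribution.

The vineyard canopy is represented as isolated single-shoot plants. Leaf
geometry constants (shoot spacing, azimuth step) are carried as config
metadata; light interception uses Beer-Lambert attenuation over the
cumulative leaf area index above each leaf, the package's principal
structural simplification of a full 3-D ray-traced canopy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .environment import DEFAULT_C_PAR

__all__ = ["CanopyConfig", "Leaf", "Canopy", "build_canopy", "leaf_light", "leaf_net_radiation"]


@dataclass(frozen=True)
class CanopyConfig:
    """Canopy structure and leaf-nitrogen configuration.

    ``leafN_content`` (g N m-2) is one of the calibrated quantities: it sets
    the leaf maximum carboxylation rate through the nitrogen-Vcmax slope.
    ``area_profile`` gives relative leaf area by node rank from the shoot top
    (normalized internally); ``k_ext`` is the Beer-Lambert extinction
    coefficient. ``shoot_spacing``/``azimuth_step`` record the field geometry
    but do not enter the attenuation model.
    """

    shoots_per_plant: int = 1
    leaf_area_per_shoot: float = 0.25
    leaves_per_shoot: int = 10
    shoot_spacing: float = 0.15
    row_spacing: float = 1.4
    azimuth_step: float = 135.0
    sla: float = 0.012
    leafN_content: float = 1.7
    k_ext: float = 0.7
    alpha_leaf: float = 0.85
    area_profile: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if not self.leaf_area_per_shoot > 0:
            raise ValueError("leaf_area_per_shoot must be > 0")
        if self.leaves_per_shoot < 1:
            raise ValueError("leaves_per_shoot must be >= 1")
        if self.k_ext < 0:
            raise ValueError("k_ext must be >= 0")
        if self.leafN_content < 0:
            raise ValueError("leafN_content must be >= 0")

    @property
    def ground_area_per_shoot(self) -> float:
        """Ground area allotted to one single-shoot plant (m2)."""
        return self.shoot_spacing * self.row_spacing


@dataclass(frozen=True)
class Leaf:
    """One discretized leaf: rank from shoot top, area, N per area, LAI above."""

    rank: int
    area: float
    na: float
    lai_above: float


@dataclass(frozen=True)
class Canopy:
    """Ordered leaf list for one single-shoot plant plus config metadata."""

    leaves: tuple[Leaf, ...]
    config: CanopyConfig

    @property
    def total_leaf_area(self) -> float:
        return sum(l.area for l in self.leaves)

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "rank": [l.rank for l in self.leaves],
                "area_m2": [l.area for l in self.leaves],
                "na_g_m2": [l.na for l in self.leaves],
                "lai_above": [l.lai_above for l in self.leaves],
            }
        )


def build_canopy(cfg: CanopyConfig) -> Canopy:
    """Build the ordered leaf list for one shoot.

    Leaf areas follow ``area_profile`` (uniform by default) normalized to sum
    to ``leaf_area_per_shoot``; nitrogen is distributed uniformly at
    ``leafN_content``. ``lai_above`` accumulates leaf area per ground area
    from the shoot top downward.
    """
    nl = cfg.leaves_per_shoot
    if cfg.area_profile is None:
        weights = np.full(nl, 1.0 / nl)
    else:
        w = np.asarray(cfg.area_profile, dtype=float)
        if len(w) != nl:
            raise ValueError(
                f"area_profile length {len(w)} != leaves_per_shoot {nl}"
            )
        tot = w.sum()
        if not np.isfinite(tot) or tot <= 0 or (w < 0).any():
            raise ValueError("area_profile must be nonnegative with positive sum")
        weights = w / tot
    areas = weights * cfg.leaf_area_per_shoot
    ground = cfg.ground_area_per_shoot
    leaves = []
    cum = 0.0
    for rank, area in enumerate(areas):
        leaves.append(Leaf(rank=rank, area=float(area), na=cfg.leafN_content, lai_above=cum / ground))
        cum += area
    return Canopy(tuple(leaves), cfg)


def leaf_light(canopy: Canopy, ppfd0: float) -> np.ndarray:
    """Per-leaf absorbed PPFD (umol m-2 s-1) by Beer-Lambert attenuation.

    PPFD_i = ppfd0 * exp(-k_ext * lai_above_i); the top leaf receives the
    incident flux and deeper leaves never receive more than shallower ones.
    """
    if ppfd0 < 0:
        raise ValueError("ppfd0 must be >= 0")
    k = canopy.config.k_ext
    lai = np.array([l.lai_above for l in canopy.leaves])
    return ppfd0 * np.exp(-k * lai)


def leaf_net_radiation(
    ppfd_abs: float,
    tair: float,
    rad: float,
    c_par: float = DEFAULT_C_PAR,
    alpha_leaf: float = 0.85,
    lw_iso: float = 0.0,
) -> float:
    """Absorbed net (isothermal) radiation per leaf, W m-2.

    Shortwave component is the absorbed PPFD converted back to energy units
    times the leaf absorptance; the isothermal longwave term (``lw_iso``,
    linearized around air temperature) defaults to zero for leaves embedded
    in a closed canopy. The temperature-dependent longwave feedback is
    handled as a radiative conductance inside the leaf energy balance.
    """
    if ppfd_abs < 0 or rad < 0:
        raise ValueError("radiation inputs must be nonnegative")
    return ppfd_abs / c_par * alpha_leaf + lw_iso
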