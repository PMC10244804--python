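"""Environmental drivers and soil water status.

Atmospheric helpers (saturation vapor pressure, VPD, PAR conversion, growing
degree days), the van Genuchten unsaturated soil hydraulic conductivity
function, the composite soil-to-root resistance, and the sparse predawn
water-potential series that stands in for soil water potential.

Package-wide unit system: water potentials in MPa, whole-plant water fluxes
in mg s-1, hourly time step. Soil conductivity is carried in relative units
(saturated value ``ks``); the root specific conductance RSC absorbs the
conversion so that Rsp = RSC / k(psi_soil) is in MPa s mg-1 per plant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SoilParams",
    "PredawnSeries",
    "HourlyWeather",
    "saturation_vapor_pressure",
    "vpd",
    "rad_to_ppfd",
    "soil_conductivity",
    "soil_root_resistance",
    "interpolate_predawn",
    "gdd",
    "read_weather_csv",
    "read_predawn_csv",
    "HydraulicDisconnectionError",
]

#: default PAR conversion, umol photons per J of global shortwave
DEFAULT_C_PAR = 2.1
#: default GDD base temperature (viticulture convention), degC
DEFAULT_GDD_BASE = 10.0
#: relative conductivity floor (fraction of ks) before declaring disconnection
CONDUCTIVITY_FLOOR_FRAC = 1e-12

WEATHER_COLUMNS = ["timestamp", "tair_c", "rh_pct", "rad_wm2", "wind_ms"]
PREDAWN_COLUMNS = ["date", "psi_predawn_mpa"]


class HydraulicDisconnectionError(RuntimeError):
    """Soil conductivity fell below the configured floor."""


@dataclass(frozen=True)
class SoilParams:
    """van Genuchten soil coefficients plus the root specific conductance.

    ``ks`` is the saturated hydraulic conductivity (relative units),
    ``alpha_v`` (MPa-1) and ``n`` (>1, dimensionless) shape the retention
    curve, ``p`` is the pore-connectivity exponent, and ``rsc`` is the
    composite root specific conductance such that Rsp = rsc / k(psi_soil).
    The root geometry terms (root spacing, radius, length density) of the
    underlying Gardner formulation are deliberately absorbed into ``rsc``.
    """

    ks: float = 1.0
    alpha_v: float = 1.0
    n: float = 1.5
    p: float = 0.5
    rsc: float = 0.004

    def __post_init__(self) -> None:
        if not self.ks > 0:
            raise ValueError(f"ks must be > 0, got {self.ks}")
        if not self.n > 1:
            raise ValueError(f"van Genuchten n must be > 1, got {self.n}")
        if not self.alpha_v > 0:
            raise ValueError(f"alpha_v must be > 0, got {self.alpha_v}")
        if self.rsc < 0:
            raise ValueError(f"rsc must be >= 0, got {self.rsc}")


@dataclass(frozen=True)
class PredawnSeries:
    """Sparse predawn leaf water potential series, proxy for soil potential.

    ``dates`` are calendar timestamps (strictly increasing), ``psi_predawn``
    in MPa (all <= 0). Linear interpolation between measurement dates, no
    extrapolation.
    """

    dates: pd.DatetimeIndex
    psi_predawn: np.ndarray

    def __post_init__(self) -> None:
        dates = pd.DatetimeIndex(self.dates)
        psi = np.asarray(self.psi_predawn, dtype=float)
        object.__setattr__(self, "dates", dates)
        object.__setattr__(self, "psi_predawn", psi)
        if len(dates) != len(psi):
            raise ValueError("dates and psi_predawn lengths differ")
        if len(dates) < 2:
            raise ValueError("predawn series needs at least 2 entries")
        if not dates.is_monotonic_increasing or dates.has_duplicates:
            raise ValueError("predawn dates must be strictly increasing")
        if np.any(psi > 0):
            raise ValueError("predawn water potential must be <= 0 MPa")


@dataclass(frozen=True)
class HourlyWeather:
    """Gap-free hourly weather forcing.

    Wraps a DataFrame indexed by hourly timestamps with columns
    ``tair`` (degC), ``rh`` (%), ``rad`` (W m-2), ``wind`` (m s-1).
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.frame
        required = {"tair", "rh", "rad", "wind"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"weather frame missing columns: {sorted(missing)}")
        if not isinstance(df.index, pd.DatetimeIndex):
            raise ValueError("weather frame must be indexed by timestamps")
        if len(df) > 1:
            deltas = np.unique(np.diff(df.index.view("i8")))
            if len(deltas) != 1 or deltas[0] != 3_600_000_000_000:
                raise ValueError("weather must be hourly and gap-free")
        if ((df["rh"] < 0) | (df["rh"] > 100)).any():
            raise ValueError("rh outside [0, 100]")
        if (df["rad"] < 0).any():
            raise ValueError("negative radiation")
        if (df["wind"] < 0).any():
            raise ValueError("negative wind speed")

    @property
    def index(self) -> pd.DatetimeIndex:
        return self.frame.index

    def covers(self, start: pd.Timestamp, end: pd.Timestamp) -> bool:
        return self.index[0] <= start and self.index[-1] >= end


# ---------------------------------------------------------------------------
# atmospheric helpers


def saturation_vapor_pressure(tair: float) -> float:
    """Saturation vapor pressure (kPa), Tetens form, tair in degC."""
    if not -20.0 <= tair <= 60.0:
        raise ValueError(f"air temperature {tair} degC outside [-20, 60]")
    return 0.6108 * math.exp(17.27 * tair / (tair + 237.3))


def vpd(tair: float, rh: float) -> float:
    """Vapor pressure deficit (kPa) from air temperature (degC) and RH (%)."""
    if not 0.0 <= rh <= 100.0:
        raise ValueError(f"relative humidity {rh}% outside [0, 100]")
    return saturation_vapor_pressure(tair) * (1.0 - rh / 100.0)


def rad_to_ppfd(rad: float, c_par: float = DEFAULT_C_PAR) -> float:
    """Global shortwave (W m-2) to PPFD (umol m-2 s-1), linear conversion."""
    if rad < 0:
        raise ValueError(f"negative radiation: {rad}")
    return rad * c_par


# ---------------------------------------------------------------------------
# soil hydraulics


def soil_conductivity(psi_soil: float, sp: SoilParams) -> float:
    """Unsaturated soil hydraulic conductivity k(psi_soil).

    van Genuchten-Mualem form with suction h = |psi_soil|:

        S = 1 / (1 + (alpha_v * h)^n)
        k = ks * S^(p - p/n) * (1 - (1 - S)^(1 - 1/n))^2

    k(0) = ks and k decreases strictly with suction.
    """
    if psi_soil > 0:
        raise ValueError(f"psi_soil must be <= 0 MPa, got {psi_soil}")
    h = -psi_soil
    if h == 0.0:
        return sp.ks
    s = 1.0 / (1.0 + (sp.alpha_v * h) ** sp.n)
    return sp.ks * s ** (sp.p - sp.p / sp.n) * (1.0 - (1.0 - s) ** (1.0 - 1.0 / sp.n)) ** 2


def soil_root_resistance(sp: SoilParams, psi_soil: float) -> float:
    """Soil-to-root resistance Rsp = RSC / k(psi_soil), MPa s mg-1 plant-1.

    Raises :class:`HydraulicDisconnectionError` once conductivity falls below
    the configured floor (fraction of ks).
    """
    if sp.rsc == 0.0:
        return 0.0
    k = soil_conductivity(psi_soil, sp)
    if k < CONDUCTIVITY_FLOOR_FRAC * sp.ks:
        raise HydraulicDisconnectionError(
            f"soil conductivity {k:.3e} below floor at psi_soil={psi_soil} MPa"
        )
    return sp.rsc / k


def interpolate_predawn(series: PredawnSeries, t: pd.Timestamp) -> float:
    """Linearly interpolated predawn potential at time ``t`` (MPa).

    Exact at measurement dates; no extrapolation outside the measured span.
    """
    t = pd.Timestamp(t)
    t0, t1 = series.dates[0], series.dates[-1]
    if t < t0 or t > t1:
        raise ValueError(
            f"time {t} outside predawn measurement span [{t0}, {t1}]; "
            "extrapolation is not supported"
        )
    x = series.dates.view("i8").astype(float)
    return float(np.interp(pd.Timestamp(t).value, x, series.psi_predawn))


def gdd(
    weather: HourlyWeather,
    window: tuple[pd.Timestamp, pd.Timestamp],
    tbase: float = DEFAULT_GDD_BASE,
) -> float:
    """Growing degree days over a calendar-day window (degC days).

    Daily mean is (Tmax + Tmin)/2 from the hourly series; days accumulate
    max(0, mean - tbase). The window is inclusive of both end days.
    """
    start, end = pd.Timestamp(window[0]).normalize(), pd.Timestamp(window[1]).normalize()
    if end < start:
        raise ValueError("empty GDD window")
    df = weather.frame
    sel = df.loc[(df.index >= start) & (df.index < end + pd.Timedelta(days=1)), "tair"]
    if sel.empty:
        raise ValueError("GDD window not covered by weather")
    daily = sel.groupby(sel.index.normalize())
    ndays = (end - start).days + 1
    if len(daily) != ndays:
        raise ValueError("GDD window not fully covered by weather")
    tmean = (daily.max() + daily.min()) / 2.0
    return float(np.maximum(0.0, tmean - tbase).sum())


# ---------------------------------------------------------------------------
# strict CSV readers (schemas fixed by the external-interface contract)


def _check_columns(df: pd.DataFrame, expected: list[str], path: str) -> None:
    if list(df.columns) != expected:
        raise ValueError(
            f"{path}: expected columns {expected}, found {list(df.columns)}"
        )


def read_weather_csv(path: str) -> HourlyWeather:
    """Read an hourly weather CSV: timestamp,tair_c,rh_pct,rad_wm2,wind_ms."""
    df = pd.read_csv(path, comment="#")
    _check_columns(df, WEATHER_COLUMNS, str(path))
    try:
        ts = pd.to_datetime(df["timestamp"], format="ISO8601")
    except (ValueError, TypeError) as exc:
        raise ValueError(f"{path}: unparseable timestamp ({exc})") from exc
    for i, col in enumerate(WEATHER_COLUMNS[1:], start=1):
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        if bad.any():
            line = int(np.flatnonzero(bad)[0]) + 2
            raise ValueError(f"{path}:{line}: non-numeric value in column {col}")
    frame = pd.DataFrame(
        {
            "tair": df["tair_c"].astype(float).values,
            "rh": df["rh_pct"].astype(float).values,
            "rad": df["rad_wm2"].astype(float).values,
            "wind": df["wind_ms"].astype(float).values,
        },
        index=pd.DatetimeIndex(ts),
    )
    return HourlyWeather(frame)


def read_predawn_csv(path: str) -> PredawnSeries:
    """Read a predawn series CSV: date,psi_predawn_mpa."""
    df = pd.read_csv(path, comment="#")
    _check_columns(df, PREDAWN_COLUMNS, str(path))
    try:
        dates = pd.to_datetime(df["date"], format="ISO8601")
    except (ValueError, TypeError) as exc:
        raise ValueError(f"{path}: unparseable date ({exc})") from exc
    psi = pd.to_numeric(df["psi_predawn_mpa"], errors="coerce")
    if psi.isna().any():
        line = int(np.flatnonzero(psi.isna())[0]) + 2
        raise ValueError(f"{path}:{line}: non-numeric psi_predawn_mpa")
    return PredawnSeries(pd.DatetimeIndex(dates), psi.values.astype(float))
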