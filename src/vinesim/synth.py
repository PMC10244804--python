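"""Synthetic Bordeaux-like vintages and observation sets.

Generates hourly weather with a hotter-earlier seasonal template (late
summer into autumn: temperature and clear-sky radiation decline with day of
year), seasonal predawn water-potential dry-downs sampled biweekly, weekly
berry observation schedules, a leaf gas-exchange response dataset standing
in for a field meta-analysis, and twin-experiment observation sets for
calibration tests. There is no rainfall process: soil water status is
imposed entirely through the predawn series, exactly as the simulator
consumes it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .berry import initial_berry_state
from .canopy import build_canopy
from .environment import HourlyWeather, PredawnSeries
from .plant import PlantParams, SeasonInputs, simulate_season, solve_hour

__all__ = [
    "DrydownSpec",
    "VintageSpec",
    "generate_weather",
    "generate_predawn",
    "make_season_inputs",
    "make_vintage_cohort",
    "make_twin_dataset",
    "generate_gx_meta",
]

PREDAWN_NOISE_SD = 0.02  # MPa
PREDAWN_ENVELOPE = (-1.03, -0.01)  # field-observed predawn range
WEATHER_LEAD_DAYS = 35  # forcing generated this many days before veraison
DRYDOWN_LEAD_DAYS = 60  # dry-down anchored at full bloom
SEASONAL_T_SLOPE = -0.07  # degC per day: hotter-earlier template
SEASONAL_RAD_SLOPE = -0.8  # W m-2 per day decline of clear-sky peak
CLEAR_SKY_PEAK = 820.0  # W m-2 at veraison


@dataclass(frozen=True)
class DrydownSpec:
    """Seasonal predawn dry-down from psi_start toward psi_end (MPa, <= 0).

    The potential declines from early summer, reaches its trough at
    ``trough_frac`` of the bloom-to-harvest span, then partially recovers
    (autumn rains rewet the profile before harvest) by ``rewet`` of the
    total depth. ``psi_end`` is the trough value.
    """

    psi_start: float = -0.08
    psi_end: float = -0.80
    shape: str = "exponential"  # or "linear"
    trough_frac: float = 0.50
    rewet: float = 0.65

    def __post_init__(self) -> None:
        if self.psi_start > 0 or self.psi_end > 0:
            raise ValueError("drydown potentials must be <= 0")
        if self.psi_start < self.psi_end:
            raise ValueError("psi_start must be >= psi_end (drying)")
        if self.shape not in ("linear", "exponential"):
            raise ValueError(f"unknown drydown shape {self.shape!r}")
        if not 0.0 < self.trough_frac <= 1.0:
            raise ValueError("trough_frac must lie in (0, 1]")
        if not 0.0 <= self.rewet < 1.0:
            raise ValueError("rewet must lie in [0, 1)")

    def value_at(self, frac: float) -> float:
        """Dry-down value at progress ``frac`` in [0, 1]."""
        f = min(max(frac, 0.0), 1.0)
        g = min(f / self.trough_frac, 1.0)
        if self.shape == "linear":
            psi = self.psi_start + (self.psi_end - self.psi_start) * g
        else:
            # exponential: most of the decline early in the season
            psi = self.psi_end + (self.psi_start - self.psi_end) * math.exp(-3.0 * g)
        if f > self.trough_frac:
            depth = self.psi_start - psi  # magnitude of the drop so far (> 0)
            recovery = (f - self.trough_frac) / (1.0 - self.trough_frac)
            psi = psi + self.rewet * depth * recovery
        return psi


@dataclass(frozen=True)
class VintageSpec:
    """One synthetic vintage: phenology, climate statistics, dry-down, seed."""

    year: int = 2004
    veraison_doy: int = 218
    harvest_doy: int = 278
    t_mean_season: float = 21.0
    t_amplitude_diurnal: float = 10.0
    cloudiness: float = 0.35
    drydown: DrydownSpec = field(default_factory=DrydownSpec)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.harvest_doy <= self.veraison_doy:
            raise ValueError("harvest must follow veraison")
        if not 0.0 <= self.cloudiness <= 1.0:
            raise ValueError("cloudiness must lie in [0, 1]")

    @property
    def veraison(self) -> pd.Timestamp:
        return pd.Timestamp(f"{self.year}-01-01") + pd.Timedelta(days=self.veraison_doy - 1)

    @property
    def harvest(self) -> pd.Timestamp:
        return pd.Timestamp(f"{self.year}-01-01") + pd.Timedelta(days=self.harvest_doy - 1)


def _diurnal_shape(hour: int) -> float:
    """Diurnal temperature shape in [-1, 1]: minimum 05:00, maximum 15:00."""
    if 5 <= hour <= 15:
        return -math.cos(math.pi * (hour - 5) / 10.0)
    h = hour if hour > 15 else hour + 24
    return math.cos(math.pi * (h - 15) / 14.0)


def generate_weather(spec: VintageSpec) -> HourlyWeather:
    """Deterministic-per-seed hourly weather for one vintage.

    Covers veraison minus the lead window (for advanced-veraison scenarios)
    through the day after harvest. Daily means follow the hotter-earlier
    seasonal template plus an AR(1) anomaly; radiation is a clear-sky
    half-sine (06:00-20:00) scaled by daily cloudiness; relative humidity is
    anti-correlated with temperature and clipped to [20, 100]; wind is
    log-normal.
    """
    rng = np.random.default_rng(spec.seed)
    start = spec.veraison - pd.Timedelta(days=WEATHER_LEAD_DAYS)
    end = spec.harvest + pd.Timedelta(days=1, hours=23)
    index = pd.date_range(start, end, freq="h")
    days = pd.date_range(start.normalize(), end.normalize(), freq="D")
    anom = 0.0
    tmean_day, cloud_day = {}, {}
    for d in days:
        anom = 0.7 * anom + rng.normal(0.0, 1.2)
        offset = (d - spec.veraison.normalize()).days
        tmean_day[d] = spec.t_mean_season + SEASONAL_T_SLOPE * offset + anom
        cloud_day[d] = float(np.clip(spec.cloudiness + 0.25 * rng.normal(), 0.0, 0.95))
    tair = np.empty(len(index))
    rad = np.empty(len(index))
    rh = np.empty(len(index))
    rh_noise = rng.normal(0.0, 2.0, size=len(index))
    wind = rng.lognormal(mean=0.5, sigma=0.35, size=len(index))
    for k, ts in enumerate(index):
        d = ts.normalize()
        tm = tmean_day[d]
        offset = (d - spec.veraison.normalize()).days
        t = tm + 0.5 * spec.t_amplitude_diurnal * _diurnal_shape(ts.hour)
        tair[k] = t
        peak = max(
            (CLEAR_SKY_PEAK + SEASONAL_RAD_SLOPE * offset) * (1.0 - 0.75 * cloud_day[d]),
            50.0,
        )
        h = ts.hour
        rad[k] = peak * math.sin(math.pi * (h - 6) / 14.0) if 6 <= h <= 20 else 0.0
        rh[k] = float(np.clip(78.0 - 3.2 * (t - tm) + rh_noise[k], 20.0, 100.0))
    frame = pd.DataFrame(
        {"tair": tair, "rh": rh, "rad": np.maximum(rad, 0.0), "wind": wind}, index=index
    )
    return HourlyWeather(frame)


def generate_predawn(spec: VintageSpec) -> PredawnSeries:
    """Biweekly predawn series following the vintage dry-down.

    Dates run from 30 days before veraison past harvest (so that hourly
    interpolation covers the full simulation window and the advanced
    scenarios). Gaussian measurement noise (0.02 MPa) is added and values
    are clipped to the field-observed envelope.
    """
    rng = np.random.default_rng(spec.seed + 7919)
    t0 = spec.veraison - pd.Timedelta(days=30)
    # the dry-down itself is anchored at full bloom (~60 days before
    # veraison): by the first sampled date it is already partly advanced,
    # as in a rainfed season where soil moisture declines from early summer
    t0_dd = spec.veraison - pd.Timedelta(days=DRYDOWN_LEAD_DAYS)
    dates = [t0]
    while dates[-1] < spec.harvest + pd.Timedelta(days=1):
        dates.append(dates[-1] + pd.Timedelta(days=14))
    span = (spec.harvest - t0_dd).days
    values = []
    for d in dates:
        frac = (d - t0_dd).days / span
        psi = spec.drydown.value_at(frac) + rng.normal(0.0, PREDAWN_NOISE_SD)
        values.append(float(np.clip(psi, PREDAWN_ENVELOPE[0], PREDAWN_ENVELOPE[1])))
    return PredawnSeries(pd.DatetimeIndex(dates), np.array(values))


def make_season_inputs(
    spec: VintageSpec,
    berry_fw: float = 0.70,
    berry_dw: float = 0.14,
    berry_sugar_gl: float = 80.0,
) -> SeasonInputs:
    """Bundle weather, predawn series, phenology and the veraison berry state."""
    return SeasonInputs(
        weather=generate_weather(spec),
        predawn=generate_predawn(spec),
        veraison=spec.veraison,
        harvest=spec.harvest,
        berry_init=initial_berry_state(berry_fw, berry_dw, berry_sugar_gl),
        label=str(spec.year),
    )


def make_vintage_cohort(
    n: int = 13, base_seed: int = 42, first_year: int = 2004
) -> list[VintageSpec]:
    """A cohort of synthetic vintages with varied climate and dry-down.

    Mirrors the structure of a 13-year field campaign: one deliberately wet
    and one deliberately dry vintage, the rest drawn from documented ranges.
    Reproducible per ``base_seed``.
    """
    if n < 1:
        raise ValueError("cohort size must be >= 1")
    rng = np.random.default_rng(base_seed)
    specs = []
    for i in range(n):
        if i == 0:
            psi_end = -0.28
        elif i == 1:
            psi_end = -0.92
        else:
            psi_end = float(rng.uniform(-1.0, -0.35))
        veraison_doy = int(212 + rng.integers(0, 11))
        duration = int(55 + rng.integers(0, 11))
        specs.append(
            VintageSpec(
                year=first_year + i,
                veraison_doy=veraison_doy,
                harvest_doy=veraison_doy + duration,
                t_mean_season=float(rng.uniform(19.5, 23.5)),
                t_amplitude_diurnal=float(rng.uniform(8.0, 12.0)),
                cloudiness=float(rng.uniform(0.20, 0.55)),
                drydown=DrydownSpec(
                    psi_start=float(rng.uniform(-0.12, -0.05)),
                    psi_end=psi_end,
                    shape="exponential",
                ),
                seed=int(base_seed + 1000 + i),
            )
        )
    return specs


def make_twin_dataset(
    inputs: SeasonInputs,
    true_params: PlantParams,
    noise_sd: dict[str, float],
    seed: int = 0,
    psi_interval_days: int = 14,
    berry_interval_days: int = 7,
    traj=None,
) -> tuple[pd.DataFrame, "object"]:
    """Twin-experiment observations from a known-truth simulation.

    Samples the truth trajectory on the field protocol's schedule (biweekly
    15:00 xylem potential; weekly end-of-day berry FW/DW/[Sugar]) and adds
    Gaussian noise per stream (keys ``psi_xylem_midday``, ``berry_fw_g``,
    ``berry_dw_g``, ``sugar_g_per_l``; an absent key means noise-free).
    Returns (tidy observation table, truth trajectory). A precomputed truth
    trajectory may be passed to draw fresh noise replicates cheaply.
    """
    if traj is None:
        traj = simulate_season(inputs, true_params)
    rng = np.random.default_rng(seed)
    df = traj.hourly
    rows = []
    day0, day_last = inputs.veraison, inputs.harvest
    d = day0 + pd.Timedelta(days=3)
    while d <= day_last:
        ts = d + pd.Timedelta(hours=15)
        val = float(df.loc[ts, "psi_xylem"]) + rng.normal(0.0, noise_sd.get("psi_xylem_midday", 0.0))
        rows.append({"date": d, "variable": "psi_xylem_midday", "value": val})
        d += pd.Timedelta(days=psi_interval_days)
    d = day0 + pd.Timedelta(days=2)
    while d <= day_last:
        ts = d + pd.Timedelta(hours=23)
        for var, col in (
            ("berry_fw_g", "berry_fw"),
            ("berry_dw_g", "berry_dw"),
            ("sugar_g_per_l", "berry_sugar_conc"),
        ):
            val = float(df.loc[ts, col]) + rng.normal(0.0, noise_sd.get(var, 0.0))
            rows.append({"date": d, "variable": var, "value": val})
        d += pd.Timedelta(days=berry_interval_days)
    return pd.DataFrame(rows), traj


def generate_gx_meta(
    params: PlantParams, seed: int = 0, n_points: int = 40
) -> pd.DataFrame:
    """Leaf gas-exchange response dataset emulating a field meta-analysis.

    Runs the whole-plant midday solution over a span of soil water
    potentials covering the field-observed predawn envelope, with jittered
    midday weather and multiplicative observation noise on gs and Pn.
    Columns: psi_predawn, psi_leaf_midday, gs, pn, tair, rh, rad.
    """
    if n_points < 20:
        raise ValueError("n_points must be >= 20")
    rng = np.random.default_rng(seed)
    canopy = build_canopy(params.canopy)
    lo, hi = PREDAWN_ENVELOPE
    psis = np.linspace(hi, lo, n_points)
    rows = []
    for psi in psis:
        tair = 26.0 + rng.uniform(-4.0, 6.0)
        rh = rng.uniform(35.0, 65.0)
        rad = rng.uniform(600.0, 880.0)
        hs = solve_hour(canopy, tair, rh, rad, float(psi), params)
        top = hs.leaf_states[0]
        rows.append(
            {
                "psi_predawn": float(psi),
                "psi_leaf_midday": top.psi_leaf,
                "gs": top.gs * (1.0 + rng.normal(0.0, 0.08)),
                "pn": top.an * (1.0 + rng.normal(0.0, 0.08)),
                "tair": tair,
                "rh": rh,
                "rad": rad,
            }
        )
    return pd.DataFrame(rows)
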