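"""Shared fixtures: default parameters, small canopies, and one short
synthetic season reused by the season-scale tests."""

import numpy as np
import pandas as pd
import pytest

import vinesim as vs
from vinesim.canopy import build_canopy
from vinesim.synth import DrydownSpec, VintageSpec, make_season_inputs


@pytest.fixture(scope="session")
def default_params() -> vs.PlantParams:
    return vs.PlantParams()


@pytest.fixture(scope="session")
def default_canopy(default_params):
    return build_canopy(default_params.canopy)


@pytest.fixture(scope="session")
def short_vintage_inputs():
    """A 30-day synthetic season with a marked dry-down."""
    spec = VintageSpec(
        year=2010,
        seed=11,
        veraison_doy=220,
        harvest_doy=250,
        drydown=DrydownSpec(psi_start=-0.06, psi_end=-0.85),
    )
    return make_season_inputs(spec)


@pytest.fixture(scope="session")
def short_trajectory(short_vintage_inputs, default_params):
    """Full simulation of the 30-day season (shared across tests)."""
    return vs.simulate_season(short_vintage_inputs, default_params)


def constant_weather_inputs(
    tair=24.0, rh=60.0, rad_peak=700.0, psi=-0.4, days=4, year=2010
):
    """Season inputs with an identical diurnal cycle every day and constant
    soil water potential (used for steady-state checks)."""
    start = pd.Timestamp(f"{year}-08-01") - pd.Timedelta(days=2)
    end = pd.Timestamp(f"{year}-08-01") + pd.Timedelta(days=days + 1, hours=23)
    index = pd.date_range(start, end, freq="h")
    rad = np.array(
        [
            rad_peak * np.sin(np.pi * (h - 6) / 14.0) if 6 <= h <= 20 else 0.0
            for h in index.hour
        ]
    )
    frame = pd.DataFrame(
        {"tair": tair, "rh": rh, "rad": np.maximum(rad, 0.0), "wind": 1.5}, index=index
    )
    weather = vs.HourlyWeather(frame)
    predawn = vs.PredawnSeries(
        pd.DatetimeIndex([index[0].normalize(), index[-1].normalize()]),
        np.array([psi, psi]),
    )
    return vs.SeasonInputs(
        weather=weather,
        predawn=predawn,
        veraison=pd.Timestamp(f"{year}-08-01"),
        harvest=pd.Timestamp(f"{year}-08-01") + pd.Timedelta(days=days - 1),
        berry_init=vs.initial_berry_state(0.70, 0.14, 80.0),
        label="constant",
    )
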