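"""Shared fixtures: small analytic grids, fields and simulated bundles."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from turtlenav.bathymetry import BathymetryGrid
from turtlenav.currents import CurrentField
from turtlenav.simulate import SimConfig, generate_bathymetry, generate_current_field


@pytest.fixture(scope="session")
def bathy():
    """Default synthetic bathymetry: island + one large bank in a 3000 m basin."""
    return generate_bathymetry()


@pytest.fixture(scope="session")
def current_field(bathy):
    """Default synthetic current field (0.29 m/s toward 227.8 deg, smooth noise)."""
    return generate_current_field(seed=7, bathy=bathy)


@pytest.fixture(scope="session")
def uniform_field():
    """Small uniform current field u=0.2, v=-0.2 over the study domain."""
    time = np.datetime64("2019-01-01", "ns") + np.arange(8) * np.timedelta64(6, "h")
    lat = np.linspace(-8.5, -4.5, 21)
    lon = np.linspace(70.0, 74.0, 21)
    shape = (8, 21, 21)
    return CurrentField(time, lat, lon, np.full(shape, 0.2), np.full(shape, -0.2))


@pytest.fixture(scope="session")
def flat_deep_grid():
    """Featureless 1000 m-deep bathymetry."""
    lat = np.linspace(-9.0, -4.0, 26)
    lon = np.linspace(69.0, 75.0, 31)
    return BathymetryGrid(lat, lon, np.full((26, 31), 1000.0))


@pytest.fixture(scope="session")
def ramp_grid():
    """Depth increasing linearly northward: depth = 100 + 500*(lat + 8)."""
    lat = np.linspace(-8.0, -5.0, 61)
    lon = np.linspace(70.0, 74.0, 41)
    depth = 100.0 + 500.0 * (lat[:, None] + 8.0) + 0.0 * lon[None, :]
    return BathymetryGrid(lat, lon, depth)


@pytest.fixture(scope="session")
def sim_bundle(bathy):
    """Five simulated turtles with observations, shared environment."""
    from turtlenav.simulate import simulate_bundle

    return simulate_bundle(5, seed=202, bathy=bathy)


def make_track(times, lats, lons, turtle_id="t1", sats=8, resid=1.0) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "turtle_id": turtle_id,
            "time": pd.to_datetime(times),
            "lat": lats,
            "lon": lons,
            "n_satellites": sats,
            "residual_error": resid,
        }
    )
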