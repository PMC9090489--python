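"""Solar position and nautical dawn.

Implements the NOAA solar-calculator equations (Meeus-derived): fractional-year
expansion of the equation of time and solar declination, then elevation from
the local hour angle. Accuracy is a few hundredths of a degree in elevation,
which resolves twilight crossing times to well under a minute — ample for
timing island departures relative to nautical dawn.

Times are UTC throughout; "local" day boundaries come from longitude
(mean solar time), never from civil time zones.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy.optimize import brentq

NAUTICAL_DAWN_ELEVATION = -12.0  # degrees

__all__ = ["solar_elevation", "nautical_dawn_before", "hours_after_nautical_dawn"]


def _frac_year(t: pd.Timestamp) -> float:
    """Fractional year in radians (NOAA convention)."""
    doy = t.dayofyear
    hour = t.hour + t.minute / 60.0 + t.second / 3600.0
    days_in_year = 366.0 if t.is_leap_year else 365.0
    return 2.0 * math.pi / days_in_year * (doy - 1 + (hour - 12.0) / 24.0)


def solar_elevation(t: pd.Timestamp, lat: float, lon: float) -> float:
    """Apparent solar elevation (degrees, no refraction) at UTC time ``t``."""
    g = _frac_year(t)
    # equation of time (minutes) and declination (radians)
    eqtime = 229.18 * (
        0.000075
        + 0.001868 * math.cos(g)
        - 0.032077 * math.sin(g)
        - 0.014615 * math.cos(2 * g)
        - 0.040849 * math.sin(2 * g)
    )
    decl = (
        0.006918
        - 0.399912 * math.cos(g)
        + 0.070257 * math.sin(g)
        - 0.006758 * math.cos(2 * g)
        + 0.000907 * math.sin(2 * g)
        - 0.002697 * math.cos(3 * g)
        + 0.00148 * math.sin(3 * g)
    )
    utc_minutes = t.hour * 60.0 + t.minute + t.second / 60.0 + t.microsecond / 6e7
    true_solar_min = (utc_minutes + eqtime + 4.0 * lon) % 1440.0
    ha = math.radians(true_solar_min / 4.0 - 180.0)  # hour angle
    phi = math.radians(lat)
    cos_zen = math.sin(phi) * math.sin(decl) + math.cos(phi) * math.cos(decl) * math.cos(ha)
    cos_zen = min(1.0, max(-1.0, cos_zen))
    return 90.0 - math.degrees(math.acos(cos_zen))


class DawnUndefinedError(ValueError):
    """Solar elevation never crosses -12 degrees near the requested time."""


def nautical_dawn_before(t: pd.Timestamp, lat: float, lon: float) -> pd.Timestamp:
    """Most recent ascending crossing of -12 deg solar elevation at or before ``t``.

    At study latitudes (|lat| well below the polar twilight limit) exactly one
    such crossing occurs per local day, so this is the nautical dawn of the
    local day containing ``t`` (or of the previous local day if ``t`` precedes
    that dawn).
    """
    t = pd.Timestamp(t)
    if t.tzinfo is not None:
        t = t.tz_convert("UTC").tz_localize(None)
    # scan back 30 h at 5-min resolution for bracketed ascending crossings;
    # look one grid step past t so that t exactly at dawn resolves to itself
    grid = pd.date_range(t - pd.Timedelta(hours=30), t + pd.Timedelta(minutes=5), freq="5min")
    elev = np.array([solar_elevation(g, lat, lon) for g in grid]) - NAUTICAL_DAWN_ELEVATION
    asc = np.nonzero((elev[:-1] < 0) & (elev[1:] >= 0))[0]

    def _refine(i: int) -> pd.Timestamp:
        t0, t1 = grid[i], grid[i + 1]

        def f(sec: float) -> float:
            return (
                solar_elevation(t0 + pd.Timedelta(seconds=sec), lat, lon)
                - NAUTICAL_DAWN_ELEVATION
            )

        sec = brentq(f, 0.0, (t1 - t0).total_seconds(), xtol=0.5)
        return t0 + pd.Timedelta(seconds=sec)

    for i in reversed(asc):
        dawn = _refine(int(i))
        if dawn <= t + pd.Timedelta(seconds=1):
            return dawn
    raise DawnUndefinedError(
        f"no ascending -12 deg crossing within 30 h before {t} at lat={lat}"
    )


def hours_after_nautical_dawn(t: pd.Timestamp, lat: float, lon: float) -> float:
    """Hours elapsed since the most recent nautical dawn; always in [0, 24)."""
    if abs(lat) >= 54.0:
        raise DawnUndefinedError(
            "nautical dawn is not guaranteed to exist year-round above |lat| 54 deg"
        )
    t = pd.Timestamp(t)
    if t.tzinfo is not None:
        t = t.tz_convert("UTC").tz_localize(None)
    dawn = nautical_dawn_before(t, lat, lon)
    return max(0.0, (t - dawn).total_seconds() / 3600.0)
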