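"""Raw-fix quality control and migration-phase segmentation.

A raw track is a per-fix table (one Fastloc-GPS observation per row):

    turtle_id, time (UTC), lat, lon, n_satellites, residual_error

Fastloc-GPS fixes carry a satellite count and a dimensionless residual error;
the standard quality rule keeps fixes with >= 4 satellites and residual < 35,
which yields positions good to a few tens of metres.

Segmentation identifies, per turtle: departure from the nesting beach, the
start of the oceanic crossing (first fix in water deeper than the 200 m
isobath) and arrival at the foraging ground (onset of localized residency,
whose centroid defines the goal).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import solar
from .bathymetry import BathymetryGrid
from .geodesy import GeoPoint, geodesic_distance

__all__ = [
    "TrackSegments",
    "NoOceanicCrossingError",
    "ArrivalUndetectedError",
    "read_tracks_csv",
    "write_tracks_csv",
    "qc_filter",
    "daily_fix_rate",
    "detect_beach_departure",
    "detect_oceanic_start",
    "detect_arrival",
    "segment_track",
    "pre_crossing_duration",
    "hours_after_nautical_dawn",
]

REQUIRED_COLUMNS = ("turtle_id", "time", "lat", "lon")
QC_COLUMNS = ("n_satellites", "residual_error")

DEFAULT_MIN_SATELLITES = 4
DEFAULT_MAX_RESIDUAL = 35.0


class NoOceanicCrossingError(ValueError):
    """Track never enters water deeper than the isobath threshold."""


class ArrivalUndetectedError(ValueError):
    """No terminal residency period found (track truncated?)."""


@dataclass
class TrackSegments:
    """Migration phase boundaries for one turtle."""

    turtle_id: str
    beach_departure_time: pd.Timestamp
    oceanic_start_time: pd.Timestamp
    arrival_time: pd.Timestamp
    departure_point: GeoPoint
    oceanic_start_point: GeoPoint
    goal: GeoPoint

    def __post_init__(self) -> None:
        if not (self.beach_departure_time <= self.oceanic_start_time <= self.arrival_time):
            raise ValueError(
                "segment ordering violated: require beach departure <= "
                "oceanic start <= arrival"
            )


# ---------------------------------------------------------------------------
# IO
# ---------------------------------------------------------------------------

def read_tracks_csv(path: str | Path) -> pd.DataFrame:
    """Read a raw fix table; sorts by (turtle_id, time) and validates schema.

    Missing QC columns are filled so every fix passes quality control, with a
    warning (QC pass-through).
    """
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"track CSV missing required column(s): {missing}")
    df["time"] = pd.to_datetime(df["time"], utc=True).dt.tz_localize(None)
    if "n_satellites" not in df.columns or "residual_error" not in df.columns:
        warnings.warn(
            "QC columns (n_satellites/residual_error) absent; all fixes will "
            "pass quality control",
            stacklevel=2,
        )
        if "n_satellites" not in df.columns:
            df["n_satellites"] = DEFAULT_MIN_SATELLITES
        if "residual_error" not in df.columns:
            df["residual_error"] = 0.0
    df = df.sort_values(["turtle_id", "time"], kind="stable").reset_index(drop=True)
    dup = df.duplicated(subset=["turtle_id", "time"])
    if dup.any():
        warnings.warn(f"dropping {int(dup.sum())} duplicate-timestamp fix(es)", stacklevel=2)
        df = df[~dup].reset_index(drop=True)
    return df


def write_tracks_csv(df: pd.DataFrame, path: str | Path) -> None:
    out = df.copy()
    out["time"] = pd.to_datetime(out["time"]).dt.strftime("%Y-%m-%dT%H:%M:%SZ")
    out.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Quality control and sampling statistics
# ---------------------------------------------------------------------------

def qc_filter(
    fixes: pd.DataFrame,
    min_sats: int = DEFAULT_MIN_SATELLITES,
    max_residual: float = DEFAULT_MAX_RESIDUAL,
) -> pd.DataFrame:
    """Keep fixes with ``n_satellites >= min_sats`` and ``residual_error < max_residual``.

    The residual bound is strict ("less than"), so a residual of exactly 35
    is rejected. Row order is preserved; an empty result warns.
    """
    keep = (fixes["n_satellites"] >= min_sats) & (fixes["residual_error"] < max_residual)
    out = fixes[keep].reset_index(drop=True)
    if len(out) == 0:
        warnings.warn("qc_filter removed every fix", stacklevel=2)
    return out


def daily_fix_rate(track: pd.DataFrame, window: tuple | None = None) -> float:
    """Fixes per day within ``window`` (default: first to last fix).

    A zero-length window raises; an empty window (no fixes inside a valid
    positive-length window) returns 0 with a warning.
    """
    t = pd.to_datetime(track["time"])
    if window is None:
        window = (t.min(), t.max())
    start, end = pd.Timestamp(window[0]), pd.Timestamp(window[1])
    days = (end - start).total_seconds() / 86400.0
    if days <= 0:
        raise ValueError("window length must be positive")
    n = int(((t >= start) & (t <= end)).sum())
    if n == 0:
        warnings.warn("no fixes inside window; rate is 0/day", stacklevel=2)
    return n / days


# ---------------------------------------------------------------------------
# Segmentation
# ---------------------------------------------------------------------------

def detect_beach_departure(
    track: pd.DataFrame,
    beach: GeoPoint | tuple,
    beach_radius_km: float = 5.0,
    move_km_per_6h: float = 2.0,
) -> int:
    """Index of the beach-departure fix.

    Departure is the last fix within ``beach_radius_km`` of the nesting beach
    before sustained movement begins — net displacement exceeding
    ``move_km_per_6h`` over the following 6 h — after which the turtle never
    returns inside the beach radius. Falls back to the last in-radius fix
    (or the first fix if none is in radius, with a warning).
    """
    lats = track["lat"].to_numpy()
    lons = track["lon"].to_numpy()
    t = pd.to_datetime(track["time"]).to_numpy()
    d_beach = np.array([geodesic_distance(beach, (la, lo)) for la, lo in zip(lats, lons)]) / 1e3
    inside = np.nonzero(d_beach <= beach_radius_km)[0]
    if len(inside) == 0:
        warnings.warn("no fix within the beach radius; using first fix as departure", stacklevel=2)
        return 0
    last_inside = inside[-1]
    for i in inside:
        if (d_beach[i + 1 :] > beach_radius_km).all() if i + 1 < len(lats) else False:
            # candidate: check sustained movement over the next 6 h
            horizon = t[i] + np.timedelta64(6, "h")
            j = int(np.searchsorted(t, horizon))
            j = min(j, len(lats) - 1)
            if j > i:
                net_km = geodesic_distance((lats[i], lons[i]), (lats[j], lons[j])) / 1e3
                if net_km > move_km_per_6h:
                    return int(i)
    return int(last_inside)


def detect_oceanic_start(
    track: pd.DataFrame, bathymetry: BathymetryGrid, threshold_m: float = 200.0
) -> tuple[pd.Timestamp, int]:
    """First fix in water deeper than ``threshold_m`` (time, row index)."""
    depths = bathymetry.depths(track["lat"].to_numpy(), track["lon"].to_numpy())
    deep = np.nonzero(depths > threshold_m)[0]
    if len(deep) == 0:
        raise NoOceanicCrossingError("track never enters water deeper than the threshold")
    i = int(deep[0])
    return pd.Timestamp(track["time"].iloc[i]), i


def detect_arrival(
    track: pd.DataFrame, radius_km: float = 20.0, min_days: float = 14.0
) -> tuple[pd.Timestamp, GeoPoint, int]:
    """Arrival at the foraging ground: onset of localized residency.

    Arrival is the earliest fix T such that every fix from T onward lies
    within ``radius_km`` of the centroid of the fixes from T onward, and the
    span from T to the last fix is at least ``min_days``. The goal is that
    terminal centroid. Returns (time, goal, row index).
    """
    lats = track["lat"].to_numpy(float)
    lons = track["lon"].to_numpy(float)
    t = pd.to_datetime(track["time"]).to_numpy()
    n = len(track)
    if n < 2:
        raise ArrivalUndetectedError("track too short for residency detection")
    # suffix centroids in one backward pass
    suf_lat = np.cumsum(lats[::-1])[::-1] / np.arange(n, 0, -1)
    suf_lon = np.cumsum(lons[::-1])[::-1] / np.arange(n, 0, -1)
    span_ok = (t[-1] - t) / np.timedelta64(1, "D") >= min_days
    for i in range(n):
        if not span_ok[i]:
            break
        c = (suf_lat[i], suf_lon[i])
        dists = np.array(
            [geodesic_distance(c, (la, lo)) for la, lo in zip(lats[i:], lons[i:])]
        )
        if (dists <= radius_km * 1e3).all():
            return pd.Timestamp(t[i]), GeoPoint.of(*c), i
    raise ArrivalUndetectedError(
        f"no terminal period of >= {min_days} d within {radius_km} km of its centroid"
    )


def segment_track(
    track: pd.DataFrame,
    bathymetry: BathymetryGrid,
    beach: GeoPoint | tuple,
    isobath_m: float = 200.0,
    beach_radius_km: float = 5.0,
    arrival_radius_km: float = 20.0,
    arrival_min_days: float = 14.0,
) -> TrackSegments:
    """Full phase segmentation of one QC-filtered track."""
    tid = str(track["turtle_id"].iloc[0]) if "turtle_id" in track else ""
    i_dep = detect_beach_departure(track, beach, beach_radius_km)
    _, i_ocean = detect_oceanic_start(track, bathymetry, isobath_m)
    arr_t, goal, _ = detect_arrival(track, arrival_radius_km, arrival_min_days)
    i_ocean = max(i_ocean, i_dep)  # a pre-departure deep fix cannot start the crossing
    times = pd.to_datetime(track["time"])
    return TrackSegments(
        turtle_id=tid,
        beach_departure_time=pd.Timestamp(times.iloc[i_dep]),
        oceanic_start_time=pd.Timestamp(times.iloc[i_ocean]),
        arrival_time=max(arr_t, pd.Timestamp(times.iloc[i_ocean])),
        departure_point=GeoPoint.of(track["lat"].iloc[i_dep], track["lon"].iloc[i_dep]),
        oceanic_start_point=GeoPoint.of(track["lat"].iloc[i_ocean], track["lon"].iloc[i_ocean]),
        goal=goal,
    )


def pre_crossing_duration(segments: TrackSegments) -> float:
    """Hours between beach departure and the start of the oceanic crossing."""
    if segments.beach_departure_time is None or segments.oceanic_start_time is None:
        raise ValueError("both segment boundaries must be defined")
    return (
        segments.oceanic_start_time - segments.beach_departure_time
    ).total_seconds() / 3600.0


def hours_after_nautical_dawn(t: pd.Timestamp, p: GeoPoint | tuple) -> float:
    """Hours of ``t`` after the most recent nautical dawn at location ``p``."""
    return solar.hours_after_nautical_dawn(t, p[0], p[1])
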