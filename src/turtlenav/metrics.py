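"""Orientation and route-efficiency statistics.

The central quantity is the straightness index: the geodesic beeline from
migration origin to goal divided by the total along-track distance. A value
of 1 means the track *is* the geodesic; values far below 1 mean circuitous
travel, the signature of target search under a coarse navigational map.

Departure orientation is summarized as the signed deviation of the departure
bearing from the bearing to the goal, wrapped to (-180, 180] with negative =
counterclockwise (westward of a northward goal line).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .geodesy import GeoPoint, geodesic_distance, initial_bearing, path_length, wrap_signed

__all__ = [
    "MigrationSummary",
    "straightness_index",
    "departure_direction",
    "deviation_from_goal",
    "circular_mean",
    "straightness_by_distance_class",
    "summarize_migration",
    "rose_bins",
]


@dataclass
class MigrationSummary:
    """Per-turtle route metrics."""

    turtle_id: str
    beeline_km: float
    path_km: float
    straightness: float
    departure_bearing_deg: float
    goal_bearing_deg: float
    departure_deviation_deg: float

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def straightness_index(track: pd.DataFrame, origin: GeoPoint | tuple, goal: GeoPoint | tuple) -> float:
    """Beeline(origin->goal) / along-track path length, in (0, 1].

    ``track`` supplies the path (columns ``lat``/``lon``); it should start at
    the origin and end in the residency cloud around the goal. Values can
    nominally exceed 1 only if the supplied path is shorter than the beeline
    (e.g. a truncated track); that raises.
    """
    if len(track) < 2:
        raise ValueError("path needs at least 2 points")
    beeline = geodesic_distance(origin, goal)
    path = path_length(track["lat"].to_numpy(), track["lon"].to_numpy())
    if path <= 0:
        raise ValueError("zero path length")
    s = beeline / path
    if s > 1.0 + 1e-9:
        raise ValueError(
            f"straightness {s:.3f} > 1: the supplied path is shorter than the "
            "beeline — origin/goal likely inconsistent with the track"
        )
    return min(s, 1.0)


def departure_direction(
    track: pd.DataFrame, exit_point: GeoPoint | tuple, min_travel_km: float = 5.0
) -> float:
    """Bearing from the island exit to the first fix >= ``min_travel_km`` of travel.

    Cumulative along-track distance is measured from the first fix at/after
    the exit point; the departure bearing is taken from the exit point to the
    first fix reaching the travel threshold, which smooths over fix-to-fix
    jitter right at the coast.
    """
    lats = track["lat"].to_numpy()
    lons = track["lon"].to_numpy()
    cum = 0.0
    for i in range(1, len(track)):
        cum += geodesic_distance((lats[i - 1], lons[i - 1]), (lats[i], lons[i]))
        if cum >= min_travel_km * 1e3:
            if (lats[i], lons[i]) == tuple(exit_point):
                continue  # degenerate loop back onto the exit fix itself
            return initial_bearing(exit_point, (lats[i], lons[i]))
    raise ValueError(f"track ends before {min_travel_km} km of travel from the exit point")


def deviation_from_goal(bearing_deg: float, goal_bearing_deg: float) -> float:
    """Signed angular deviation (bearing - goal), wrapped to (-180, 180].

    Negative values are counterclockwise of the goal line: for a northward
    goal, a westward departure gives a negative deviation.
    """
    return wrap_signed(bearing_deg - goal_bearing_deg)


def circular_mean(angles_deg) -> tuple[float, float]:
    """Unit-vector mean direction of a set of angles.

    Returns ``(mean_deg, resultant_length)`` with the mean wrapped to
    (-180, 180] and the resultant length in [0, 1]. A resultant length below
    1e-12 means the directions cancel and the mean is undefined (raises).
    """
    a = np.radians(np.asarray(angles_deg, float))
    if a.size == 0:
        raise ValueError("need at least one angle")
    s, c = np.sin(a).mean(), np.cos(a).mean()
    r = math.hypot(s, c)
    if r < 1e-12:
        raise ValueError("circular mean undefined: resultant length ~ 0")
    return wrap_signed(math.degrees(math.atan2(s, c))), r


def straightness_by_distance_class(
    summaries: pd.DataFrame, threshold_km: float = 200.0, welch: bool = True
) -> dict:
    """Compare straightness between short- and long-beeline migrations.

    ``summaries`` needs ``beeline_km`` and ``straightness`` columns. Groups
    are beeline < threshold vs >= threshold; reports per-class mean/s.d./n
    and a two-sample t statistic (Welch by default, pooled optionally).
    """
    short = summaries.loc[summaries.beeline_km < threshold_km, "straightness"]
    long_ = summaries.loc[summaries.beeline_km >= threshold_km, "straightness"]
    if len(short) < 2 or len(long_) < 2:
        raise ValueError("need >= 2 migrations in each distance class")
    t, p = stats.ttest_ind(short, long_, equal_var=not welch)
    return {
        "threshold_km": threshold_km,
        "mean_short": float(short.mean()),
        "sd_short": float(short.std(ddof=1)),
        "n_short": int(len(short)),
        "mean_long": float(long_.mean()),
        "sd_long": float(long_.std(ddof=1)),
        "n_long": int(len(long_)),
        "t": float(t),
        "p": float(p),
        "welch": welch,
    }


def summarize_migration(
    track: pd.DataFrame,
    origin: GeoPoint | tuple,
    goal: GeoPoint | tuple,
    exit_point: GeoPoint | tuple | None = None,
    min_travel_km: float = 5.0,
) -> MigrationSummary:
    """Compute the full per-turtle route summary.

    The beeline runs from the beach-departure point to the foraging-site
    centroid; the departure bearing is measured from ``exit_point`` (defaults
    to ``origin``) after ``min_travel_km`` of travel, and its deviation is
    relative to the goal bearing from that same exit point.
    """
    tid = str(track["turtle_id"].iloc[0]) if "turtle_id" in track else ""
    exit_point = origin if exit_point is None else exit_point
    beeline_km = geodesic_distance(origin, goal) / 1e3
    path_km = path_length(track["lat"].to_numpy(), track["lon"].to_numpy()) / 1e3
    dep = departure_direction(track, exit_point, min_travel_km)
    goal_bearing = initial_bearing(exit_point, goal)
    return MigrationSummary(
        turtle_id=tid,
        beeline_km=beeline_km,
        path_km=path_km,
        straightness=straightness_index(track, origin, goal),
        departure_bearing_deg=dep,
        goal_bearing_deg=goal_bearing,
        departure_deviation_deg=deviation_from_goal(dep, goal_bearing),
    )


def rose_bins(angles_deg, bin_width: float = 10.0) -> pd.DataFrame:
    """Counts of signed angles in ``bin_width``-degree bins for rose diagrams.

    Bins are centred so that 0 deg (the goal direction) is a bin edge-centred
    class: [-5, 5), [5, 15), ... for the default 10-degree width.
    """
    a = np.array([wrap_signed(x) for x in np.asarray(angles_deg, float)])
    edges = np.arange(-180.0 - bin_width / 2, 180.0 + bin_width, bin_width)
    edges = edges[(edges >= -180.0 - bin_width / 2) & (edges <= 180.0 + bin_width / 2)]
    counts, _ = np.histogram(a, bins=edges)
    centers = (edges[:-1] + edges[1:]) / 2
    return pd.DataFrame({"bin_center_deg": centers, "count": counts})
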