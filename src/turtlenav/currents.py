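"""Ocean-current association, swimming-vector recovery and drift partition.

The observed ground track of a swimming migrant is the sum of its active
swimming and passive current advection. Given a gridded current field (e.g. a
6-hourly ocean reanalysis at ~0.08 deg, near-surface level), each 6-h track
step is paired with the current at its start location/time; subtracting the
current vector from the ground velocity recovers the active swimming vector:

    v_swim = v_ground - v_current

Off-course movement is quantified as the displacement component perpendicular
to the beeline toward the goal (positive = left of the beeline, facing the
goal). Because the decomposition is linear, per-step perpendicular
displacements satisfy an exact closure:

    ground-perp = current-perp + swim-perp

and summing each term over the oceanic crossing partitions the total lateral
deviation at bank entry between current advection and the animal's own
swimming. A turtle "compensated" for drift when its swimming reduced the
lateral deviation relative to what the current alone would have produced.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr
from scipy import stats

from .bathymetry import BathymetryGrid
from .geodesy import EnuVelocity, GeoPoint, initial_bearing
from .tracks import TrackSegments

__all__ = [
    "CurrentField",
    "NoCurrentDataError",
    "DriftPartition",
    "read_current_field",
    "sample_current",
    "swimming_vector",
    "perpendicular_component",
    "decompose_track",
    "partition_deviation",
    "deviation_regression",
]


class NoCurrentDataError(ValueError):
    """No usable current value at the requested point/time (outside grid or all-masked)."""


@dataclass
class CurrentField:
    """Gridded eastward/northward current velocities on (time, lat, lon).

    ``u``/``v`` are m/s; land cells are NaN (masked). Axes must be strictly
    ascending; the time axis is the field's native slicing (6-hourly for the
    reanalysis emulated here).
    """

    time: np.ndarray   # datetime64[ns], ascending
    lat: np.ndarray
    lon: np.ndarray
    u: np.ndarray      # (ntime, nlat, nlon) eastward m/s
    v: np.ndarray      # northward m/s
    depth_label: str = "1.5m"

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, "datetime64[ns]")
        self.lat = np.asarray(self.lat, float)
        self.lon = np.asarray(self.lon, float)
        self.u = np.asarray(self.u, float)
        self.v = np.asarray(self.v, float)
        for ax in (self.lat, self.lon):
            if not (np.diff(ax) > 0).all():
                raise ValueError("spatial axes must be strictly ascending")
        if len(self.time) > 1 and not (np.diff(self.time).astype(int) > 0).all():
            raise ValueError("time axis must be strictly ascending")
        shape = (len(self.time), len(self.lat), len(self.lon))
        if self.u.shape != shape or self.v.shape != shape:
            raise ValueError(f"u/v must have shape {shape}")

    def to_dataset(self) -> xr.Dataset:
        return xr.Dataset(
            {
                "uo": (("time", "lat", "lon"), self.u, {"units": "m s-1"}),
                "vo": (("time", "lat", "lon"), self.v, {"units": "m s-1"}),
            },
            coords={"time": self.time, "lat": self.lat, "lon": self.lon},
            attrs={"depth": self.depth_label},
        )


def read_current_field(path: str | Path) -> CurrentField:
    """Read a current field from a CF-style NetCDF file or a long-format CSV.

    NetCDF: dimensions ``time/lat/lon``, variables ``uo``/``vo`` (or ``u``/``v``).
    CSV fallback columns: ``time, lat, lon, u, v``.
    """
    path = Path(path)
    if path.suffix.lower() in (".nc", ".cdf", ".nc3"):
        ds = xr.open_dataset(path, engine="scipy")
        uname = "uo" if "uo" in ds else "u"
        vname = "vo" if "vo" in ds else "v"
        u = ds[uname].transpose("time", "lat", "lon").values
        v = ds[vname].transpose("time", "lat", "lon").values
        return CurrentField(ds["time"].values, ds["lat"].values, ds["lon"].values, u, v)
    df = pd.read_csv(path, parse_dates=["time"])
    piv_u = df.pivot_table(index=["time", "lat"], columns="lon", values="u")
    times = piv_u.index.get_level_values("time").unique().sort_values()
    lats = np.sort(df["lat"].unique())
    lons = np.sort(df["lon"].unique())
    u = np.full((len(times), len(lats), len(lons)), np.nan)
    v = np.full_like(u, np.nan)
    ti = {t: i for i, t in enumerate(times)}
    lai = {la: i for i, la in enumerate(lats)}
    loi = {lo: i for i, lo in enumerate(lons)}
    for row in df.itertuples(index=False):
        u[ti[row.time], lai[row.lat], loi[row.lon]] = row.u
        v[ti[row.time], lai[row.lat], loi[row.lon]] = row.v
    return CurrentField(times.to_numpy(), lats, lons, u, v)


def _time_index(field: CurrentField, t: np.datetime64, interp: str) -> list[tuple[int, float]]:
    """Time slice indices and weights (nearest-neighbour or linear)."""
    times = field.time.astype("int64")
    tt = np.datetime64(t, "ns").astype("int64")
    if tt < times[0] or tt > times[-1]:
        # tolerate half a slice spacing beyond the ends (nearest snaps back)
        spacing = times[1] - times[0] if len(times) > 1 else 0
        if tt < times[0] - spacing / 2 or tt > times[-1] + spacing / 2:
            raise NoCurrentDataError(f"time {t} outside current-field coverage")
        return [(0 if tt < times[0] else len(times) - 1, 1.0)]
    j = int(np.searchsorted(times, tt, side="right") - 1)
    j = min(j, len(times) - 2) if len(times) > 1 else 0
    if len(times) == 1:
        return [(0, 1.0)]
    frac = (tt - times[j]) / (times[j + 1] - times[j])
    if interp == "nearest":
        return [(j + 1, 1.0)] if frac > 0.5 else [(j, 1.0)]
    return [(j, 1.0 - frac), (j + 1, frac)]


def sample_current(
    field: CurrentField, p: GeoPoint | tuple, t, time_interp: str = "nearest"
) -> EnuVelocity:
    """Current velocity at point ``p`` and time ``t``.

    Bilinear interpolation in space with masked (NaN, i.e. land) neighbours
    excluded and the remaining weights renormalized; nearest-neighbour in
    time by default (matching the native slicing of 6-hourly fields), linear
    in time with ``time_interp="linear"``.
    """
    lat, lon = float(p[0]), float(p[1])
    if not (field.lat[0] <= lat <= field.lat[-1] and field.lon[0] <= lon <= field.lon[-1]):
        raise NoCurrentDataError(f"point ({lat}, {lon}) outside current-field coverage")
    i = max(0, min(int(np.searchsorted(field.lat, lat, side="right") - 1), len(field.lat) - 2))
    j = max(0, min(int(np.searchsorted(field.lon, lon, side="right") - 1), len(field.lon) - 2))
    fy = (lat - field.lat[i]) / (field.lat[i + 1] - field.lat[i])
    fx = (lon - field.lon[j]) / (field.lon[j + 1] - field.lon[j])
    w = np.array([(1 - fy) * (1 - fx), (1 - fy) * fx, fy * (1 - fx), fy * fx])

    u_acc = v_acc = 0.0
    for k, tw in _time_index(field, np.datetime64(pd.Timestamp(t)), time_interp):
        uu = field.u[k, i : i + 2, j : j + 2].ravel()
        vv = field.v[k, i : i + 2, j : j + 2].ravel()
        ok = np.isfinite(uu) & np.isfinite(vv)
        wsum = w[ok].sum()
        if wsum <= 0:
            raise NoCurrentDataError(f"all current neighbours masked at ({lat}, {lon}), {t}")
        u_acc += tw * float((w[ok] * uu[ok]).sum() / wsum)
        v_acc += tw * float((w[ok] * vv[ok]).sum() / wsum)
    return EnuVelocity(u_acc, v_acc)


def swimming_vector(ground: EnuVelocity, current: EnuVelocity) -> EnuVelocity:
    """Active swimming velocity: ground velocity minus current velocity."""
    return EnuVelocity(ground.east - current.east, ground.north - current.north)


def perpendicular_component(vel: EnuVelocity, beeline_bearing_deg: float, dt_s: float) -> float:
    """Signed perpendicular displacement (km) of ``vel`` over ``dt_s`` seconds.

    Projects onto the unit vector 90 deg counterclockwise from the beeline
    bearing, so positive values are displacements to the left of the beeline
    when facing the goal (westward for a northward beeline).
    """
    if dt_s <= 0:
        raise ValueError("dt must be positive")
    th = math.radians(beeline_bearing_deg)
    left_e, left_n = -math.cos(th), math.sin(th)
    return (vel.east * left_e + vel.north * left_n) * dt_s / 1e3


@dataclass
class DriftPartition:
    """Summed lateral deviation at bank entry, split by cause."""

    turtle_id: str
    total_perp_km: float     # ground track
    current_perp_km: float   # current advection alone
    swim_perp_km: float      # active swimming alone
    compensated: bool        # swimming reduced the current-induced deviation
    n_steps: int
    beeline_bearing_deg: float

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def decompose_track(
    interp_track: pd.DataFrame,
    field: CurrentField,
    beeline_bearing_deg: float,
    goal: GeoPoint | tuple | None = None,
    per_step_goal_bearing: bool = False,
    time_interp: str = "nearest",
) -> pd.DataFrame:
    """Per-step ground/current/swim decomposition of an interpolated track.

    ``interp_track`` is a regular-interval node table (``time/lat/lon``).
    Each step uses the current sampled at the step-start node. The
    perpendicular axis is fixed at ``beeline_bearing_deg`` unless
    ``per_step_goal_bearing`` is set, in which case the bearing from each
    step-start node to ``goal`` is used instead.
    """
    from .geodesy import step_velocities

    steps = step_velocities(interp_track)
    rows = []
    for r in steps.itertuples(index=False):
        cur = sample_current(field, (r.lat, r.lon), r.time, time_interp)
        ground = EnuVelocity(r.ground_east_ms, r.ground_north_ms)
        swim = swimming_vector(ground, cur)
        bb = beeline_bearing_deg
        if per_step_goal_bearing:
            if goal is None:
                raise ValueError("per_step_goal_bearing requires goal")
            bb = initial_bearing((r.lat, r.lon), goal)
        rows.append(
            {
                "time": r.time,
                "lat": r.lat,
                "lon": r.lon,
                "dt_s": r.dt_s,
                "speed_ms": r.speed_ms,
                "bearing_deg": r.bearing_deg,
                "ground_east_ms": ground.east,
                "ground_north_ms": ground.north,
                "current_east_ms": cur.east,
                "current_north_ms": cur.north,
                "swim_east_ms": swim.east,
                "swim_north_ms": swim.north,
                "swim_speed_ms": swim.speed,
                "current_speed_ms": cur.speed,
                "beeline_bearing_deg": bb,
                "perp_ground_km": perpendicular_component(ground, bb, r.dt_s),
                "perp_current_km": perpendicular_component(cur, bb, r.dt_s),
                "perp_swim_km": perpendicular_component(swim, bb, r.dt_s),
            }
        )
    return pd.DataFrame(rows)


def partition_deviation(
    interp_track: pd.DataFrame,
    field: CurrentField,
    segments: TrackSegments,
    bathymetry: BathymetryGrid,
    isobath_m: float = 200.0,
    signed: bool = True,
    per_step_goal_bearing: bool = False,
    time_interp: str = "nearest",
) -> tuple[DriftPartition, pd.DataFrame]:
    """Partition the lateral deviation over the oceanic crossing.

    Sums per-step perpendicular displacements of the ground, current and swim
    vectors from the oceanic start to the first interpolated node back in
    water shallower than ``isobath_m`` (bank entry); if the track never
    re-enters shallow water the sums run to the last node, with a warning.
    ``signed=False`` sums absolute per-step magnitudes instead (no closure
    in that mode).
    """
    t = pd.to_datetime(interp_track["time"])
    mask = t >= segments.oceanic_start_time
    sub = interp_track[mask].reset_index(drop=True)
    if len(sub) < 2:
        raise ValueError("no interpolated steps after the oceanic start")
    depths = bathymetry.depths(sub["lat"].to_numpy(), sub["lon"].to_numpy())
    shallow = np.nonzero(depths < isobath_m)[0]
    # skip any leading shallow nodes right at the crossing start
    first_deep = int(np.argmax(depths >= isobath_m)) if (depths >= isobath_m).any() else None
    end = None
    if first_deep is not None:
        after = shallow[shallow > first_deep]
        if len(after):
            end = int(after[0])
    if end is None:
        warnings.warn(
            "track never re-enters shallow water; partition computed to the last node",
            stacklevel=2,
        )
        end = len(sub) - 1
    sub = sub.iloc[: end + 1]

    bb = initial_bearing(segments.departure_point, segments.goal)
    dec = decompose_track(
        sub, field, bb, goal=segments.goal,
        per_step_goal_bearing=per_step_goal_bearing, time_interp=time_interp,
    )
    if signed:
        tot = float(dec.perp_ground_km.sum())
        cur = float(dec.perp_current_km.sum())
        swim = float(dec.perp_swim_km.sum())
    else:
        tot = float(dec.perp_ground_km.abs().sum())
        cur = float(dec.perp_current_km.abs().sum())
        swim = float(dec.perp_swim_km.abs().sum())
    part = DriftPartition(
        turtle_id=segments.turtle_id,
        total_perp_km=tot,
        current_perp_km=cur,
        swim_perp_km=swim,
        compensated=bool(abs(tot) < abs(cur) - 1e-6),  # tolerance beats float fuzz
        n_steps=len(dec),
        beeline_bearing_deg=bb,
    )
    return part, dec


def deviation_regression(partitions: pd.DataFrame | list) -> dict:
    """OLS of total lateral deviation on its active-swimming component.

    Accepts a DataFrame with ``total_perp_km``/``swim_perp_km`` columns (or a
    list of :class:`DriftPartition`). Reports slope, intercept, r2, F and p.
    """
    if not isinstance(partitions, pd.DataFrame):
        partitions = pd.DataFrame([p.as_dict() for p in partitions])
    if len(partitions) < 3:
        raise ValueError("need >= 3 partitions for a regression")
    x = partitions["swim_perp_km"].to_numpy(float)
    y = partitions["total_perp_km"].to_numpy(float)
    if np.ptp(x) == 0:
        raise ValueError("degenerate regression: swim deviations are constant")
    res = stats.linregress(x, y)
    n = len(x)
    r2 = res.rvalue**2
    if r2 >= 1.0:
        f = math.inf
    else:
        f = r2 / (1 - r2) * (n - 2)
    return {
        "slope": float(res.slope),
        "intercept": float(res.intercept),
        "r2": float(r2),
        "F": float(f),
        "df": (1, n - 2),
        "p": float(res.pvalue),
        "n": n,
    }
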