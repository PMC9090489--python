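"""Gridded bathymetry: depth lookups, 200 m isobath classification and crossings.

Depth convention: metres positive downward; land is depth <= 0. Grids stored as
negative-down elevation (the GEBCO convention) must be negated on load —
``read_bathymetry`` handles this via its ``convention`` argument.

The 200 m isobath is the study's working definition of "shallow water": the
submerged banks that serve as migration targets are the areas shallower than
200 m. The boundary convention here is strict — depth < threshold is shallow,
depth >= threshold (including exactly 200 m) is deep.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr
from scipy import stats

from .geodesy import GeoPoint

__all__ = [
    "BathymetryGrid",
    "OutsideGridError",
    "read_bathymetry",
    "classify_depth",
    "isobath_crossings",
    "speed_by_depth_class",
]

DEFAULT_ISOBATH_M = 200.0


class OutsideGridError(ValueError):
    """Query point outside the grid's spatial coverage."""


def _bilinear(lat_ax: np.ndarray, lon_ax: np.ndarray, grid: np.ndarray,
              lat: float, lon: float) -> float:
    """Bilinear interpolation on a regular (lat, lon) grid; NaNs propagate."""
    if not (lat_ax[0] <= lat <= lat_ax[-1] and lon_ax[0] <= lon <= lon_ax[-1]):
        raise OutsideGridError(f"point ({lat}, {lon}) outside grid coverage")
    i = min(np.searchsorted(lat_ax, lat, side="right") - 1, len(lat_ax) - 2)
    j = min(np.searchsorted(lon_ax, lon, side="right") - 1, len(lon_ax) - 2)
    i = max(i, 0)
    j = max(j, 0)
    fy = (lat - lat_ax[i]) / (lat_ax[i + 1] - lat_ax[i])
    fx = (lon - lon_ax[j]) / (lon_ax[j + 1] - lon_ax[j])
    z = grid[i : i + 2, j : j + 2]
    return float(
        z[0, 0] * (1 - fy) * (1 - fx)
        + z[0, 1] * (1 - fy) * fx
        + z[1, 0] * fy * (1 - fx)
        + z[1, 1] * fy * fx
    )


@dataclass
class BathymetryGrid:
    """Regular lat/lon depth grid, metres positive down (land <= 0)."""

    lat: np.ndarray       # ascending
    lon: np.ndarray       # ascending
    depth_m: np.ndarray   # shape (nlat, nlon)

    def __post_init__(self) -> None:
        self.lat = np.asarray(self.lat, float)
        self.lon = np.asarray(self.lon, float)
        self.depth_m = np.asarray(self.depth_m, float)
        if not (np.diff(self.lat) > 0).all() or not (np.diff(self.lon) > 0).all():
            raise ValueError("grid axes must be strictly ascending")
        if self.depth_m.shape != (len(self.lat), len(self.lon)):
            raise ValueError("depth array shape does not match axes")
        if not np.isfinite(self.depth_m).all():
            raise ValueError("depth grid contains non-finite values")

    def depth_at(self, p: GeoPoint | tuple) -> float:
        """Bilinearly interpolated depth (m, positive down) at point ``p``."""
        return _bilinear(self.lat, self.lon, self.depth_m, p[0], p[1])

    def depths(self, lats, lons) -> np.ndarray:
        return np.array([self.depth_at((la, lo)) for la, lo in zip(lats, lons)])

    def to_dataset(self) -> xr.Dataset:
        return xr.Dataset(
            {"depth": (("lat", "lon"), self.depth_m)},
            coords={"lat": self.lat, "lon": self.lon},
            attrs={"units": "m", "positive": "down"},
        )


def read_bathymetry(path: str | Path, convention: str = "auto") -> BathymetryGrid:
    """Read a bathymetry grid from a CF-style NetCDF file or a long-format CSV.

    CSV columns: ``lat, lon, depth`` (or ``elevation``). ``convention`` is
    ``"depth"`` (positive down), ``"elevation"`` (positive up, negated on
    load), or ``"auto"``: a variable named *elevation*, or one whose ocean
    values are predominantly negative, is treated as elevation.
    """
    path = Path(path)
    if path.suffix.lower() in (".nc", ".cdf", ".nc3"):
        ds = xr.open_dataset(path, engine="scipy")
        name = next(v for v in ("depth", "elevation", "z") if v in ds)
        da = ds[name].transpose(..., "lat", "lon")
        vals = da.values.astype(float)
        lat, lon = ds["lat"].values, ds["lon"].values
    else:
        df = pd.read_csv(path)
        name = "depth" if "depth" in df.columns else "elevation"
        piv = df.pivot_table(index="lat", columns="lon", values=name)
        lat, lon = piv.index.to_numpy(), piv.columns.to_numpy()
        vals = piv.to_numpy(float)
    if convention == "auto":
        convention = "elevation" if (name == "elevation" or np.nanmedian(vals) < 0) else "depth"
    if convention == "elevation":
        vals = -vals
    order_lat = np.argsort(lat)
    order_lon = np.argsort(lon)
    return BathymetryGrid(lat[order_lat], lon[order_lon], vals[np.ix_(order_lat, order_lon)])


def classify_depth(
    track: pd.DataFrame, grid: BathymetryGrid, threshold_m: float = DEFAULT_ISOBATH_M
) -> pd.Series:
    """Per-fix labels: ``"shallow"`` iff interpolated depth < threshold, else ``"deep"``.

    Land (depth <= 0) counts as shallow for segmentation purposes.
    """
    depths = grid.depths(track["lat"].to_numpy(), track["lon"].to_numpy())
    return pd.Series(np.where(depths < threshold_m, "shallow", "deep"), index=track.index)


def isobath_crossings(
    track: pd.DataFrame, grid: BathymetryGrid, threshold_m: float = DEFAULT_ISOBATH_M
) -> pd.DataFrame:
    """Ordered isobath-crossing events along a track.

    One event per consecutive pair of fixes whose shallow/deep labels differ.
    The crossing point and time are linearly interpolated between the two
    fixes by depth (the fraction at which interpolated depth would equal the
    threshold). Columns: ``time, lat, lon, direction`` where direction is
    ``"deep_to_shallow"`` or ``"shallow_to_deep"``.
    """
    df = track.reset_index(drop=True)
    depths = grid.depths(df["lat"].to_numpy(), df["lon"].to_numpy())
    labels = depths < threshold_m  # True = shallow
    t = pd.to_datetime(df["time"].to_numpy())
    events = []
    for i in range(len(df) - 1):
        if labels[i] == labels[i + 1]:
            continue
        d0, d1 = depths[i], depths[i + 1]
        frac = 0.5 if d1 == d0 else float(np.clip((threshold_m - d0) / (d1 - d0), 0.0, 1.0))
        events.append(
            {
                "time": t[i] + frac * (t[i + 1] - t[i]),
                "lat": df.lat[i] + frac * (df.lat[i + 1] - df.lat[i]),
                "lon": df.lon[i] + frac * (df.lon[i + 1] - df.lon[i]),
                "direction": "shallow_to_deep" if labels[i] else "deep_to_shallow",
                "index_before": i,
            }
        )
    return pd.DataFrame(events, columns=["time", "lat", "lon", "direction", "index_before"])


def speed_by_depth_class(steps_by_turtle: dict[str, pd.DataFrame]) -> dict:
    """Deep/shallow travel-speed contrast across turtles.

    ``steps_by_turtle`` maps turtle id to a per-step frame with ``speed_ms``
    and ``depth_class`` columns (labels from :func:`classify_depth` evaluated
    at step starts). Computes per-turtle class mean speeds, then a paired
    t-test on (deep - shallow) means across turtles with both classes present;
    turtles missing a class are excluded from the test with a warning.
    """
    per = []
    for tid, df in steps_by_turtle.items():
        g = df.groupby("depth_class")["speed_ms"].mean()
        per.append(
            {
                "turtle_id": tid,
                "mean_speed_deep_ms": g.get("deep", np.nan),
                "mean_speed_shallow_ms": g.get("shallow", np.nan),
            }
        )
    per_df = pd.DataFrame(per)
    paired = per_df.dropna(subset=["mean_speed_deep_ms", "mean_speed_shallow_ms"])
    excluded = sorted(set(per_df.turtle_id) - set(paired.turtle_id))
    if excluded:
        warnings.warn(
            f"{len(excluded)} turtle(s) lack fixes in one depth class and are "
            f"excluded from the paired test: {excluded}",
            stacklevel=2,
        )
    result = {
        "per_turtle": per_df,
        "mean_speed_deep_ms": float(paired.mean_speed_deep_ms.mean()) if len(paired) else np.nan,
        "mean_speed_shallow_ms": float(paired.mean_speed_shallow_ms.mean()) if len(paired) else np.nan,
        "n_paired": int(len(paired)),
        "t": np.nan,
        "df": np.nan,
        "p": np.nan,
    }
    if len(paired) >= 2:
        diffs = paired.mean_speed_deep_ms - paired.mean_speed_shallow_ms
        if np.allclose(diffs.std(ddof=1), 0.0):
            result["t"] = np.inf if diffs.mean() > 0 else (-np.inf if diffs.mean() < 0 else 0.0)
            result["df"] = len(paired) - 1
            result["p"] = 0.0 if diffs.mean() != 0 else 1.0
        else:
            t, p = stats.ttest_rel(paired.mean_speed_deep_ms, paired.mean_speed_shallow_ms)
            result.update(t=float(t), df=len(paired) - 1, p=float(p))
    return result
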