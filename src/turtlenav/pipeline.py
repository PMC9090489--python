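"""End-to-end pipeline: raw fixes + grids -> per-turtle and group summaries.

``run_pipeline`` composes the stages in study order: quality control, phase
segmentation, 6-h interpolation, route metrics, depth-class speeds, and the
current/swimming drift partition, then writes per-turtle CSVs and a group
statistics JSON. Turtles failing a stage are excluded from downstream tables
with a reason code rather than aborting the run.
"""

from __future__ import annotations

import configparser
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import bathymetry as bath
from . import currents as cur
from . import metrics as met
from . import tracks as trk
from .geodesy import GeoPoint, initial_bearing, interpolate_positions, step_velocities

logger = logging.getLogger("turtlenav")

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "group_statistics"]


@dataclass
class PipelineConfig:
    """All tunable constants of the analysis, with study defaults."""

    beach_lat: float = -7.48
    beach_lon: float = 72.49
    min_satellites: int = 4
    max_residual: float = 35.0
    interp_interval_h: float = 6.0
    max_gap_h: float = 48.0
    interp_method: str = "latlon"          # or "geodesic"
    departure_min_travel_km: float = 5.0
    isobath_m: float = 200.0
    beach_radius_km: float = 5.0
    arrival_radius_km: float = 20.0
    arrival_min_days: float = 14.0
    distance_class_km: float = 200.0
    welch: bool = True
    signed_partition: bool = True
    per_step_goal_bearing: bool = False
    time_interp: str = "nearest"           # current time matching
    path_on_interpolated: bool = False     # path length from raw fixes by default
    seed: int = 0

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        """Load from an INI-style file; keys may live in any section."""
        cp = configparser.ConfigParser()
        cp.read(path)
        flat: dict = {}
        for section in cp.sections():
            flat.update(dict(cp[section]))
        kwargs = {}
        for f_ in cls.__dataclass_fields__.values():
            if f_.name in flat:
                raw = flat[f_.name]
                if f_.type == "bool" or isinstance(f_.default, bool):
                    kwargs[f_.name] = raw.strip().lower() in ("1", "true", "yes", "on")
                elif isinstance(f_.default, int) and not isinstance(f_.default, bool):
                    kwargs[f_.name] = int(raw)
                elif isinstance(f_.default, float):
                    kwargs[f_.name] = float(raw)
                else:
                    kwargs[f_.name] = raw
        return cls(**kwargs)


@dataclass
class PipelineResult:
    summaries: pd.DataFrame          # one MigrationSummary row per turtle
    segments: pd.DataFrame           # phase boundaries per turtle
    steps: pd.DataFrame              # per-6h-step decomposition rows (all turtles)
    partitions: pd.DataFrame         # one DriftPartition row per turtle
    group: dict                      # group-level statistics
    exclusions: pd.DataFrame         # turtle_id, stage, reason

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.summaries.to_csv(outdir / "migration_summaries.csv", index=False)
        self.segments.to_csv(outdir / "track_segments.csv", index=False)
        self.steps.to_csv(outdir / "step_decomposition.csv", index=False)
        self.partitions.to_csv(outdir / "drift_partitions.csv", index=False)
        self.exclusions.to_csv(outdir / "exclusions.csv", index=False)
        with open(outdir / "group_statistics.json", "w") as fh:
            json.dump(self.group, fh, indent=2, default=_jsonable)


def _jsonable(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, (np.bool_,)):
        return bool(x)
    if isinstance(x, (pd.Timestamp, np.datetime64)):
        return str(x)
    raise TypeError(f"not JSON-serializable: {type(x)}")


def run_pipeline(
    fixes: pd.DataFrame,
    current: cur.CurrentField | None,
    bathy: bath.BathymetryGrid,
    config: PipelineConfig | None = None,
) -> PipelineResult:
    """Run the full analysis over a multi-turtle fix table.

    ``fixes`` has the raw-track schema (see :mod:`turtlenav.tracks`);
    ``current`` may be None, in which case the decomposition stage is skipped
    for all turtles (reason code ``no_current_field``).
    """
    cfg = config or PipelineConfig()
    beach = GeoPoint.of(cfg.beach_lat, cfg.beach_lon)
    interval = pd.Timedelta(hours=cfg.interp_interval_h)
    max_gap = pd.Timedelta(hours=cfg.max_gap_h)

    summaries, seg_rows, step_frames, part_rows, excl = [], [], [], [], []
    speed_frames: dict[str, pd.DataFrame] = {}

    for tid, group in fixes.groupby("turtle_id", sort=True):
        tid = str(tid)
        track = trk.qc_filter(group.reset_index(drop=True), cfg.min_satellites, cfg.max_residual)
        if len(track) < 2:
            excl.append({"turtle_id": tid, "stage": "qc", "reason": "too_few_fixes_after_qc"})
            continue
        try:
            segments = trk.segment_track(
                track, bathy, beach, cfg.isobath_m, cfg.beach_radius_km,
                cfg.arrival_radius_km, cfg.arrival_min_days,
            )
        except (trk.NoOceanicCrossingError, trk.ArrivalUndetectedError) as e:
            excl.append({"turtle_id": tid, "stage": "segmentation", "reason": type(e).__name__})
            continue
        logger.info(
            "%s: departure %s, oceanic start %s, arrival %s",
            tid, segments.beach_departure_time, segments.oceanic_start_time,
            segments.arrival_time,
        )

        t = pd.to_datetime(track["time"])
        mig = track[
            (t >= segments.beach_departure_time) & (t <= segments.arrival_time)
        ].reset_index(drop=True)
        if len(mig) < 2:
            excl.append({"turtle_id": tid, "stage": "migration", "reason": "no_migration_fixes"})
            continue

        try:
            interp = interpolate_positions(mig, interval, max_gap, cfg.interp_method)
        except Exception as e:  # pragma: no cover - defensive
            excl.append({"turtle_id": tid, "stage": "interpolation", "reason": type(e).__name__})
            continue

        # route metrics: departure direction measured from the island exit
        # (= oceanic start fix), path from raw migration fixes by default
        # the migration path runs from the departure fix to the goal itself
        # (the residency centroid), so straightness = beeline/path stays <= 1
        # even for a near-geodesic track whose last fix stops short of the goal
        path_track = interp if cfg.path_on_interpolated else mig
        path_track = pd.concat(
            [
                path_track[["lat", "lon"]],
                pd.DataFrame({"lat": [segments.goal.lat], "lon": [segments.goal.lon]}),
            ],
            ignore_index=True,
        )
        post_exit = mig[pd.to_datetime(mig["time"]) >= segments.oceanic_start_time]
        from .geodesy import geodesic_distance, path_length

        try:
            dep = met.departure_direction(
                post_exit, segments.oceanic_start_point, cfg.departure_min_travel_km
            )
            gb = initial_bearing(segments.oceanic_start_point, segments.goal)
            summary = met.MigrationSummary(
                turtle_id=tid,
                beeline_km=geodesic_distance(segments.departure_point, segments.goal) / 1e3,
                path_km=path_length(
                    path_track["lat"].to_numpy(), path_track["lon"].to_numpy()
                ) / 1e3,
                straightness=met.straightness_index(
                    path_track, segments.departure_point, segments.goal
                ),
                departure_bearing_deg=dep,
                goal_bearing_deg=gb,
                departure_deviation_deg=met.deviation_from_goal(dep, gb),
            )
        except ValueError as e:
            excl.append({"turtle_id": tid, "stage": "metrics", "reason": str(e)[:60]})
            continue
        row = summary.as_dict()
        row["daily_fix_rate"] = trk.daily_fix_rate(
            mig, (segments.beach_departure_time, segments.arrival_time)
        )
        row["pre_crossing_h"] = trk.pre_crossing_duration(segments)
        try:
            row["departure_h_after_dawn"] = trk.hours_after_nautical_dawn(
                segments.oceanic_start_time, segments.oceanic_start_point
            )
        except Exception:
            row["departure_h_after_dawn"] = np.nan
        summaries.append(row)
        seg_rows.append(
            {
                "turtle_id": tid,
                "beach_departure_time": segments.beach_departure_time,
                "oceanic_start_time": segments.oceanic_start_time,
                "arrival_time": segments.arrival_time,
                "goal_lat": segments.goal.lat,
                "goal_lon": segments.goal.lon,
            }
        )

        # depth-class speeds on the interpolated migration track
        steps = step_velocities(interp)
        if len(steps):
            steps["depth_class"] = bath.classify_depth(steps, bathy, cfg.isobath_m).to_numpy()
            speed_frames[tid] = steps

        if current is None:
            excl.append({"turtle_id": tid, "stage": "decomposition", "reason": "no_current_field"})
            continue
        try:
            part, dec = cur.partition_deviation(
                interp, current, segments, bathy, cfg.isobath_m,
                signed=cfg.signed_partition,
                per_step_goal_bearing=cfg.per_step_goal_bearing,
                time_interp=cfg.time_interp,
            )
        except (cur.NoCurrentDataError,) as e:
            excl.append({"turtle_id": tid, "stage": "decomposition", "reason": "no_current_data"})
            continue
        except ValueError as e:
            excl.append({"turtle_id": tid, "stage": "decomposition", "reason": str(e)[:60]})
            continue
        dec.insert(0, "turtle_id", tid)
        # oceanic steps: both endpoints in deep water (used for speed summaries)
        d0 = bathy.depths(dec["lat"].to_numpy(), dec["lon"].to_numpy())
        dec["deep_step"] = d0 >= cfg.isobath_m
        if len(dec) > 1:
            dec.loc[dec.index[:-1], "deep_step"] &= d0[1:] >= cfg.isobath_m
        # the final step ends at the bank-entry node (shallow by construction)
        dec.loc[dec.index[-1], "deep_step"] = False
        step_frames.append(dec)
        part_rows.append(part.as_dict())

    res = PipelineResult(
        summaries=pd.DataFrame(summaries),
        segments=pd.DataFrame(seg_rows),
        steps=pd.concat(step_frames, ignore_index=True) if step_frames else pd.DataFrame(),
        partitions=pd.DataFrame(part_rows),
        group={},
        exclusions=pd.DataFrame(excl, columns=["turtle_id", "stage", "reason"]),
    )
    res.group = group_statistics(res, speed_frames, cfg)
    return res


def group_statistics(
    res: PipelineResult, speed_frames: dict[str, pd.DataFrame], cfg: PipelineConfig
) -> dict:
    """Group-level statistics recomputable from the per-turtle tables."""
    g: dict = {"config": asdict(cfg), "n_turtles": int(len(res.summaries))}
    s = res.summaries
    if len(s):
        g["straightness"] = {
            "mean": float(s.straightness.mean()),
            "sd": float(s.straightness.std(ddof=1)) if len(s) > 1 else np.nan,
            "min": float(s.straightness.min()),
            "max": float(s.straightness.max()),
            "n_above_0p9": int((s.straightness > 0.9).sum()),
        }
        g["beeline_km"] = {
            "mean": float(s.beeline_km.mean()),
            "min": float(s.beeline_km.min()),
            "max": float(s.beeline_km.max()),
        }
        g["path_km"] = {"mean": float(s.path_km.mean()), "max": float(s.path_km.max())}
        mean_dev, r = met.circular_mean(s.departure_deviation_deg)
        g["departure_deviation_deg"] = {
            "circular_mean": mean_dev,
            "resultant_length": r,
            "min": float(s.departure_deviation_deg.min()),
            "max": float(s.departure_deviation_deg.max()),
        }
        g["daily_fix_rate"] = {
            "mean": float(s.daily_fix_rate.mean()),
            "sd": float(s.daily_fix_rate.std(ddof=1)) if len(s) > 1 else np.nan,
        }
        g["pre_crossing_h"] = {
            "mean": float(s.pre_crossing_h.mean()),
            "min": float(s.pre_crossing_h.min()),
            "max": float(s.pre_crossing_h.max()),
        }
        dawn = s.departure_h_after_dawn.dropna()
        if len(dawn):
            g["departure_h_after_dawn"] = {
                "mean": float(dawn.mean()),
                "min": float(dawn.min()),
                "max": float(dawn.max()),
            }
        try:
            g["straightness_by_distance_class"] = met.straightness_by_distance_class(
                s, cfg.distance_class_km, cfg.welch
            )
        except ValueError:
            g["straightness_by_distance_class"] = None
    if speed_frames:
        sp = bath.speed_by_depth_class(speed_frames)
        g["speed_by_depth_class"] = {
            k: v for k, v in sp.items() if k != "per_turtle"
        }
    st = res.steps
    if len(st):
        oceanic = st[st.get("deep_step", pd.Series(True, index=st.index))]
        per = oceanic.groupby("turtle_id")
        g["current_speed_ms"] = {
            "mean": float(per.current_speed_ms.mean().mean()),
            "sd": float(per.current_speed_ms.mean().std(ddof=1)),
        }
        g["swim_speed_ms"] = {
            "mean": float(per.swim_speed_ms.mean().mean()),
            "sd": float(per.swim_speed_ms.mean().std(ddof=1)),
        }
        # mean current direction over oceanic steps
        ang = np.degrees(
            np.arctan2(oceanic.current_east_ms.mean(), oceanic.current_north_ms.mean())
        )
        g["current_direction_deg"] = float(np.mod(ang, 360.0))
    p = res.partitions
    if len(p):
        g["drift_partition"] = {
            "n": int(len(p)),
            "mean_abs_total_perp_km": float(p.total_perp_km.abs().mean()),
            "n_compensated": int(p.compensated.sum()),
        }
        try:
            g["deviation_regression"] = cur.deviation_regression(p)
        except ValueError:
            g["deviation_regression"] = None
    g["exclusions"] = res.exclusions.to_dict("records")
    return g
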