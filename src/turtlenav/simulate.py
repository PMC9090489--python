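"""Synthetic migrations: a crude-map navigator advected by ocean currents.

The generator emulates the study system end to end so that every pipeline
stage can be tested against known truth: an island origin with a shallow
skirt, elliptical submerged banks delimited by the 200 m isobath, a smooth
southwest-flowing current field, and a behavioural agent that

1. travels slowly along the coast from its nesting beach to an island exit,
2. departs into deep water on a heading equal to the true goal bearing plus a
   persistent perceived-bearing error (von Mises, optionally biased — a crude
   map sense), which relaxes smoothly toward zero over the crossing
   (mid-ocean course corrections),
3. slows and re-orients when it first encounters shallow bank water,
4. switches to correlated-random-walk search once closer to the goal than its
   map resolution, until it hits the goal cell, and
5. finishes with a localized residency epilogue that defines arrival.

Each internal step (default 6 min, far below the 6-h analysis interval so
discretization does not alias the decomposition) displaces the agent by
swim + current. Observations are a Poisson subsample of the truth with
isotropic GPS noise and synthesized Fastloc quality fields.

All randomness flows from one seeded generator per simulation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bathymetry import BathymetryGrid
from .currents import CurrentField
from .geodesy import initial_bearing, geodesic_distance, wrap_bearing, wrap_signed

__all__ = [
    "SimConfig",
    "SimTrack",
    "generate_bathymetry",
    "generate_current_field",
    "simulate_track",
    "observe_fixes",
    "simulate_bundle",
]

M_PER_DEG_LAT = 111194.9  # mean-radius metres per degree of latitude (coarse uses only)

_WGS84_A = 6378137.0
_WGS84_E2 = 1.0 - (1.0 - 1.0 / 298.257223563) ** 2


def meters_per_degree(lat_deg: float) -> tuple[float, float]:
    """WGS-84 metres per degree of latitude and longitude at ``lat_deg``.

    Uses the meridional radius of curvature M and the parallel radius N*cos(lat),
    so that the simulator's local-plane integration is consistent with
    ellipsoidal (Vincenty) distance measurement to well below 0.01%.
    """
    s2 = math.sin(math.radians(lat_deg)) ** 2
    w = math.sqrt(1.0 - _WGS84_E2 * s2)
    m_lat = math.radians(1.0) * _WGS84_A * (1.0 - _WGS84_E2) / (w ** 3)
    m_lon = math.radians(1.0) * _WGS84_A * math.cos(math.radians(lat_deg)) / w
    return m_lat, m_lon


@dataclass
class SimConfig:
    """Parameters of one simulated migration (defaults emulate the study system)."""

    seed: int = 0
    origin: tuple = (-7.48, 72.49)       # nesting beach, SE coast of the island
    island_exit: tuple = (-7.34, 72.41)  # NW departure point
    goal: tuple = (-6.40, 71.90)         # foraging site on the main bank

    swim_speed: float = 0.73             # m/s, oceanic active swimming
    coastal_speed: float = 0.25          # m/s along the coast pre-departure
    heading_kappa: float = 4.0           # von Mises concentration of the perceived goal bearing
    departure_bias_deg: float = -27.1    # mean of the departure bearing error (deg, CCW-negative)
    heading_relax: float = 0.92          # per-reassessment retention of the bearing error
    jitter_kappa: float = 800.0          # per-interval heading jitter concentration (sd ~2 deg):
                                         # observed ocean legs are nearly straight, with course
                                         # corrections coming from gradual error relaxation
    reassess_interval_h: float = 6.0

    map_resolution_km: float = 50.0      # switch to search inside this goal distance
    search_step_km: float = 3.0          # CRW heading persistence distance during search
    search_turn_kappa: float = 3.0       # turn concentration of the deep-water search walk
    search_goal_kappa: float = 1.0       # weak goal bias of the on-bank search walk
    goal_capture_km: float = 2.0

    reorient_on_shallow: bool = True
    shallow_residual: float = 0.2        # bearing-error shrink factor at bank entry
    shallow_speed_factor: float = 0.34   # ~0.22/0.64, the observed shallow/deep speed ratio

    current_mean_speed: float = 0.29     # m/s
    current_mean_direction: float = 227.8  # deg, flowing toward the southwest
    current_noise: float = 0.05          # m/s, smooth perturbation s.d.

    fix_rate_per_day: float = 7.05
    gps_noise_m: float = 30.0
    qc_fail_fraction: float = 0.1

    internal_step_min: float = 6.0
    residency_days: float = 16.0
    max_days: float = 60.0
    start_time: str = "2019-01-01T00:00:00"

    def __post_init__(self) -> None:
        if self.swim_speed <= 0 or self.coastal_speed <= 0 or self.fix_rate_per_day <= 0:
            raise ValueError("speeds and fix rate must be positive")
        if self.heading_kappa < 0 or self.map_resolution_km < 0:
            raise ValueError("kappa and map resolution must be non-negative")


@dataclass
class SimTrack:
    """Simulation truth plus the emitted observations."""

    config: SimConfig
    time: np.ndarray          # datetime64[ns], internal steps
    lat: np.ndarray
    lon: np.ndarray
    swim_east: np.ndarray     # m/s, truth
    swim_north: np.ndarray
    current_east: np.ndarray
    current_north: np.ndarray
    mode: np.ndarray          # 'coastal'|'crossing'|'bank'|'search'|'residency'
    departure_time: pd.Timestamp
    oceanic_start_time: pd.Timestamp | None
    bank_entry_time: pd.Timestamp | None
    arrival_time: pd.Timestamp | None
    departure_error_deg: float
    truncated: bool
    fixes: pd.DataFrame | None = None

    def truth_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.time,
                "lat": self.lat,
                "lon": self.lon,
                "swim_east_ms": self.swim_east,
                "swim_north_ms": self.swim_north,
                "current_east_ms": self.current_east,
                "current_north_ms": self.current_north,
                "mode": self.mode,
            }
        )


# ---------------------------------------------------------------------------
# Environment generators
# ---------------------------------------------------------------------------

DEFAULT_DOMAIN = (-8.5, -4.5, 70.0, 74.0)  # lat_min, lat_max, lon_min, lon_max


def generate_bathymetry(
    island_center: tuple = (-7.42, 72.45),
    island_radius_km: float = 6.0,
    skirt_radius_km: float = 14.0,
    bank_specs: list[dict] | None = None,
    domain: tuple = DEFAULT_DOMAIN,
    resolution_deg: float = 0.02,
    basin_depth_m: float = 3000.0,
) -> BathymetryGrid:
    """Deep basin with an island (land disc + shallow skirt) and elliptical banks.

    Each bank spec is ``{"center": (lat, lon), "semi_lat_deg": a, "semi_lon_deg":
    b, "top_depth_m": d}``; depth rises from the basin to ``top_depth_m`` so
    that the 200 m isobath falls exactly on the specified ellipse (normalized
    radius 1), with a linear ramp shoreward of it.
    """
    if bank_specs is None:
        bank_specs = [
            {"center": (-6.0, 71.6), "semi_lat_deg": 0.95, "semi_lon_deg": 1.05,
             "top_depth_m": 30.0},
        ]
    lat_min, lat_max, lon_min, lon_max = domain
    lat = np.linspace(lat_min, lat_max, int(round((lat_max - lat_min) / resolution_deg)) + 1)
    lon = np.linspace(lon_min, lon_max, int(round((lon_max - lon_min) / resolution_deg)) + 1)
    glon, glat = np.meshgrid(lon, lat)
    depth = np.full(glat.shape, basin_depth_m)

    # banks: piecewise-linear in normalized elliptical radius r —
    # top at r<=0.9, 200 m exactly at r=1, basin depth at r=1.35
    for spec in bank_specs:
        c = spec["center"]
        r = np.hypot((glat - c[0]) / spec["semi_lat_deg"], (glon - c[1]) / spec["semi_lon_deg"])
        top = spec["top_depth_m"]
        d = np.full_like(r, basin_depth_m)
        inner = r <= 0.9
        ramp1 = (r > 0.9) & (r <= 1.0)
        ramp2 = (r > 1.0) & (r <= 1.35)
        d[inner] = top
        d[ramp1] = top + (200.0 - top) * (r[ramp1] - 0.9) / 0.1
        d[ramp2] = 200.0 + (basin_depth_m - 200.0) * (r[ramp2] - 1.0) / 0.35
        depth = np.minimum(depth, d)

    # island: land disc, beach at depth 0 on the rim, skirt ramping to 200 m
    # at skirt_radius then to the basin a bit further out
    m_per_deg_lon = M_PER_DEG_LAT * math.cos(math.radians(island_center[0]))
    r_km = np.hypot((glat - island_center[0]) * M_PER_DEG_LAT,
                    (glon - island_center[1]) * m_per_deg_lon) / 1e3
    d_isl = np.full_like(r_km, np.inf)
    land = r_km <= island_radius_km
    skirt = (r_km > island_radius_km) & (r_km <= skirt_radius_km)
    beyond = (r_km > skirt_radius_km) & (r_km <= skirt_radius_km * 1.6)
    d_isl[land] = -5.0
    d_isl[skirt] = 200.0 * (r_km[skirt] - island_radius_km) / (skirt_radius_km - island_radius_km)
    d_isl[beyond] = 200.0 + (basin_depth_m - 200.0) * (
        (r_km[beyond] - skirt_radius_km) / (0.6 * skirt_radius_km)
    )
    depth = np.where(np.isfinite(d_isl), np.minimum(depth, d_isl), depth)
    return BathymetryGrid(lat, lon, depth)


def _smooth_noise(rng: np.random.Generator, shape: tuple, sigma: tuple) -> np.ndarray:
    """Unit-variance Gaussian-filtered white noise."""
    from scipy.ndimage import gaussian_filter

    w = rng.standard_normal(shape)
    f = gaussian_filter(w, sigma=sigma, mode="nearest")
    sd = f.std()
    return f / sd if sd > 0 else f


def generate_current_field(
    mean_speed: float = 0.29,
    mean_direction: float = 227.8,
    noise: float = 0.05,
    domain: tuple = DEFAULT_DOMAIN,
    resolution_deg: float = 0.08,
    start_time: str = "2019-01-01T00:00:00",
    duration_days: float = 60.0,
    slice_hours: float = 6.0,
    seed: int = 0,
    space_corr_cells: float = 6.0,
    time_corr_slices: float = 4.0,
    bathy: BathymetryGrid | None = None,
    attenuation_depth_m: float = 200.0,
    min_attenuation: float = 0.15,
) -> CurrentField:
    """Mean flow plus smooth spatio-temporally correlated perturbations.

    The default mean vector points toward 227.8 deg (southwest) at 0.29 m/s;
    the perturbation is Gaussian-filtered white noise (correlation scales of a
    few grid cells / slices, i.e. mesoscale and day-scale), scaled to ``noise``
    m/s per component. Bit-reproducible under ``seed``.

    If ``bathy`` is given, velocities are attenuated over shallow water by the
    factor ``clip(depth / attenuation_depth_m, min_attenuation, 1)`` —
    open-ocean flow does not extend unchanged onto a bank shallower than a
    few hundred metres, and without this attenuation a 0.25 m/s shallow-water
    swimmer could never out-swim a 0.29 m/s current to cross the bank.
    """
    lat_min, lat_max, lon_min, lon_max = domain
    lat = np.linspace(lat_min, lat_max, int(round((lat_max - lat_min) / resolution_deg)) + 1)
    lon = np.linspace(lon_min, lon_max, int(round((lon_max - lon_min) / resolution_deg)) + 1)
    t0 = np.datetime64(start_time, "ns")
    nt = int(duration_days * 24 / slice_hours) + 1
    time = t0 + (np.arange(nt) * int(slice_hours * 3600 * 1e9)).astype("timedelta64[ns]")
    th = math.radians(mean_direction)
    u0 = mean_speed * math.sin(th)
    v0 = mean_speed * math.cos(th)
    shape = (nt, len(lat), len(lon))
    rng = np.random.default_rng(seed)
    if noise > 0:
        sig = (time_corr_slices, space_corr_cells, space_corr_cells)
        u = u0 + noise * _smooth_noise(rng, shape, sig)
        v = v0 + noise * _smooth_noise(rng, shape, sig)
    else:
        u = np.full(shape, u0)
        v = np.full(shape, v0)
    if bathy is not None:
        glon, glat = np.meshgrid(lon, lat)
        depth = np.array(
            [bathy.depth_at((la, lo)) for la, lo in zip(glat.ravel(), glon.ravel())]
        ).reshape(glat.shape)
        factor = np.clip(depth / attenuation_depth_m, min_attenuation, 1.0)
        u = u * factor
        v = v * factor
    return CurrentField(time, lat, lon, u, v)


# ---------------------------------------------------------------------------
# Fast regular-grid samplers for the inner integration loop
# ---------------------------------------------------------------------------

class _FastGrid:
    """Bilinear sampler assuming uniform axis spacing (as generated above)."""

    def __init__(self, lat: np.ndarray, lon: np.ndarray, *fields: np.ndarray):
        self.lat0, self.dlat = lat[0], lat[1] - lat[0]
        self.lon0, self.dlon = lon[0], lon[1] - lon[0]
        self.nlat, self.nlon = len(lat), len(lon)
        self.fields = fields

    def sample(self, lat: float, lon: float, tidx: int | None = None):
        fy = (lat - self.lat0) / self.dlat
        fx = (lon - self.lon0) / self.dlon
        i = min(max(int(fy), 0), self.nlat - 2)
        j = min(max(int(fx), 0), self.nlon - 2)
        wy, wx = fy - i, fx - j
        out = []
        for f in self.fields:
            z = f[tidx] if tidx is not None else f
            out.append(
                z[i, j] * (1 - wy) * (1 - wx)
                + z[i, j + 1] * (1 - wy) * wx
                + z[i + 1, j] * wy * (1 - wx)
                + z[i + 1, j + 1] * wy * wx
            )
        return out


def _vm(rng: np.random.Generator, mu_deg: float, kappa: float) -> float:
    """One von Mises draw in degrees (point mass at mu for kappa -> inf)."""
    if kappa <= 0:
        return wrap_signed(math.degrees(rng.uniform(-math.pi, math.pi)) + mu_deg)
    if kappa > 1e6:
        return wrap_signed(mu_deg)
    return wrap_signed(math.degrees(rng.vonmises(math.radians(wrap_signed(mu_deg)), kappa)))


def simulate_track(
    config: SimConfig, current: CurrentField, bathy: BathymetryGrid
) -> SimTrack:
    """Integrate one migration through the given current field and bathymetry."""
    rng = np.random.default_rng(config.seed)
    dt = config.internal_step_min * 60.0
    n_max = int(config.max_days * 86400.0 / dt) + 1
    t0 = np.datetime64(config.start_time, "ns")

    cur_grid = _FastGrid(current.lat, current.lon, current.u, current.v)
    bat_grid = _FastGrid(bathy.lat, bathy.lon, bathy.depth_m)
    cur_t0 = current.time[0].astype("int64")
    cur_dt = (current.time[1] - current.time[0]).astype("int64") if len(current.time) > 1 else 1
    cur_nt = len(current.time)

    lat = np.empty(n_max)
    lon = np.empty(n_max)
    swim_e = np.zeros(n_max)
    swim_n = np.zeros(n_max)
    cur_e = np.zeros(n_max)
    cur_n = np.zeros(n_max)
    mode = np.empty(n_max, dtype=object)

    lat[0], lon[0] = config.origin
    phase = "coastal"
    err = 0.0                    # current perceived-bearing error, deg
    departure_error = math.nan
    heading = math.nan           # search-mode CRW heading
    search_travel = 0.0
    offshore = False             # coastal phase: island exit reached
    reassess_steps = max(1, int(round(config.reassess_interval_h * 3600.0 / dt)))
    # per-internal-step equivalents of the per-interval relaxation and jitter
    relax_step = config.heading_relax ** (1.0 / reassess_steps)
    jitter_sd_deg = (
        math.degrees(1.0 / math.sqrt(config.jitter_kappa)) if config.jitter_kappa > 0 else 0.0
    )
    jitter_step = jitter_sd_deg / math.sqrt(reassess_steps)
    t_ocean = t_bank = t_arrive = None
    truncated = False
    res_end_step = None
    i = 0
    for i in range(n_max - 1):
        la, lo = lat[i], lon[i]
        if not (bat_grid.lat0 <= la <= bat_grid.lat0 + bat_grid.dlat * (bat_grid.nlat - 1)
                and bat_grid.lon0 <= lo <= bat_grid.lon0 + bat_grid.dlon * (bat_grid.nlon - 1)):
            truncated = True
            i -= 1
            break
        t_ns = t0.astype("int64") + int(i * dt * 1e9)
        tidx = min(max(int(round((t_ns - cur_t0) / cur_dt)), 0), cur_nt - 1)
        (depth,) = bat_grid.sample(la, lo)
        u, v = cur_grid.sample(la, lo, tidx)
        shallow = depth < 200.0

        d_goal = geodesic_distance((la, lo), config.goal) / 1e3
        goal_bearing = initial_bearing((la, lo), config.goal) if d_goal > 1e-4 else 0.0

        if phase == "coastal":
            if not shallow:
                phase = "crossing"
                t_ocean = t_ns
                err = _vm(rng, config.departure_bias_deg, config.heading_kappa)
                departure_error = err
            else:
                if not offshore and geodesic_distance((la, lo), config.island_exit) < 1500.0:
                    offshore = True  # exit reached: push off the skirt toward the goal
                if offshore:
                    # migration committed: full swimming speed off the skirt
                    hdg = wrap_bearing(goal_bearing + err)
                    speed = config.swim_speed
                else:
                    hdg = initial_bearing((la, lo), config.island_exit)
                    speed = config.coastal_speed

        if phase == "crossing":
            # The perceived-bearing error relaxes smoothly toward zero (the
            # continuous-time analogue of a per-interval relaxation + jitter,
            # integrated at the internal step): the track curves gently, which
            # is what gradual mid-ocean course corrections look like. The
            # departure bearing is held for two full reassessment intervals
            # first — departures are committed and initial legs straight.
            if t_ocean is not None and t_ns >= t_ocean + 2 * reassess_steps * dt * 1e9:
                err = relax_step * err + jitter_step * rng.standard_normal()
            if shallow:
                phase = "bank"
                t_bank = t_ns
                if config.reorient_on_shallow:
                    err *= config.shallow_residual
            elif config.map_resolution_km > 0 and d_goal <= config.map_resolution_km:
                phase = "search"
                heading = wrap_bearing(goal_bearing + _vm(rng, 0.0, config.search_turn_kappa))
                search_travel = 0.0
            else:
                hdg = wrap_bearing(goal_bearing + err)
                speed = config.swim_speed

        if phase == "bank":
            if d_goal <= config.goal_capture_km:
                phase = "residency"
                t_arrive = t_ns
                res_end_step = i + int(config.residency_days * 86400.0 / dt)
            elif config.map_resolution_km > 0 and d_goal <= config.map_resolution_km:
                phase = "search"
                heading = wrap_bearing(goal_bearing + _vm(rng, 0.0, config.search_turn_kappa))
                search_travel = 0.0
            else:
                err = relax_step * err + jitter_step * rng.standard_normal()
                hdg = wrap_bearing(goal_bearing + err)
                speed = config.swim_speed * (config.shallow_speed_factor if shallow else 1.0)

        if phase == "search":
            # Inside the map-resolution disc the agent cannot refine its goal
            # estimate: it walks. Straying outside the disc re-engages the
            # crude map (steer back toward the goal); on the bank local cues
            # weakly bias the walk toward the familiar foraging area.
            if d_goal <= config.goal_capture_km:
                phase = "residency"
                t_arrive = t_ns
                res_end_step = i + int(config.residency_days * 86400.0 / dt)
            else:
                if d_goal > config.map_resolution_km:
                    heading = goal_bearing
                    search_travel = 0.0
                elif search_travel >= config.search_step_km * 1e3:
                    if shallow:
                        heading = _vm(rng, goal_bearing, config.search_goal_kappa)
                    else:
                        heading = wrap_bearing(
                            heading + _vm(rng, 0.0, config.search_turn_kappa)
                        )
                    search_travel = 0.0
                hdg = heading
                speed = config.swim_speed * (config.shallow_speed_factor if shallow else 1.0)
                search_travel += speed * dt

        if phase == "residency":
            if res_end_step is not None and i >= res_end_step:
                i -= 1
                break
            if d_goal > 3.0:
                hdg = goal_bearing
            else:
                hdg = rng.uniform(0.0, 360.0)
            speed = 0.1

        rad = math.radians(hdg)
        se, sn = speed * math.sin(rad), speed * math.cos(rad)
        swim_e[i], swim_n[i] = se, sn
        cur_e[i], cur_n[i] = u, v
        de = (se + u) * dt
        dn = (sn + v) * dt
        m_lat, m_lon = meters_per_degree(la)
        lat[i + 1] = la + dn / m_lat
        lon[i + 1] = lo + de / m_lon
        mode[i] = phase
    else:
        truncated = truncated or (t_arrive is None)

    n = i + 2
    mode[n - 1] = mode[n - 2] if n >= 2 else "coastal"
    times = t0 + (np.arange(n) * int(dt * 1e9)).astype("timedelta64[ns]")
    if t_arrive is None:
        truncated = True

    def _ts(x):
        return pd.Timestamp(np.datetime64(int(x), "ns")) if x is not None else None

    return SimTrack(
        config=config,
        time=times,
        lat=lat[:n].copy(),
        lon=lon[:n].copy(),
        swim_east=swim_e[:n].copy(),
        swim_north=swim_n[:n].copy(),
        current_east=cur_e[:n].copy(),
        current_north=cur_n[:n].copy(),
        mode=mode[:n].copy(),
        departure_time=pd.Timestamp(t0),
        oceanic_start_time=_ts(t_ocean),
        bank_entry_time=_ts(t_bank),
        arrival_time=_ts(t_arrive),
        departure_error_deg=departure_error,
        truncated=truncated,
    )


def observe_fixes(
    truth: SimTrack,
    fix_rate_per_day: float | None = None,
    gps_noise_m: float | None = None,
    qc_fail_fraction: float | None = None,
    seed: int | None = None,
    turtle_id: str = "sim",
) -> pd.DataFrame:
    """Fastloc-like observation of a true track.

    Fix times are a Poisson process at ``fix_rate_per_day`` over the truth
    span, with one fix pinned at the start (the deployment position report).
    Positions are the linearly interpolated truth plus isotropic Gaussian
    noise of s.d. ``gps_noise_m``; satellite counts and residual errors are
    drawn so that ``qc_fail_fraction`` of fixes violate the quality rule.
    """
    cfg = truth.config
    rate = cfg.fix_rate_per_day if fix_rate_per_day is None else fix_rate_per_day
    noise = cfg.gps_noise_m if gps_noise_m is None else gps_noise_m
    fail = cfg.qc_fail_fraction if qc_fail_fraction is None else qc_fail_fraction
    rng = np.random.default_rng(cfg.seed + 1 if seed is None else seed)

    t_int = truth.time.astype("int64")
    span_s = (t_int[-1] - t_int[0]) / 1e9
    gaps = rng.exponential(86400.0 / rate, size=int(rate * span_s / 86400.0 * 3) + 20)
    offsets = np.concatenate([[0.0], np.cumsum(gaps)])
    offsets = offsets[offsets <= span_s]
    t_fix = t_int[0] + (offsets * 1e9).astype("int64")

    lat = np.interp(t_fix, t_int, truth.lat)
    lon = np.interp(t_fix, t_int, truth.lon)
    if noise > 0:
        dlat = rng.standard_normal(len(t_fix)) * noise / M_PER_DEG_LAT
        dlon = rng.standard_normal(len(t_fix)) * noise / (
            M_PER_DEG_LAT * np.cos(np.radians(lat))
        )
        lat = lat + dlat
        lon = lon + dlon

    n = len(t_fix)
    fails = rng.random(n) < fail
    n_sats = np.where(fails & (rng.random(n) < 0.5), 3, rng.integers(4, 11, size=n))
    residual = rng.uniform(0.0, 34.9, size=n)
    # fixes marked to fail but with enough satellites get a bad residual
    bad_resid = fails & (n_sats >= 4)
    residual[bad_resid] = rng.uniform(35.0, 80.0, size=int(bad_resid.sum()))
    return pd.DataFrame(
        {
            "turtle_id": turtle_id,
            "time": pd.to_datetime(t_fix),
            "lat": lat,
            "lon": lon,
            "n_satellites": n_sats,
            "residual_error": residual,
        }
    )


def simulate_bundle(
    n_turtles: int,
    seed: int = 0,
    config: SimConfig | None = None,
    current: CurrentField | None = None,
    bathy: BathymetryGrid | None = None,
    goal_jitter_deg: float = 0.25,
):
    """Simulate a multi-turtle study bundle sharing one environment.

    Each turtle gets its own seed and a goal jittered (uniformly, within
    ``goal_jitter_deg``) around the template goal but constrained to shallow
    bank water, emulating individually specific foraging sites. Returns
    ``(fixes DataFrame, list[SimTrack], CurrentField, BathymetryGrid)``.
    """
    from dataclasses import replace

    base = config or SimConfig(seed=seed)
    rng = np.random.default_rng(seed)
    if bathy is None:
        bathy = generate_bathymetry()
    if current is None:
        current = generate_current_field(
            mean_speed=base.current_mean_speed,
            mean_direction=base.current_mean_direction,
            noise=base.current_noise,
            duration_days=base.max_days,
            start_time=base.start_time,
            seed=seed + 10_000,
            bathy=bathy,
        )
    fixes_all = []
    truths = []
    for k in range(n_turtles):
        goal = base.goal
        for _ in range(50):
            cand = (
                base.goal[0] + rng.uniform(-goal_jitter_deg, goal_jitter_deg),
                base.goal[1] + rng.uniform(-goal_jitter_deg, goal_jitter_deg),
            )
            if 0.0 < bathy.depth_at(cand) < 150.0:
                goal = cand
                break
        cfg = replace(base, seed=seed + 1000 + k, goal=goal)
        tr = simulate_track(cfg, current, bathy)
        tr.fixes = observe_fixes(tr, turtle_id=f"sim{k:02d}")
        truths.append(tr)
        fixes_all.append(tr.fixes)
    return pd.concat(fixes_all, ignore_index=True), truths, current, bathy
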