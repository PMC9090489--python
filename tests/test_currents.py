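"""Current sampling, swimming-vector recovery and the drift partition."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from turtlenav.currents import (
    CurrentField,
    NoCurrentDataError,
    decompose_track,
    deviation_regression,
    partition_deviation,
    perpendicular_component,
    sample_current,
    swimming_vector,
)
from turtlenav.geodesy import EnuVelocity, GeoPoint, destination, initial_bearing


def _linear_field(nt=4):
    """u = 0.1 + 0.05*(lat + 8), v = -0.2 + 0.03*(lon - 70): analytic bilinear."""
    time = np.datetime64("2019-01-01", "ns") + np.arange(nt) * np.timedelta64(6, "h")
    lat = np.linspace(-8.5, -4.5, 9)
    lon = np.linspace(70.0, 74.0, 11)
    u = np.broadcast_to(0.1 + 0.05 * (lat[:, None] + 8.0), (nt, 9, 11)).copy()
    v = np.broadcast_to(-0.2 + 0.03 * (lon[None, :] - 70.0), (nt, 9, 11)).copy()
    return CurrentField(time, lat, lon, u, v)


class TestSampleCurrent:
    def test_uniform_field(self, uniform_field):
        for p in [(-7.0, 72.0), (-8.4, 70.1), (-4.6, 73.9)]:
            vel = sample_current(uniform_field, p, "2019-01-01 07:00")
            assert vel == pytest.approx((0.2, -0.2))

    def test_grid_node_value(self):
        f = _linear_field()
        vel = sample_current(f, (f.lat[3], f.lon[4]), f.time[1])
        assert vel.east == pytest.approx(0.1 + 0.05 * (f.lat[3] + 8.0), abs=1e-12)
        assert vel.north == pytest.approx(-0.2 + 0.03 * (f.lon[4] - 70.0), abs=1e-12)

    def test_bilinear_matches_closed_form(self):
        f = _linear_field()
        rng = np.random.default_rng(3)
        for _ in range(50):
            lat, lon = rng.uniform(-8.5, -4.5), rng.uniform(70.0, 74.0)
            vel = sample_current(f, (lat, lon), "2019-01-01 03:00")
            assert vel.east == pytest.approx(0.1 + 0.05 * (lat + 8.0), abs=1e-12)
            assert vel.north == pytest.approx(-0.2 + 0.03 * (lon - 70.0), abs=1e-12)

    def test_outside_grid_signals(self, uniform_field):
        with pytest.raises(NoCurrentDataError):
            sample_current(uniform_field, (0.0, 72.0), "2019-01-01 00:00")
        with pytest.raises(NoCurrentDataError):
            sample_current(uniform_field, (-7.0, 72.0), "2030-01-01 00:00")

    def test_masked_neighbours_renormalized(self):
        f = _linear_field()
        f.u[:, 4, 5] = np.nan
        f.v[:, 4, 5] = np.nan
        # query inside the cell whose corner (4,5) is masked
        lat = f.lat[4] + 0.1 * (f.lat[5] - f.lat[4])
        lon = f.lon[5] + 0.1 * (f.lon[6] - f.lon[5])
        vel = sample_current(f, (lat, lon), f.time[0])
        assert np.isfinite(vel.east) and np.isfinite(vel.north)

    def test_all_masked_signals(self):
        f = _linear_field()
        f.u[:, :2, :2] = np.nan
        f.v[:, :2, :2] = np.nan
        p = (f.lat[0] + 1e-3, f.lon[0] + 1e-3)
        with pytest.raises(NoCurrentDataError):
            sample_current(f, p, f.time[0])

    def test_time_nearest_vs_linear(self):
        time = np.datetime64("2019-01-01", "ns") + np.arange(2) * np.timedelta64(6, "h")
        lat = np.linspace(-8.0, -6.0, 3)
        lon = np.linspace(71.0, 73.0, 3)
        u = np.stack([np.zeros((3, 3)), np.ones((3, 3))])
        f = CurrentField(time, lat, lon, u, u.copy())
        p = (-7.0, 72.0)
        near = sample_current(f, p, "2019-01-01 02:00", time_interp="nearest")
        lin = sample_current(f, p, "2019-01-01 03:00", time_interp="linear")
        assert near.east == 0.0
        assert lin.east == pytest.approx(0.5)


class TestSwimmingVector:
    def test_zero_current_identity(self):
        g = EnuVelocity(0.3, -0.6)
        assert swimming_vector(g, EnuVelocity(0.0, 0.0)) == g

    def test_printed_mean_speed_construction(self):
        swim = swimming_vector(EnuVelocity(0.0, 0.5), EnuVelocity(0.0, -0.23))
        assert swim == pytest.approx((0.0, 0.73))

    @given(
        ge=st.floats(-2, 2), gn=st.floats(-2, 2), ce=st.floats(-2, 2), cn=st.floats(-2, 2)
    )
    @settings(max_examples=100, deadline=None)
    def test_inverse_identity(self, ge, gn, ce, cn):
        g, c = EnuVelocity(ge, gn), EnuVelocity(ce, cn)
        s = swimming_vector(g, c)
        back = EnuVelocity(g.east - s.east, g.north - s.north)
        assert back.east == pytest.approx(c.east, abs=1e-12)
        assert back.north == pytest.approx(c.north, abs=1e-12)


class TestPerpendicular:
    def test_parallel_is_zero(self):
        v = EnuVelocity(math.sin(math.radians(30.0)), math.cos(math.radians(30.0)))
        assert perpendicular_component(v, 30.0, 21600.0) == pytest.approx(0.0, abs=1e-12)

    def test_westward_of_north_beeline_positive(self):
        # due-north beeline, 0.1 m/s westward flow, 6 h -> +2.16 km (left)
        out = perpendicular_component(EnuVelocity(-0.1, 0.0), 0.0, 21600.0)
        assert out == pytest.approx(2.16, abs=1e-12)

    def test_matches_rotation_oracle(self):
        rng = np.random.default_rng(17)
        for _ in range(100):
            v = EnuVelocity(rng.normal(), rng.normal())
            bb = rng.uniform(0, 360)
            dt = rng.uniform(1, 1e5)
            # oracle: rotate ENU into (along, left) frame with a rotation matrix
            th = math.radians(bb)
            rot = np.array(
                [[math.sin(th), math.cos(th)], [-math.cos(th), math.sin(th)]]
            )
            along, left = rot @ np.array([v.east, v.north])
            assert perpendicular_component(v, bb, dt) == pytest.approx(
                left * dt / 1e3, rel=1e-12, abs=1e-12
            )


class TestDecomposition:
    def _interp_track(self, start, bearing, speed, n=8):
        pts = [start]
        cur = start
        for _ in range(n):
            nxt = destination(cur, bearing, speed * 21600.0)
            pts.append((nxt.lat, nxt.lon))
            cur = (nxt.lat, nxt.lon)
        lats, lons = zip(*pts)
        return pd.DataFrame(
            {
                "time": pd.date_range("2019-01-01", periods=n + 1, freq="6h"),
                "lat": lats,
                "lon": lons,
            }
        )

    def test_closure_invariant(self, uniform_field):
        track = self._interp_track((-8.0, 72.5), 320.0, 0.6)
        dec = decompose_track(track, uniform_field, beeline_bearing_deg=320.0)
        resid = dec.perp_ground_km - (dec.perp_current_km + dec.perp_swim_km)
        assert np.abs(resid).max() < 1e-9 * np.abs(dec.perp_ground_km).max().clip(min=1.0)

    def test_zero_current_attributes_all_to_swimming(self):
        time = np.datetime64("2019-01-01", "ns") + np.arange(8) * np.timedelta64(6, "h")
        lat = np.linspace(-8.5, -4.5, 5)
        lon = np.linspace(70.0, 74.0, 5)
        z = np.zeros((8, 5, 5))
        f = CurrentField(time, lat, lon, z, z.copy())
        track = self._interp_track((-8.0, 72.5), 300.0, 0.6)
        dec = decompose_track(track, f, beeline_bearing_deg=330.0)
        assert np.allclose(dec.perp_swim_km, dec.perp_ground_km)
        assert np.allclose(dec.perp_current_km, 0.0)


class TestRegression:
    def test_exact_printed_line(self):
        x = np.array([-20.0, 0.0, 15.0, 40.0, 80.0, 120.0])
        y = 38.4 + 0.781 * x
        parts = pd.DataFrame({"swim_perp_km": x, "total_perp_km": y})
        out = deviation_regression(parts)
        assert out["slope"] == pytest.approx(0.781, abs=1e-12)
        assert out["intercept"] == pytest.approx(38.4, abs=1e-12)
        assert out["r2"] == pytest.approx(1.0, abs=1e-12)

    def test_independent_y_slope_zero(self):
        rng = np.random.default_rng(5)
        x = rng.uniform(-50, 120, 200)
        y = rng.normal(40.0, 5.0, 200)
        out = deviation_regression(pd.DataFrame({"swim_perp_km": x, "total_perp_km": y}))
        assert abs(out["slope"]) < 0.2
        assert out["r2"] < 0.05

    def test_matches_statsmodels_oracle(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(8)
        x = rng.uniform(-50, 120, 15)
        y = 38.4 + 0.781 * x + rng.normal(0, 10, 15)
        out = deviation_regression(pd.DataFrame({"swim_perp_km": x, "total_perp_km": y}))
        fit = sm.OLS(y, sm.add_constant(x)).fit()
        assert out["slope"] == pytest.approx(fit.params[1], abs=1e-9)
        assert out["intercept"] == pytest.approx(fit.params[0], abs=1e-9)
        assert out["r2"] == pytest.approx(fit.rsquared, abs=1e-9)
        assert out["F"] == pytest.approx(fit.fvalue, rel=1e-6)
        assert out["p"] == pytest.approx(fit.f_pvalue, rel=1e-6)

    def test_degenerate_x_signals(self):
        parts = pd.DataFrame({"swim_perp_km": [1.0] * 5, "total_perp_km": range(5)})
        with pytest.raises(ValueError, match="degenerate"):
            deviation_regression(parts)


class TestPartition:
    """Constructed crossings over analytic bathymetry."""

    @staticmethod
    def _wide_ramp():
        """Depth = 100 + 500*(lat + 8): 200 m isobath at lat -7.8, wide coverage."""
        import numpy as np
        from turtlenav.bathymetry import BathymetryGrid

        lat = np.linspace(-10.0, -4.0, 121)
        lon = np.linspace(69.0, 75.0, 61)
        depth = 100.0 + 500.0 * (lat[:, None] + 8.0) + 0.0 * lon[None, :]
        return BathymetryGrid(lat, lon, depth)

    @staticmethod
    def _segments(dep, goal, t0="2019-01-01 00:00"):
        from turtlenav.tracks import TrackSegments

        return TrackSegments(
            "t",
            pd.Timestamp(t0),
            pd.Timestamp(t0),
            pd.Timestamp(t0) + pd.Timedelta(days=30),
            GeoPoint(*dep),
            GeoPoint(*dep),
            GeoPoint(*goal),
        )

    @staticmethod
    def _uniform(u, v, nt=60):
        time = np.datetime64("2019-01-01", "ns") + np.arange(nt) * np.timedelta64(6, "h")
        lat = np.linspace(-9.0, -4.0, 6)
        lon = np.linspace(69.0, 75.0, 7)
        return CurrentField(
            time, lat, lon, np.full((nt, 6, 7), u), np.full((nt, 6, 7), v)
        )

    def _ground_track(self, start, vels_enu, dt=21600.0):
        """Integrate exact ENU velocities into a node table."""
        pts = [start]
        cur = start
        for e, n in vels_enu:
            sp = math.hypot(e, n)
            if sp == 0:
                pts.append(cur)
                continue
            b = math.degrees(math.atan2(e, n)) % 360.0
            nxt = destination(cur, b, sp * dt)
            cur = (nxt.lat, nxt.lon)
            pts.append(cur)
        lats, lons = zip(*pts)
        return pd.DataFrame(
            {
                "time": pd.date_range("2019-01-01", periods=len(pts), freq="6h"),
                "lat": lats,
                "lon": lons,
            }
        )

    def test_zero_current_straight_swim_all_zero(self):
        ramp_grid = self._wide_ramp()
        # ramp grid: shallow south of lat -7.8; goal north, start in deep water
        start, goal = (-7.95, 72.0), (-5.5, 72.0)
        # go north (beeline) at 0.6: perpendicular components all ~0
        f = self._uniform(0.0, 0.0)
        n_steps = 20
        track = self._ground_track(start, [(0.0, 0.6)] * n_steps)
        seg = self._segments(start, goal)
        part, dec = partition_deviation(track, f, seg, ramp_grid)
        assert part.total_perp_km == pytest.approx(0.0, abs=1e-6)
        assert part.current_perp_km == pytest.approx(0.0, abs=1e-6)
        assert part.swim_perp_km == pytest.approx(0.0, abs=1e-6)

    def test_cross_current_attribution(self):
        ramp_grid = self._wide_ramp()
        # shallow water NORTH in this grid? depth = 100+500*(lat+8): deeper north.
        # Build a southward crossing into shallow: start deep (-5.5), goal shallow (-7.9)
        start, goal = (-5.5, 72.0), (-7.9, 72.0)
        u_cur = -0.15  # westward cross-current; beeline is due south
        swim = (0.0, -0.6)
        ground = (swim[0] + u_cur, swim[1])
        track = self._ground_track(start, [ground] * 24)
        f = self._uniform(u_cur, 0.0)
        seg = self._segments(start, goal)
        part, dec = partition_deviation(track, f, seg, ramp_grid)
        # beeline due south: left side is east; westward current -> negative perp
        assert part.current_perp_km < 0
        assert part.swim_perp_km == pytest.approx(0.0, abs=1e-2)
        assert part.total_perp_km == pytest.approx(part.current_perp_km, abs=1e-2)
        assert not part.compensated

    def test_compensating_swimmer(self):
        ramp_grid = self._wide_ramp()
        start, goal = (-5.5, 72.0), (-7.9, 72.0)
        u_cur = -0.15
        swim = (0.10, -0.6)  # aims up-current
        ground = (swim[0] + u_cur, swim[1])
        track = self._ground_track(start, [ground] * 24)
        f = self._uniform(u_cur, 0.0)
        part, _ = partition_deviation(track, f, self._segments(start, goal), ramp_grid)
        assert part.compensated
        assert abs(part.total_perp_km) < abs(part.current_perp_km)

    def test_closure_on_partition(self):
        ramp_grid = self._wide_ramp()
        start, goal = (-5.5, 72.0), (-7.9, 72.0)
        rng = np.random.default_rng(14)
        vels = [(rng.normal(-0.1, 0.1), -0.55) for _ in range(24)]
        track = self._ground_track(start, vels)
        f = self._uniform(-0.1, 0.05)
        part, dec = partition_deviation(track, f, self._segments(start, goal), ramp_grid)
        assert part.total_perp_km == pytest.approx(
            part.current_perp_km + part.swim_perp_km, rel=1e-9, abs=1e-9
        )

    def test_no_shallow_reentry_warns(self, flat_deep_grid):
        start, goal = (-8.0, 72.0), (-5.0, 72.0)
        track = self._ground_track(start, [(0.0, 0.55)] * 20)
        f = self._uniform(0.0, 0.0)
        with pytest.warns(UserWarning, match="never re-enters"):
            partition_deviation(track, f, self._segments(start, goal), flat_deep_grid)

    def test_missing_current_excludes(self):
        ramp_grid = self._wide_ramp()
        start, goal = (-5.5, 72.0), (-7.9, 72.0)
        track = self._ground_track(start, [(0.0, -0.6)] * 24)
        f = self._uniform(0.0, 0.0, nt=2)  # field ends long before the crossing
        with pytest.raises(NoCurrentDataError):
            partition_deviation(track, f, self._segments(start, goal), ramp_grid)
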