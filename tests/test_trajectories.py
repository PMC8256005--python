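import math

import numpy as np
import pandas as pd
import pytest

from cardui.errors import LaunchError, PolarSingularityError
from cardui.kernels import KernelArea, split_subregions
from cardui.trajectories import (
    M_PER_DEG,
    FlightBehavior,
    SuccessCriteria,
    Trajectory,
    classify,
    headwind_feasibility,
    interp_wind,
    local_solar_time,
    run_batch,
    run_trajectory,
    step,
)
from conftest import uniform_atmosphere


class TestLocalSolarTime:
    @pytest.mark.parametrize(
        "lon,offset_minutes",
        [(0.0, 0), (-15.0, -60), (7.5, 30)],
    )
    def test_fifteen_degrees_per_hour(self, lon, offset_minutes):
        utc = pd.Timestamp("2010-01-01 12:00")
        assert local_solar_time(utc, lon) == utc + pd.Timedelta(minutes=offset_minutes)

    def test_longitude_domain_enforced(self):
        with pytest.raises(ValueError):
            local_solar_time(pd.Timestamp("2010-01-01"), 180.0)


class TestInterpWind:
    def test_constant_fields_sample_constant(self, calm_atmosphere):
        t = pd.Timestamp("2010-01-02 12:00")
        for lon, lat, alt in [(0.0, 10.0, 1000.0), (10.0, 30.0, 2000.0)]:
            u, v, temp = interp_wind(calm_atmosphere, lon, lat, alt, t)
            assert (u, v) == (0.0, 0.0)
            assert temp == 20.0

    def test_planar_u_field_interpolates_linearly(self):
        import xarray as xr

        from cardui.grids import GridField
        from cardui.trajectories import AtmosphereFields

        lons = np.arange(-10.0, 11.0, 2.0)
        lats = np.arange(0.0, 21.0, 2.0)
        times = pd.date_range("2010-01-01", periods=24, freq="h")
        lvl = [500.0, 2500.0]
        u = 2.0 + 0.5 * lons[None, None, None, :] * np.ones(
            (len(times), 2, len(lats), 1)
        )
        coords = {"time": times, "level": lvl, "lat": lats, "lon": lons}
        dims = ("time", "level", "lat", "lon")
        mk = lambda a, n: GridField(xr.DataArray(a, coords=coords, dims=dims, name=n))
        fields = AtmosphereFields(
            mk(u, "u"), mk(np.zeros_like(u), "v"), mk(np.full_like(u, 20.0), "T")
        )
        out = interp_wind(fields, 3.0, 10.0, 1500.0, times[3])
        assert out[0] == pytest.approx(3.5, abs=1e-9)

    def test_query_past_last_time_slice_is_domain_exit(self, calm_atmosphere):
        out = interp_wind(
            calm_atmosphere, 0.0, 10.0, 1500.0, pd.Timestamp("2011-06-01")
        )
        assert out is None


class TestStep:
    def test_calm_air_hour_is_21_6_km_due_north(self):
        beh = FlightBehavior()
        lon, lat = step((0.0, 13.0), (0.0, 0.0), beh, 3600.0)
        assert lon == 0.0
        assert lat - 13.0 == pytest.approx(21_600.0 / M_PER_DEG, rel=1e-12)
        assert lat - 13.0 == pytest.approx(0.1943, abs=2e-4)

    def test_opposing_wind_cancels_airspeed(self):
        beh = FlightBehavior()
        lon, lat = step((0.0, 13.0), (0.0, -6.0), beh, 3600.0)
        assert (lon, lat) == (0.0, 13.0)

    def test_equator_symmetry_of_angular_displacement(self):
        beh = FlightBehavior(airspeed=0.0)
        lon, lat = step((0.0, 0.0), (6.0, 6.0), beh, 3600.0)
        assert lon == pytest.approx(lat, rel=1e-12)

    def test_polar_guard(self):
        with pytest.raises(PolarSingularityError):
            step((0.0, 89.5), (0.0, 0.0), FlightBehavior(), 600.0)


class TestRunTrajectory:
    def test_strong_southerly_crosses_on_day_two(self):
        # ground speed 26 m/s; 15 degrees to 28N needs ~17.8 h of flight
        fields = uniform_atmosphere(0.0, 20.0)
        traj = run_trajectory(
            (0.0, 13.0), "2010-01-02", 1500.0, fields,
            FlightBehavior(), SuccessCriteria(28.0),
        )
        assert traj.category == "crossed_sahara"
        assert 11.0 < traj.flight_seconds / 3600.0 <= 22.0

    def test_calm_air_falls_short_of_the_maghreb(self, calm_atmosphere):
        traj = run_trajectory(
            (0.0, 13.0), "2010-01-02", 1500.0, calm_atmosphere,
            FlightBehavior(), SuccessCriteria(28.0),
        )
        # 44 h at 6 m/s is ~950.4 km, ending near 21.5N
        assert traj.category == "failed"
        assert traj.lats[-1] == pytest.approx(13.0 + 950.4e3 / M_PER_DEG, rel=1e-3)

    def test_cold_field_terminates_on_first_step(self):
        fields = uniform_atmosphere(0.0, 10.0, temp=5.0)
        traj = run_trajectory((0.0, 13.0), "2010-01-02", 1500.0, fields)
        assert traj.termination == "cold_terminated"
        assert traj.flight_seconds == 0.0
        assert traj.endpoint == (0.0, 13.0)

    def test_launch_outside_hull_is_an_error(self, calm_atmosphere):
        with pytest.raises(LaunchError):
            run_trajectory((100.0, 13.0), "2010-01-02", 1500.0, calm_atmosphere)

    def test_timestamps_strictly_increasing_and_window_bounded(self, calm_atmosphere):
        beh = FlightBehavior()
        traj = run_trajectory((0.0, 13.0), "2010-01-02", 1500.0, calm_atmosphere, beh)
        t = pd.DatetimeIndex(traj.times)
        assert (np.diff(t.values) > np.timedelta64(0, "s")).all()
        assert traj.flight_seconds / 3600.0 <= beh.max_flight_hours


class TestClassify:
    def _traj(self, lats, lons=None):
        lons = lons or [0.0] * len(lats)
        return Trajectory(
            launch_lon=lons[0], launch_lat=lats[0], launch_date=None, altitude=1500.0,
            times=[], lons=list(lons), lats=list(lats), samples=[],
            termination="completed",
        )

    def test_crossing_latitude(self):
        assert classify(self._traj([13.0, 29.0]), SuccessCriteria(28.0)) == "crossed_sahara"

    def test_southern_launch_reaching_northern_squares(self):
        kern = split_subregions(KernelArea([(0.0, 13.0), (0.0, 16.0)], {}), 15.0)
        crit = SuccessCriteria.from_kernel(kern)
        traj = self._traj([13.5, 16.5], [0.5, 0.5])
        assert classify(traj, crit, "southern") == "reached_north"
        assert classify(traj, crit, "northern") == "failed"

    def test_invariant_to_resampling(self):
        crit = SuccessCriteria(28.0)
        sparse = self._traj([13.0, 20.0, 27.0])
        lats = np.interp(np.linspace(0, 2, 21), [0, 1, 2], [13.0, 20.0, 27.0])
        dense = self._traj(list(lats))
        assert classify(sparse, crit) == classify(dense, crit) == "failed"


class TestRunBatch:
    def test_empty_plan_gives_empty_summary(self, calm_atmosphere):
        from cardui.trajectories import summarize_batch

        batch = run_batch(KernelArea([], {}), [], calm_atmosphere)
        assert batch.empty
        assert summarize_batch(batch).empty

    def test_counting_cells_dates_altitudes(self, calm_atmosphere):
        kern = KernelArea([(0.0, 13.0), (2.0, 13.0)], {})
        dates = pd.date_range("2010-01-02", periods=3, freq="D")
        beh = FlightBehavior(altitudes=(1000.0, 1500.0, 2000.0))
        batch = run_batch(kern, dates, calm_atmosphere, beh, SuccessCriteria(28.0))
        assert len(batch) == 2 * 3 * 3
        counts = batch["category"].value_counts()
        assert counts.sum() == len(batch)  # every trajectory classified


class TestHeadwindFeasibility:
    def test_flight_boundary_layer_arithmetic(self):
        assert headwind_feasibility(6.0, 2.0, 2500.0, 12.0) == 14.5
        assert headwind_feasibility(6.0, 2.0, 2500.0, 24.0) == 7.2
        assert headwind_feasibility(6.0, 0.0, 2500.0, 24.0) == 4.8

    def test_unbeatable_headwind_is_infeasible(self):
        assert math.isinf(headwind_feasibility(6.0, 6.0, 2500.0, 12.0))

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            headwind_feasibility(6.0, -1.0, 2500.0, 12.0)
        with pytest.raises(ValueError):
            headwind_feasibility(6.0, 2.0, 0.0, 12.0)
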