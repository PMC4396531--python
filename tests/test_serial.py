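"""Serial-index autocorrelation, warped axis, latency-decay trajectories."""
import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from nsdyn.errors import ConfigError, DataFormatError
from nsdyn.serial import (
    build_trajectory,
    first_acf_peak,
    plane_center_of_mass,
    serial_autocorrelation,
    warped_time_axis,
)
from nsdyn.types import SerialSeries, Trajectory, empty_response_table


def table_from(lat, dec, censored=None):
    n = len(lat)
    t = empty_response_table(n)
    t["stim_time_s"] = np.arange(n) * 5.0
    t["success"] = True
    t["latency_ms"] = lat
    t["decay_ms"] = dec
    if censored is not None:
        t["censored_decay"] = censored
    return t


class TestAutocorrelation:
    def test_hand_evaluated_reference_value(self):
        acf = serial_autocorrelation(np.array([1.0, 2.0, 3.0, 4.0]), max_lag=1)
        assert acf.rho[1] == pytest.approx(0.25)

    def test_lag_zero_is_exactly_one(self):
        acf = serial_autocorrelation(np.array([3.0, 1.0, 4.0, 1.0, 5.0]), max_lag=2)
        assert acf.rho[0] == 1.0

    @given(st.integers(0, 500))
    def test_bounded_by_one_in_magnitude(self, seed):
        x = np.random.default_rng(seed).standard_normal(40)
        acf = serial_autocorrelation(x, max_lag=30)
        assert np.all(np.abs(acf.rho) <= 1.0 + 1e-12)

    def test_constant_series_is_degenerate(self):
        with pytest.raises(DataFormatError, match="degenerate"):
            serial_autocorrelation(np.full(20, 7.0), max_lag=3)

    def test_series_shorter_than_lags_is_an_error(self):
        with pytest.raises(DataFormatError):
            serial_autocorrelation(np.arange(5.0), max_lag=10)

    def test_exchangeable_series_stays_within_confidence_band(self):
        rng = np.random.default_rng(2024)
        x = rng.permutation(np.arange(400.0))
        acf = serial_autocorrelation(x, max_lag=100)
        frac_inside = np.mean(np.abs(acf.rho[1:]) <= 2 / np.sqrt(400))
        assert frac_inside >= 0.9

    def test_oscillating_series_peak_at_period(self):
        i = np.arange(600)
        x = np.sin(2 * np.pi * i / 60) + 0.1 * np.random.default_rng(5).standard_normal(600)
        acf = serial_autocorrelation(x, max_lag=120)
        assert first_acf_peak(acf) == pytest.approx(60, abs=6)


class TestWarpedAxis:
    def test_regular_responses(self):
        assert warped_time_axis(np.arange(0, 100, 5.0), np.array([10]))[0] == 50.0

    def test_lag_zero_maps_to_zero_seconds(self):
        assert warped_time_axis(np.array([0.0, 4.0, 14.0]), np.array([0]))[0] == 0.0

    def test_irregular_times_use_mean_interval(self):
        assert warped_time_axis(np.array([0.0, 4.0, 14.0]), np.array([1]))[0] == 7.0

    def test_attached_to_acf_from_series(self):
        s = SerialSeries(np.array([1.0, 2.0, 1.5, 2.5]), np.array([0.0, 5.0, 10.0, 15.0]))
        acf = serial_autocorrelation(s, max_lag=2)
        np.testing.assert_allclose(acf.warped_lag_s, [0.0, 5.0, 10.0])


class TestTrajectory:
    def test_constant_points_unchanged_by_smoothing(self):
        t = table_from([100.0] * 20, [200.0] * 20)
        traj = build_trajectory(t, smooth_window=5, segment_len=50)
        np.testing.assert_array_equal(traj.smoothed, traj.points)

    def test_segments_are_consecutive_fifties(self):
        t = table_from(np.linspace(50, 250, 120), np.linspace(100, 400, 120))
        traj = build_trajectory(t, smooth_window=11, segment_len=50)
        assert traj.segments == [(0, 50), (50, 100)]

    def test_smoothing_commutes_with_affine_maps(self):
        rng = np.random.default_rng(8)
        lat = rng.uniform(80, 200, 60)
        dec = rng.uniform(100, 400, 60)
        a = build_trajectory(table_from(lat, dec), smooth_window=7)
        b = build_trajectory(table_from(2 * lat + 5, dec), smooth_window=7)
        np.testing.assert_allclose(b.smoothed[:, 0], 2 * a.smoothed[:, 0] + 5)

    def test_censored_decays_excluded_by_default(self):
        cen = np.zeros(20, bool)
        cen[3] = True
        traj = build_trajectory(table_from([100.0] * 20, [200.0] * 20, cen), 5)
        assert traj.points.shape[0] == 19

    def test_even_smoothing_window_rejected(self):
        with pytest.raises(ConfigError, match="odd"):
            build_trajectory(table_from([100.0] * 20, [200.0] * 20), smooth_window=4)

    def test_fewer_successes_than_window_warns_and_skips_smoothing(self):
        t = table_from([100.0, 120.0, 110.0], [200.0, 190.0, 210.0])
        with pytest.warns(UserWarning, match="smoothing skipped"):
            traj = build_trajectory(t, smooth_window=11)
        np.testing.assert_array_equal(traj.smoothed, traj.points)


class TestCenterOfMass:
    def test_single_point(self):
        traj = Trajectory(np.array([[100.0, 200.0]]), np.array([[100.0, 200.0]]))
        com = plane_center_of_mass(traj)
        assert com == (pytest.approx(100.0), pytest.approx(200.0))

    def test_log_plane_gives_geometric_mean(self):
        pts = np.array([[10.0, 10.0], [1000.0, 1000.0]])
        traj = Trajectory(pts, pts)
        com = plane_center_of_mass(traj, log_plane=True)
        assert com == (pytest.approx(100.0), pytest.approx(100.0))
        lin = plane_center_of_mass(traj, log_plane=False)
        assert lin == (pytest.approx(505.0), pytest.approx(505.0))

    def test_empty_trajectory_is_an_error(self):
        empty = np.empty((0, 2))
        with pytest.raises(DataFormatError):
            plane_center_of_mass(Trajectory(empty, empty))
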