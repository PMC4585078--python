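"""Marker processing: triangulation, angles, filtering, onset, slope."""

import numpy as np
import pytest

from fourlink.errors import (
    InsufficientElevationError,
    NoSwingError,
    ReachabilityError,
)
from fourlink.geometry import joint_and_com_positions
from fourlink.kinematics import (
    Trial,
    detect_swing_onset,
    differentiate,
    filter_and_resample,
    initial_toe_to_barrier_distance,
    segment_angles,
    toe_trajectory_slope,
    trial_to_trajectory,
    triangulate_knee,
)


class TestTriangulation:
    def test_fully_extended_collinear(self):
        knee = triangulate_knee(np.zeros(2), np.array([0.21, 0.0]), 0.10, 0.11)
        assert knee == pytest.approx((0.10, 0.0), abs=1e-7)

    def test_closed_form_intersection(self):
        # t = (d^2 + r1^2 - r2^2)/(2d) = 0.068, h = sqrt(r1^2 - t^2)
        knee = triangulate_knee(np.zeros(2), np.array([0.0, -0.15]), 0.10, 0.11)
        assert knee == pytest.approx((0.0733212, -0.068), abs=1e-6)

    def test_unreachable_raises(self):
        with pytest.raises(ReachabilityError):
            triangulate_knee(np.zeros(2), np.array([0.22, 0.0]), 0.10, 0.11)

    def test_within_tolerance_clamps_to_boundary(self):
        knee = triangulate_knee(np.zeros(2), np.array([0.21 + 5e-7, 0.0]), 0.10, 0.11)
        assert knee == pytest.approx((0.10, 0.0), abs=1e-5)

    def test_anterior_solution_chosen(self, rng):
        # For a vertical hip-ankle line both intersections are x-mirrored;
        # the anatomical (larger-x) one must come back.
        knee = triangulate_knee(np.zeros(2), np.array([0.0, -0.18]), 0.10, 0.11)
        assert knee[0] > 0

    def test_vectorized_matches_scalar(self, rng):
        hips = rng.normal(0, 0.01, (5, 2))
        ankles = hips + np.array([0.05, -0.15])
        series = triangulate_knee(hips, ankles, 0.10, 0.11)
        for k in range(5):
            single = triangulate_knee(hips[k], ankles[k], 0.10, 0.11)
            assert series[k] == pytest.approx(single)


class TestSegmentAngles:
    def test_recovers_generating_angles(self, geometry, rng):
        theta = np.array([-0.9, -2.1, -1.4, -1.2]) + 0.05 * rng.standard_normal((40, 4)).cumsum(0) * 0.01
        joints, _ = joint_and_com_positions(geometry, theta, origin=(0.0, 0.18))
        markers = {
            "iliac_crest": joints[:, 0] + np.array([-0.03, 0.03]),
            "hip": joints[:, 0],
            "ankle": joints[:, 2],
            "paw_joint": joints[:, 3],
            "toe": joints[:, 4],
        }
        trial = Trial("t", markers, 60.0, 0.04)
        recovered = segment_angles(trial, geometry)
        assert np.max(np.abs(recovered - theta)) < 1e-6

    def test_cardinal_directions(self, geometry):
        theta = np.tile([0.0, -np.pi / 2, -np.pi / 4, -np.pi / 4], (3, 1))
        joints, _ = joint_and_com_positions(geometry, theta)
        markers = {
            "iliac_crest": joints[:, 0],
            "hip": joints[:, 0],
            "ankle": joints[:, 2],
            "paw_joint": joints[:, 3],
            "toe": joints[:, 4],
        }
        out = segment_angles(Trial("t", markers, 60.0, 0.04), geometry)
        assert out[0, 0] == pytest.approx(0.0, abs=1e-9)
        assert out[0, 1] == pytest.approx(-np.pi / 2, abs=1e-9)


class TestFilterAndResample:
    def test_dc_gain_unity(self):
        t, out = filter_and_resample(np.full(120, 3.7), 60.0)
        assert out == pytest.approx(3.7, abs=1e-9)
        assert np.allclose(np.diff(t), 0.001)

    @pytest.mark.parametrize(
        "freq, expected_gain, tol",
        [
            (2.0, 1.0 / (1 + (2 / 10) ** 4), 0.01),  # passband, |H|^2 of order-2 butter
            (10.0, 0.5, 0.02),  # -6 dB at cutoff for the zero-phase pass
        ],
    )
    def test_sinusoid_gain(self, freq, expected_gain, tol):
        t_in = np.arange(0, 4.0, 1 / 60)
        x = np.sin(2 * np.pi * freq * t_in)
        t, out = filter_and_resample(x, 60.0)
        middle = out[(t > 1.0) & (t < 3.0)]
        gain = np.max(np.abs(middle))
        assert gain == pytest.approx(expected_gain, rel=tol)

    def test_too_short_series_raises(self):
        with pytest.raises(ValueError):
            filter_and_resample(np.zeros(5), 60.0)


class TestDifferentiate:
    def test_ramp_and_constant(self):
        t = np.arange(100) * 1e-3
        assert differentiate(3 * t, 1e-3) == pytest.approx(3.0)
        assert differentiate(np.full(50, 2.0), 1e-3) == pytest.approx(0.0)

    def test_sinusoid_truncation_bound(self):
        t = np.arange(0, 1, 1e-3)
        x = np.sin(2 * np.pi * 5 * t)
        d = differentiate(x, 1e-3)
        exact = 2 * np.pi * 5 * np.cos(2 * np.pi * 5 * t)
        bound = (2 * np.pi * 5) ** 2 * 1e-3 / 2
        assert np.max(np.abs(d[:-2] - exact[:-2])) <= bound * 1.01

    def test_length_preserved(self):
        assert len(differentiate(np.arange(10.0), 1e-3)) == 10


class TestSwingOnset:
    def test_flat_toe_raises(self):
        path = np.zeros((500, 2))
        with pytest.raises(NoSwingError):
            detect_swing_onset(path)

    def test_linear_rise_crossing_index(self):
        t = np.arange(600) * 1e-3
        y = np.where(t < 0.2, 0.0, 0.1 * (t - 0.2))
        path = np.column_stack([t, y])
        # 0.5 cm reached at t = 0.25 s; the rule requires strictly exceeding
        # the threshold, so the sample sitting exactly on it is not counted
        assert detect_swing_onset(path) == 251

    def test_brief_blip_ignored(self):
        y = np.zeros(600)
        y[300:310] = 0.02  # only 10 ms above threshold
        with pytest.raises(NoSwingError):
            detect_swing_onset(np.column_stack([np.zeros(600), y]))


class TestToeSlope:
    def test_unit_diagonal(self):
        s = np.linspace(0, 0.1, 200)
        assert toe_trajectory_slope(np.column_stack([s, s])) == pytest.approx(1.0, rel=1e-6)

    def test_steep_rise(self):
        y = np.linspace(0, 0.08, 400)
        x = y / 2.0  # dy/dx = 2
        assert toe_trajectory_slope(np.column_stack([x, y])) == pytest.approx(2.0, rel=1e-6)

    def test_parabolic_path(self):
        x = np.linspace(0, 0.12, 2000)
        y = x**2 / 0.1
        expected = 0.02 / (np.sqrt(0.005) - np.sqrt(0.003))  # 1.25483
        assert toe_trajectory_slope(np.column_stack([x, y])) == pytest.approx(expected, rel=1e-3)

    def test_translation_invariance(self):
        x = np.linspace(0, 0.12, 2000)
        y = x**2 / 0.1
        base = toe_trajectory_slope(np.column_stack([x, y]))
        shifted = toe_trajectory_slope(np.column_stack([x + 1.3, y]))
        assert shifted == pytest.approx(base, rel=1e-9)

    def test_insufficient_elevation(self):
        path = np.column_stack([np.linspace(0, 0.1, 100), np.full(100, 0.02)])
        with pytest.raises(InsufficientElevationError):
            toe_trajectory_slope(path)

    def test_backward_motion_flagged_negative(self):
        y = np.linspace(0, 0.08, 300)
        x = -y  # toe retreats while rising
        with pytest.warns(UserWarning):
            assert toe_trajectory_slope(np.column_stack([x, y])) < 0


class TestPipelineRoundTrip:
    def test_noiseless_trial_angle_recovery(self, geometry, noiseless_trial):
        """Markers from known smooth angles reproduce those angles after
        filtering/resampling to within 0.01 rad."""
        trial, truth = noiseless_trial
        traj = trial_to_trajectory(trial, geometry)
        tt = truth.trajectory
        # compare over the swing portion, away from record edges
        n = min(len(tt.theta) - 60, len(traj.theta) - 300 - 60)
        dev = np.abs(traj.theta[300 : 300 + n] - tt.theta[:n])
        assert dev.max() < 0.05
        assert np.median(dev) < 0.01

    def test_onset_near_command_onset(self, geometry, noiseless_trial):
        trial, truth = noiseless_trial
        traj = trial_to_trajectory(trial, geometry)
        onset_s = traj.swing_onset_index * traj.dt
        assert truth.torque_onset < onset_s < truth.torque_onset + 0.2

    def test_initial_distance_close_to_nominal(self, geometry, noiseless_trial):
        trial, truth = noiseless_trial
        measured = initial_toe_to_barrier_distance(trial, geometry)
        # the toe advances a little before the onset threshold trips
        assert 0 < measured <= truth.distance + 1e-6
        assert measured == pytest.approx(truth.distance, abs=0.06)
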