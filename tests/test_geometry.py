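"""Segment parameters, forward kinematics and the 20-equation system."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from fourlink.geometry import (
    JOINT_NAMES,
    LegState,
    SegmentParams,
    assemble_dynamics_system,
    forward_angular_accelerations,
    inverse_joint_torques,
    joint_and_com_positions,
    make_default_cat_leg,
    mechanical_energy,
)

from conftest import random_state


def gravitational_joint_torques(geometry, theta):
    """Independent static oracle: torque at each joint equals the moment of
    all distal segment weight about that joint (anticlockwise positive)."""
    joints, coms = joint_and_com_positions(geometry, theta)
    tau = np.zeros(4)
    for j in range(4):
        for i in range(j, 4):
            tau[j] += geometry.segments[i].mass * geometry.g * (coms[i, 0] - joints[j, 0])
    return tau


class TestDefaults:
    def test_default_masses_and_lengths(self, geometry):
        assert [s.mass for s in geometry.segments] == [0.200, 0.100, 0.040, 0.020]
        assert [s.length for s in geometry.segments] == [0.10, 0.11, 0.05, 0.02]
        assert geometry.total_length == pytest.approx(0.28)

    def test_uniform_rod_inertia(self, geometry):
        thigh = geometry.segments[0]
        assert thigh.a == thigh.length / 2
        assert thigh.moment_of_inertia == pytest.approx(1.6667e-4, rel=1e-4)
        for s in geometry.segments:
            assert s.moment_of_inertia == pytest.approx(s.mass * s.a**2 / 3)

    def test_invalid_segment_rejected(self):
        with pytest.raises(ValueError):
            SegmentParams("thigh", -0.1, 0.1)
        with pytest.raises(ValueError):
            SegmentParams("thigh", 0.1, 0.0)


class TestForwardKinematics:
    @pytest.mark.parametrize(
        "theta, expected_toe",
        [
            (np.zeros(4), (0.28, 0.0)),
            (-np.pi / 2 * np.ones(4), (0.0, -0.28)),
        ],
    )
    def test_toe_tip_cardinal_postures(self, geometry, theta, expected_toe):
        joints, _ = joint_and_com_positions(geometry, theta)
        assert joints[4] == pytest.approx(expected_toe, abs=1e-12)

    def test_chain_summation(self, geometry):
        joints, _ = joint_and_com_positions(geometry, np.array([0.0, -np.pi / 2, 0.0, 0.0]))
        assert joints[2] == pytest.approx((0.10, -0.11), abs=1e-12)

    def test_com_between_joints(self, geometry, rng):
        theta = rng.uniform(-np.pi, np.pi, 4)
        joints, coms = joint_and_com_positions(geometry, theta)
        for i in range(4):
            assert coms[i] == pytest.approx((joints[i] + joints[i + 1]) / 2)


class TestStatics:
    def test_hanging_leg_torque_free(self, geometry):
        state = LegState(-np.pi / 2 * np.ones(4), np.zeros(4))
        sol = inverse_joint_torques(geometry, state, np.zeros(4))
        assert np.max(np.abs(sol.torques)) < 1e-10

    def test_horizontal_leg_hip_torque(self, geometry):
        state = LegState(np.zeros(4), np.zeros(4))
        sol = inverse_joint_torques(geometry, state, np.zeros(4))
        # g * sum(m_i x_com_i) = 9.81 * 0.0403
        assert sol.torques[0] == pytest.approx(0.395343, abs=1e-9)
        assert sol.torques[1] == pytest.approx(0.140283, abs=1e-9)

    def test_static_oracle_random_postures(self, geometry, rng):
        for _ in range(20):
            theta = rng.uniform(-np.pi, np.pi, 4)
            state = LegState(theta, np.zeros(4))
            sol = inverse_joint_torques(geometry, state, np.zeros(4))
            oracle = gravitational_joint_torques(geometry, theta)
            assert np.max(np.abs(sol.torques - oracle)) < 1e-10


class TestDynamicsSystem:
    def test_matrix_is_square_20(self, geometry, rng):
        system = assemble_dynamics_system(
            geometry, random_state(rng), theta_ddot=np.zeros(4)
        )
        assert system.matrix.shape == (20, 20)
        assert len(system.unknown_layout) == 20
        assert system.mode == "inverse"

    def test_requires_exactly_one_known_block(self, geometry, rng):
        state = random_state(rng)
        with pytest.raises(ValueError):
            assemble_dynamics_system(geometry, state)
        with pytest.raises(ValueError):
            assemble_dynamics_system(
                geometry, state, theta_ddot=np.zeros(4), torques=np.zeros(4)
            )

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        theta=arrays(np.float64, 4, elements=st.floats(-np.pi, np.pi)),
        theta_dot=arrays(np.float64, 4, elements=st.floats(-10, 10)),
        thdd=arrays(np.float64, 4, elements=st.floats(-100, 100)),
    )
    def test_duality_property(self, geometry, theta, theta_dot, thdd):
        """For any finite state and target acceleration, the inverse-mode
        torques drive the forward mode back to that acceleration."""
        state = LegState(theta, theta_dot)
        tau = inverse_joint_torques(geometry, state, thdd).torques
        back = forward_angular_accelerations(geometry, state, tau).theta_ddot
        assert np.max(np.abs(back - thdd)) < 1e-9 * max(1.0, np.max(np.abs(thdd)))

    def test_inverse_forward_duality(self, geometry, rng):
        for _ in range(50):
            state = random_state(rng, vel_scale=10.0)
            thdd = rng.uniform(-100, 100, 4)
            tau = inverse_joint_torques(geometry, state, thdd).torques
            back = forward_angular_accelerations(geometry, state, tau).theta_ddot
            assert np.max(np.abs(back - thdd) / np.maximum(np.abs(thdd), 1e-12)) < 1e-9

    def test_whole_body_newton_balance(self, geometry, rng):
        state = random_state(rng)
        thdd = rng.uniform(-50, 50, 4)
        sol = inverse_joint_torques(geometry, state, thdd)
        m = geometry.masses
        total = (m[:, None] * sol.com_accelerations).sum(axis=0)
        weight = np.array([0.0, m.sum() * geometry.g])
        assert np.max(np.abs(sol.joint_forces[0] - total - weight)) < 1e-9

    def test_nonfinite_state_rejected(self, geometry):
        state = LegState(np.array([np.nan, 0, 0, 0]), np.zeros(4))
        with pytest.raises(ValueError):
            assemble_dynamics_system(geometry, state, theta_ddot=np.zeros(4))


class TestEnergy:
    def test_hanging_rest_energy_is_pure_potential(self, geometry):
        state = LegState(-np.pi / 2 * np.ones(4), np.zeros(4))
        _, coms = joint_and_com_positions(geometry, state.theta)
        expected = sum(
            s.mass * geometry.g * coms[i, 1] for i, s in enumerate(geometry.segments)
        )
        assert mechanical_energy(geometry, state) == pytest.approx(expected)

    def test_kinetic_energy_is_nonnegative_addition(self, geometry, rng):
        theta = rng.uniform(-np.pi, np.pi, 4)
        still = mechanical_energy(geometry, LegState(theta, np.zeros(4)))
        moving = mechanical_energy(geometry, LegState(theta, rng.uniform(-3, 3, 4)))
        assert moving >= still
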