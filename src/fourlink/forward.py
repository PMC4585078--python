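"""Forward dynamics: fixed-step RK4 simulation of the swinging leg.

The state is (theta, theta_dot) of the four segments; at each evaluation
the forward-mode 20x20 system yields the angular accelerations produced
by the commanded joint torques.  Torque profiles are zero-order held on
their own 1-ms grid (all four RK4 stages of a step see the torque sample
in effect at the step's start), and torque is zero past the end of the
profile.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .errors import DivergenceError, FourlinkError
from .geometry import (
    LegGeometry,
    LegState,
    forward_angular_accelerations,
    joint_and_com_positions,
)
from .inverse import TorqueProfile
from .kinematics import KinematicTrajectory, toe_trajectory_slope

#: Angular-velocity bound beyond which the simulation is declared divergent.
VELOCITY_BOUND = 1.0e3  # rad/s


@dataclass
class SimulationConfig:
    """Inputs of one forward simulation.

    ``extra_torque``, if given, is a continuous plant augmentation
    ``f(t, state) -> (4,)`` added to the zero-order-held profile torque at
    every integrator stage (the synthetic generator uses it for passive
    joint impedance; the analysis model never does).
    """

    initial_state: LegState
    torque_source: TorqueProfile
    dt: float = 0.001  # s
    duration: float | None = None  # s; defaults to the profile length
    extra_torque: Callable[[float, LegState], np.ndarray] | None = None

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if self.duration is None:
            self.duration = self.torque_source.duration
        if self.duration < self.dt:
            raise ValueError("duration must be at least one step")


def angular_accelerations(
    geometry: LegGeometry, state: LegState, torques: np.ndarray
) -> np.ndarray:
    """Angular accelerations (4,) produced by the given joint torques."""
    return forward_angular_accelerations(geometry, state, torques).theta_ddot


def _held_torque(profile: TorqueProfile, t: float) -> np.ndarray:
    k = int(np.floor(t / profile.dt + 1e-9))
    if k < 0 or k >= len(profile):
        return np.zeros(4)
    return profile.tau[k]


def simulate_swing(
    geometry: LegGeometry,
    config: SimulationConfig,
    origin: tuple[float, float] | None = None,
) -> KinematicTrajectory:
    """Integrate the swing with classical fixed-step RK4.

    Returns a :class:`KinematicTrajectory` sampled at every step (angles,
    velocities, commanded-torque accelerations, and the toe path about
    ``origin``, default ``geometry.hip_origin``).  Raises
    :class:`DivergenceError` if any angular velocity exceeds
    {VELOCITY_BOUND} rad/s.
    """
    if origin is None:
        origin = geometry.hip_origin
    dt = config.dt
    n_steps = int(round(config.duration / dt))
    profile = config.torque_source

    extra = config.extra_torque

    def total_torque(t: float, state: LegState) -> np.ndarray:
        tau = _held_torque(profile, t)
        if extra is not None:
            tau = tau + extra(t, state)
        return tau

    def deriv(t: float, y: np.ndarray) -> np.ndarray:
        state = LegState(y[:4], y[4:])
        thdd = forward_angular_accelerations(geometry, state, total_torque(t, state)).theta_ddot
        return np.concatenate([y[4:], thdd])

    y = np.concatenate([config.initial_state.theta, config.initial_state.theta_dot])
    t_grid = np.arange(n_steps + 1) * dt
    theta = np.empty((n_steps + 1, 4))
    theta_dot = np.empty((n_steps + 1, 4))
    theta_ddot = np.empty((n_steps + 1, 4))
    for k in range(n_steps + 1):
        theta[k] = y[:4]
        theta_dot[k] = y[4:]
        state_k = LegState(y[:4], y[4:])
        theta_ddot[k] = forward_angular_accelerations(
            geometry, state_k, total_torque(t_grid[k], state_k)
        ).theta_ddot
        if np.any(np.abs(y[4:]) > VELOCITY_BOUND):
            raise DivergenceError(
                f"angular velocity exceeded {VELOCITY_BOUND} rad/s", step=k
            )
        if k == n_steps:
            break
        t = t_grid[k]
        k1 = deriv(t, y)
        k2 = deriv(t + dt / 2, y + dt / 2 * k1)
        k3 = deriv(t + dt / 2, y + dt / 2 * k2)
        k4 = deriv(t + dt, y + dt * k3)
        y = y + dt / 6 * (k1 + 2 * k2 + 2 * k3 + k4)

    joints, _ = joint_and_com_positions(geometry, theta, origin=origin)
    return KinematicTrajectory(
        t=t_grid,
        theta=theta,
        theta_dot=theta_dot,
        theta_ddot=theta_ddot,
        toe_path=joints[:, 4],
        swing_onset_index=0,
        dt=dt,
    )


def run_fixed_command_experiment(
    geometry: LegGeometry,
    avg_profile: TorqueProfile,
    avg_initial_velocities: np.ndarray,
    initial_states: list[LegState],
    barrier_x: float,
    origin: tuple[float, float] | None = None,
) -> list[tuple[float, float]]:
    """Drive every initial geometry with one fixed torque command.

    Each simulation starts from a trial's own swing-onset angles but with
    the subset-average initial angular velocities, and is driven by the
    subset-average torque profile for the profile's duration.  Returns a
    ``(initial toe-to-barrier distance, simulated toe-trajectory slope)``
    pair per initial state, in input order.
    """
    avg_initial_velocities = np.asarray(avg_initial_velocities, dtype=float).reshape(4)
    if origin is None:
        origin = geometry.hip_origin
    results: list[tuple[float, float]] = []
    for state in initial_states:
        start = LegState(state.theta.copy(), avg_initial_velocities.copy())
        try:
            traj = simulate_swing(
                geometry,
                SimulationConfig(initial_state=start, torque_source=avg_profile),
                origin=origin,
            )
            distance = float(barrier_x - traj.toe_path[0, 0])
            slope = toe_trajectory_slope(traj.toe_path)
        except FourlinkError:
            # A simulation that diverges or whose toe never climbs through
            # the slope heights yields no usable slope; report NaN so the
            # caller can exclude it without losing the other simulations.
            distance = float(barrier_x - _toe_x(geometry, state, origin))
            slope = float("nan")
        results.append((distance, slope))
    return results


def _toe_x(geometry: LegGeometry, state: LegState, origin) -> float:
    joints, _ = joint_and_com_positions(geometry, state.theta, origin=origin)
    return float(joints[4, 0])
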