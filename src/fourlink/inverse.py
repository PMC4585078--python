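"""Inverse dynamics: joint torque/force time series and summary metrics.

At every 1-ms step of a :class:`~fourlink.kinematics.KinematicTrajectory`
the 20-equation system is solved in inverse mode for the four joint
torques and eight joint interaction forces.  Profiles are aligned at the
detected swing onset; subset averages over the first 200 ms and the mean
torque over the first 30 ms of swing are the summary statistics used by
the distance analyses.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .geometry import JOINT_NAMES, LegGeometry, LegState, inverse_joint_torques
from .kinematics import KinematicTrajectory


@dataclass
class TorqueProfile:
    """Joint torques and interaction forces on a 1-ms grid from swing onset.

    ``tau`` is (T, 4) ordered hip, knee, ankle, paw joint, anticlockwise
    positive; ``forces`` is (T, 4, 2) of (fx, fy) at each joint.
    """

    t: np.ndarray  # (T,), s, 0 at swing onset
    tau: np.ndarray  # (T, 4), N*m
    forces: np.ndarray  # (T, 4, 2), N
    dt: float = 0.001

    def __post_init__(self) -> None:
        if not (len(self.t) == len(self.tau) == len(self.forces)):
            raise ValueError("t, tau and forces must have equal length")
        if not (np.all(np.isfinite(self.tau)) and np.all(np.isfinite(self.forces))):
            raise ValueError("torque profile contains non-finite values")

    def __len__(self) -> int:
        return len(self.t)

    @property
    def duration(self) -> float:
        return len(self) * self.dt


@dataclass
class InitialTorqueMetrics:
    """Mean joint torques over the first ``window`` seconds of swing."""

    hip_tau0: float
    knee_tau0: float
    ankle_tau0: float
    paw_tau0: float
    window: float

    def __post_init__(self) -> None:
        if self.window <= 0:
            raise ValueError("window must be > 0")


def solve_trial_torques(
    geometry: LegGeometry, traj: KinematicTrajectory, from_onset: bool = True
) -> TorqueProfile:
    """Solve the inverse-mode system at every step of a trajectory.

    With ``from_onset`` (default) the returned profile starts at the
    trajectory's detected swing onset with its clock reset to zero,
    matching how profiles are averaged and used to drive simulations.

    Each returned sample is the torque over the step ``[t_k, t_k + dt)``.
    Since profiles are zero-order held when driving the forward model, the
    solve uses the step-midpoint state: the angle midway between
    consecutive samples, the forward-difference velocity (itself a
    midpoint estimate), and the average of the two adjacent
    forward-difference accelerations.  This keeps the inverse solve dual
    to the RK4 + zero-order-hold forward integration instead of
    accumulating an O(dt) phase drift.
    """
    start = traj.swing_onset_index if from_onset else 0
    n = len(traj) - start
    tau = np.empty((n, 4))
    forces = np.empty((n, 4, 2))
    for k in range(n):
        i = start + k
        if i + 1 < len(traj):
            theta = 0.5 * (traj.theta[i] + traj.theta[i + 1])
        else:
            theta = traj.theta[i]
        thdd = 0.5 * (traj.theta_ddot[i - 1] + traj.theta_ddot[i]) if i > 0 else traj.theta_ddot[i]
        state = LegState(theta, traj.theta_dot[i])
        sol = inverse_joint_torques(geometry, state, thdd, step=i)
        tau[k] = sol.torques
        forces[k] = sol.joint_forces
    t = np.arange(n) * traj.dt
    return TorqueProfile(t=t, tau=tau, forces=forces, dt=traj.dt)


def average_torque_profiles(
    profiles: list[TorqueProfile], duration: float = 0.200
) -> TorqueProfile:
    """Sample-wise mean profile over the first ``duration`` seconds.

    Profiles are assumed aligned at swing onset.  Profiles shorter than
    ``duration`` are excluded with a warning; an empty list (or no profile
    long enough) is an error.
    """
    if not profiles:
        raise ValueError("no torque profiles to average")
    dt = profiles[0].dt
    n = int(round(duration / dt))
    usable = [p for p in profiles if len(p) >= n]
    dropped = len(profiles) - len(usable)
    if dropped:
        warnings.warn(f"excluded {dropped} profile(s) shorter than {duration} s")
    if not usable:
        raise ValueError(f"no profile is at least {duration} s long")
    tau = np.mean([p.tau[:n] for p in usable], axis=0)
    forces = np.mean([p.forces[:n] for p in usable], axis=0)
    return TorqueProfile(t=np.arange(n) * dt, tau=tau, forces=forces, dt=dt)


def initial_torques(profile: TorqueProfile, window: float = 0.030) -> InitialTorqueMetrics:
    """Mean torque per joint over the first ``window`` seconds of swing."""
    if window <= 0:
        raise ValueError("window must be > 0")
    n = int(round(window / profile.dt))
    if n > len(profile):
        raise ValueError(f"profile shorter ({profile.duration} s) than window ({window} s)")
    means = profile.tau[:n].mean(axis=0)
    named = dict(zip(JOINT_NAMES, means))
    return InitialTorqueMetrics(
        hip_tau0=float(named["hip"]),
        knee_tau0=float(named["knee"]),
        ankle_tau0=float(named["ankle"]),
        paw_tau0=float(named["paw_joint"]),
        window=window,
    )
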