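"""Planar four-link leg model and its Newton-Euler equation system.

The hind leg is idealised as four uniform rigid rods (thigh, shank, paw,
toe) pinned in a chain at the hip, knee, ankle and paw joints.  The hip is
a fixed inertial origin.  Segment angles are measured anticlockwise from
the positive x-axis at each segment's proximal joint and torques are
positive anticlockwise.

For each segment there are three dynamics equations (planar force balance
and moment balance about the centre of mass) and two kinematic-chain
equations tying the centre-of-mass linear acceleration to the angular
state of all proximal segments.  Together these form one linear system of
20 equations in 20 unknowns, which is solved per time step in one of two
labelings:

* inverse mode -- angular accelerations known; unknowns are the 4 joint
  torques, 8 joint interaction forces and 8 centre-of-mass accelerations;
* forward mode -- joint torques known; unknowns are the 4 angular
  accelerations plus the same forces and accelerations.

Both modes are two column selections of a single assembly routine, which
makes the inverse<->forward duality exact up to the linear solver.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import SingularSystemError

#: Canonical proximal-to-distal segment order.
SEGMENT_NAMES = ("thigh", "shank", "paw", "toe")

#: Joint names, proximal joint of each segment in order.
JOINT_NAMES = ("hip", "knee", "ankle", "paw_joint")

STANDARD_GRAVITY = 9.81  # m/s^2


@dataclass(frozen=True)
class SegmentParams:
    """One uniform rigid rod of the chain.

    The half length ``a`` and the moment of inertia about the centre of
    mass ``I = (1/3) m a**2`` (equivalently ``(1/12) m L**2``) are derived,
    so the uniform-rod invariants hold by construction.
    """

    name: str
    mass: float  # kg
    length: float  # m

    def __post_init__(self) -> None:
        if self.mass <= 0:
            raise ValueError(f"segment {self.name!r}: mass must be > 0")
        if self.length <= 0:
            raise ValueError(f"segment {self.name!r}: length must be > 0")

    @property
    def a(self) -> float:
        """Half length (m): distance from either joint to the centre of mass."""
        return self.length / 2.0

    @property
    def moment_of_inertia(self) -> float:
        """Moment of inertia about the centre of mass (kg m^2)."""
        return self.mass * self.a**2 / 3.0


@dataclass(frozen=True)
class LegGeometry:
    """Fixed mechanical parameters of the four-link leg plus the task frame.

    ``hip_origin`` is the hip position in the ground frame (gravity acts in
    -y; y = 0 is the ground).  ``barrier_x`` and ``barrier_height`` locate
    the (remembered) obstacle in that frame.
    """

    segments: tuple[SegmentParams, SegmentParams, SegmentParams, SegmentParams]
    g: float = STANDARD_GRAVITY
    hip_origin: tuple[float, float] = (0.0, 0.18)
    barrier_x: float = 0.04
    barrier_height: float = 0.065

    def __post_init__(self) -> None:
        if len(self.segments) != 4:
            raise ValueError("exactly four segments (thigh, shank, paw, toe) required")
        if self.g <= 0:
            raise ValueError("g must be stored positive (gravity acts in -y)")

    @property
    def lengths(self) -> np.ndarray:
        return np.array([s.length for s in self.segments])

    @property
    def masses(self) -> np.ndarray:
        return np.array([s.mass for s in self.segments])

    @property
    def half_lengths(self) -> np.ndarray:
        return np.array([s.a for s in self.segments])

    @property
    def inertias(self) -> np.ndarray:
        return np.array([s.moment_of_inertia for s in self.segments])

    @property
    def total_length(self) -> float:
        return float(self.lengths.sum())


@dataclass
class LegState:
    """Instantaneous angular state: 4 segment angles and velocities.

    Angles are anticlockwise from +x at each segment's proximal joint and
    are continuous in time (no wrapping).
    """

    theta: np.ndarray  # (4,), rad
    theta_dot: np.ndarray  # (4,), rad/s

    def __post_init__(self) -> None:
        self.theta = np.asarray(self.theta, dtype=float).reshape(4)
        self.theta_dot = np.asarray(self.theta_dot, dtype=float).reshape(4)

    def copy(self) -> "LegState":
        return LegState(self.theta.copy(), self.theta_dot.copy())


@dataclass
class DynamicsSystem:
    """Assembled 20x20 linear system A x = b in one of the two labelings."""

    matrix: np.ndarray  # (20, 20)
    rhs: np.ndarray  # (20,)
    unknown_layout: tuple[str, ...]
    mode: str  # "inverse" | "forward"


@dataclass
class DynamicsSolution:
    """Solution of one 20x20 solve, split into named blocks.

    ``joint_forces[i]`` is the (fx, fy) interaction force at segment i's
    proximal joint (the distal force on segment i is ``joint_forces[i+1]``,
    identically zero beyond the toe).
    """

    torques: np.ndarray  # (4,) N*m
    theta_ddot: np.ndarray  # (4,) rad/s^2
    joint_forces: np.ndarray  # (4, 2) N
    com_accelerations: np.ndarray  # (4, 2) m/s^2


def make_default_cat_leg(**overrides) -> LegGeometry:
    """Default cat hind-leg geometry.

    Segment masses 200/100/40/20 g and lengths 10/11/5/2 cm for thigh,
    shank, paw and toe; all values stored in SI units.  Keyword overrides
    are applied with :func:`dataclasses.replace`.
    """
    segments = (
        SegmentParams("thigh", 0.200, 0.10),
        SegmentParams("shank", 0.100, 0.11),
        SegmentParams("paw", 0.040, 0.05),
        SegmentParams("toe", 0.020, 0.02),
    )
    geometry = LegGeometry(segments=segments)
    if overrides:
        geometry = replace(geometry, **overrides)
    return geometry


def joint_and_com_positions(
    geometry: LegGeometry, theta: np.ndarray, origin: tuple[float, float] = (0.0, 0.0)
) -> tuple[np.ndarray, np.ndarray]:
    """Forward kinematics of the chain.

    Returns ``(joints, coms)`` where ``joints`` has shape (5, 2) holding
    hip, knee, ankle, paw joint and toe tip, and ``coms`` has shape (4, 2)
    holding the segment centres of mass.  Positions are hip-relative by
    default; pass ``origin=geometry.hip_origin`` for the ground frame.
    ``theta`` may also be an (T, 4) array, in which case the outputs gain a
    leading time axis.
    """
    theta = np.asarray(theta, dtype=float)
    single = theta.ndim == 1
    th = np.atleast_2d(theta)  # (T, 4)
    L = geometry.lengths
    a = geometry.half_lengths
    u = np.stack([np.cos(th), np.sin(th)], axis=-1)  # (T, 4, 2)

    joints = np.zeros((th.shape[0], 5, 2))
    joints[:, 0] = np.asarray(origin, dtype=float)
    for i in range(4):
        joints[:, i + 1] = joints[:, i] + L[i] * u[:, i]
    coms = joints[:, :4] + a[:, None] * u

    if single:
        return joints[0], coms[0]
    return joints, coms


# Column layout of the extended (20 x 24) coefficient matrix over ALL
# quantities; each mode selects 20 of these as unknowns and moves the
# remaining four to the right-hand side.
_TAU = slice(0, 4)  # joint torques tau_1..tau_4
_THDD = slice(4, 8)  # angular accelerations
_F = slice(8, 16)  # fx_1, fy_1, ..., fx_4, fy_4
_ACC = slice(16, 24)  # xdd_1, ydd_1, ..., xdd_4, ydd_4

_FORCE_LABELS = tuple(f"{c}_{j}" for j in JOINT_NAMES for c in ("fx", "fy"))
_ACC_LABELS = tuple(f"{c}_{s}" for s in SEGMENT_NAMES for c in ("xdd", "ydd"))
_TAU_LABELS = tuple(f"tau_{j}" for j in JOINT_NAMES)
_THDD_LABELS = tuple(f"thdd_{s}" for s in SEGMENT_NAMES)


def _extended_system(geometry: LegGeometry, state: LegState) -> tuple[np.ndarray, np.ndarray]:
    """20 equations over the 24 columns [tau, thdd, forces, com accels]."""
    m = geometry.masses
    a = geometry.half_lengths
    L = geometry.lengths
    I = geometry.inertias
    g = geometry.g
    s = np.sin(state.theta)
    c = np.cos(state.theta)
    w2 = state.theta_dot**2

    M = np.zeros((20, 24))
    b = np.zeros(20)
    for i in range(4):
        r = 3 * i
        # Force balance: fx_i - fx_{i+1} = m xdd ; fy_i - fy_{i+1} - m g = m ydd.
        M[r, 8 + 2 * i] = 1.0
        M[r, 16 + 2 * i] = -m[i]
        M[r + 1, 9 + 2 * i] = 1.0
        M[r + 1, 17 + 2 * i] = -m[i]
        b[r + 1] = m[i] * g
        # Moment balance about the COM:
        # tau_i - tau_{i+1} + a s (fx_i + fx_{i+1}) - a c (fy_i + fy_{i+1}) = I thdd.
        M[r + 2, i] = 1.0
        M[r + 2, 8 + 2 * i] = a[i] * s[i]
        M[r + 2, 9 + 2 * i] = -a[i] * c[i]
        M[r + 2, 4 + i] = -I[i]
        if i < 3:
            M[r, 8 + 2 * (i + 1)] = -1.0
            M[r + 1, 9 + 2 * (i + 1)] = -1.0
            M[r + 2, i + 1] = -1.0
            M[r + 2, 8 + 2 * (i + 1)] = a[i] * s[i]
            M[r + 2, 9 + 2 * (i + 1)] = -a[i] * c[i]
        # Chain kinematics: the COM acceleration of segment i follows the
        # angular state of segments 0..i (full length for proximal links,
        # half length for segment i itself).
        kx, ky = 12 + 2 * i, 13 + 2 * i
        M[kx, 16 + 2 * i] = 1.0
        M[ky, 17 + 2 * i] = 1.0
        for j in range(i + 1):
            coef = a[i] if j == i else L[j]
            M[kx, 4 + j] += coef * s[j]
            b[kx] -= coef * c[j] * w2[j]
            M[ky, 4 + j] -= coef * c[j]
            b[ky] -= coef * s[j] * w2[j]
    return M, b


def assemble_dynamics_system(
    geometry: LegGeometry,
    state: LegState,
    *,
    theta_ddot: np.ndarray | None = None,
    torques: np.ndarray | None = None,
) -> DynamicsSystem:
    """Assemble the 20x20 system for one time step.

    Exactly one of ``theta_ddot`` (inverse mode) or ``torques`` (forward
    mode) must be supplied; the given block is moved to the right-hand side
    and the remaining 20 quantities become the unknowns.
    """
    if (theta_ddot is None) == (torques is None):
        raise ValueError("supply exactly one of theta_ddot (inverse) or torques (forward)")
    if not (np.all(np.isfinite(state.theta)) and np.all(np.isfinite(state.theta_dot))):
        raise ValueError("state angles/velocities must be finite")

    M, b = _extended_system(geometry, state)
    if theta_ddot is not None:
        known = np.asarray(theta_ddot, dtype=float).reshape(4)
        b = b - M[:, _THDD] @ known
        cols = np.r_[0:4, 8:24]
        layout = _TAU_LABELS + _FORCE_LABELS + _ACC_LABELS
        mode = "inverse"
    else:
        known = np.asarray(torques, dtype=float).reshape(4)
        b = b - M[:, _TAU] @ known
        cols = np.r_[4:24]
        layout = _THDD_LABELS + _FORCE_LABELS + _ACC_LABELS
        mode = "forward"
    return DynamicsSystem(matrix=M[:, cols], rhs=b, unknown_layout=layout, mode=mode)


def solve_dynamics(
    system: DynamicsSystem,
    *,
    theta_ddot: np.ndarray | None = None,
    torques: np.ndarray | None = None,
    step: int | None = None,
) -> DynamicsSolution:
    """Solve an assembled system, filling in the known block of the solution."""
    try:
        x = np.linalg.solve(system.matrix, system.rhs)
    except np.linalg.LinAlgError as exc:
        raise SingularSystemError(f"singular {system.mode}-mode system: {exc}", step=step) from exc
    head = x[:4]
    forces = x[4:12].reshape(4, 2)
    com_acc = x[12:20].reshape(4, 2)
    if system.mode == "inverse":
        return DynamicsSolution(
            torques=head,
            theta_ddot=np.asarray(theta_ddot, dtype=float).reshape(4),
            joint_forces=forces,
            com_accelerations=com_acc,
        )
    return DynamicsSolution(
        torques=np.asarray(torques, dtype=float).reshape(4),
        theta_ddot=head,
        joint_forces=forces,
        com_accelerations=com_acc,
    )


def inverse_joint_torques(
    geometry: LegGeometry, state: LegState, theta_ddot: np.ndarray, step: int | None = None
) -> DynamicsSolution:
    """Joint torques and interaction forces producing the given accelerations."""
    system = assemble_dynamics_system(geometry, state, theta_ddot=theta_ddot)
    return solve_dynamics(system, theta_ddot=theta_ddot, step=step)


def forward_angular_accelerations(
    geometry: LegGeometry, state: LegState, torques: np.ndarray, step: int | None = None
) -> DynamicsSolution:
    """Angular accelerations produced by the given joint torques."""
    system = assemble_dynamics_system(geometry, state, torques=torques)
    return solve_dynamics(system, torques=torques, step=step)


def mechanical_energy(geometry: LegGeometry, state: LegState) -> float:
    """Total mechanical energy (J), with potential energy zero at hip height.

    Kinetic energy sums translational COM terms and rotational terms about
    each COM; potential energy uses hip-relative COM heights, so the value
    is frame-consistent for conservation checks.
    """
    L = geometry.lengths
    a = geometry.half_lengths
    th, thd = state.theta, state.theta_dot
    _, coms = joint_and_com_positions(geometry, th)
    # COM velocity of segment i: sum of proximal-link tip velocities plus its own.
    energy = 0.0
    for i in range(4):
        v = np.zeros(2)
        for j in range(i + 1):
            coef = a[i] if j == i else L[j]
            v += coef * thd[j] * np.array([-np.sin(th[j]), np.cos(th[j])])
        seg = geometry.segments[i]
        energy += 0.5 * seg.mass * float(v @ v)
        energy += 0.5 * seg.moment_of_inertia * thd[i] ** 2
        energy += seg.mass * geometry.g * coms[i, 1]
    return energy
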