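"""Seeded synthetic stepping trials with known ground truth.

No animal recordings ship with this package, so every pipeline stage is
exercised on trials produced here: a standing hind leg, placed so the toe
sits a chosen distance behind the (remembered) barrier, is driven through
a swing by a joint-torque command and sampled exactly as a motion-capture
system would see it (markers at 60 Hz with Gaussian noise, EMG at 1 kHz).

The command has two parts, both zero-order-held on a 1-ms grid:

* a **base command**, identical for every trial: the static
  anti-gravity torque of one fixed reference stance (the most crouched,
  near-barrier posture) plus smooth plateau flexion pulses at the hip and
  ankle.  Because the command does not depend on the trial's distance,
  every kinematic difference across distances at zero modulation is
  purely mechanical: crouched legs, which the baseline supports almost
  exactly, lift steeply on the spot, while extended legs, for which the
  same baseline over-supports the hip, sweep forward in a low arc;
* a **knee modulation pulse**, a raised-cosine-edged flexion plateau whose
  amplitude grows linearly as the toe starts closer to the barrier
  (``knee_modulation_gain``, N*m per metre of proximity) -- the "neural"
  contribution.  It starts shortly after the torque onset and its
  plateau spans the whole range of swing-onset times the cohort
  produces, so the initial-torque window always samples it at full
  amplitude.

Knee-flexor EMG (ST, Sart_m) amplitude is proportional to the modulated
knee drive; hip-flexor EMG (IP) is distance-independent.

The simulated plant additionally has small passive viscous damping at the
ankle and paw joints (the light distal rods would otherwise ring at their
undamped natural frequencies, which real paws, with tissue and muscle
impedance, do not) and releases the posture-specific standing hold over a
short ramp so the command takes over without a step discontinuity.  All
randomness flows from the single spec seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline

from .emg import EMGTrace
from .errors import PostureError
from .forward import SimulationConfig, simulate_swing
from .geometry import (
    LegGeometry,
    LegState,
    inverse_joint_torques,
    joint_and_com_positions,
)
from .inverse import TorqueProfile
from .kinematics import KinematicTrajectory, Trial

#: EMG scale: arbitrary units of carrier amplitude per N*m of knee drive.
EMG_GAIN_AU_PER_NM = 10.0
#: Nominal knee drive at zero modulation, used only to give the flexor EMG
#: a nonzero baseline amplitude (N*m equivalent).
EMG_BASE_DRIVE_NM = 0.020
EMG_SAMPLE_RATE = 1000.0  # Hz
MARKER_SAMPLE_RATE = 60.0  # Hz
#: Iliac-crest marker offset from the hip marker (m); plumbing only.
ILIAC_OFFSET = np.array([-0.03, 0.03])


def _default_pulses() -> dict:
    """Base-command flexion pulses: per-joint plateau amplitude (N*m,
    anticlockwise positive), cosine edge rise time and total duration (s).
    The knee carries no base pulse; its drive is the modulation."""
    return {
        "hip": {"amplitude": +0.030, "rise": 0.025, "duration": 0.480},
        "knee": {"amplitude": 0.0, "rise": 0.025, "duration": 0.480},
        "ankle": {"amplitude": +0.010, "rise": 0.025, "duration": 0.480},
        "paw_joint": {"amplitude": +0.0005, "rise": 0.025, "duration": 0.480},
    }


@dataclass
class CohortSpec:
    """Conditions of one synthetic cohort.

    ``knee_modulation_gain`` is the extra knee flexion amplitude (N*m) per
    metre of toe proximity to the barrier; 0 switches the neural
    modulation off entirely, making every trial's command bit-identical.
    ``base_profile_params`` holds the base-command pulse shapes;
    ``baseline_distance`` selects the stance whose static anti-gravity
    torque forms the command baseline.
    """

    n_trials: int = 50
    distance_range: tuple[float, float] = (0.05, 0.25)
    knee_modulation_gain: float = 0.08  # N*m per m of proximity
    base_profile_params: dict = field(default_factory=_default_pulses)
    baseline_distance: float = 0.05  # m; stance behind the command baseline
    #: The knee column of the baseline is taken from a slightly less
    #: crouched stance: the resulting mild knee-flexion deficit at far
    #: starts lifts the trailing toe early, while the near stance stays
    #: close to balance.
    knee_baseline_distance: float = 0.10  # m
    knee_pulse_start: float = 0.0  # s after torque onset
    knee_pulse_rise: float = 0.025  # s
    knee_pulse_duration: float = 0.480  # s
    marker_noise_sd: float = 5.0e-4  # m
    emg_noise_sd: float = 0.05  # AU
    seed: int = 0
    # --- plant ---
    pre_swing_duration: float = 0.300  # s of standing before the torque onset
    sim_duration: float = 0.480  # s simulated under the command
    ankle_damping: float = 3.0e-3  # N*m*s/rad, passive, plant only
    paw_damping: float = 1.0e-3  # N*m*s/rad, passive, plant only
    #: Passive elastic stiffness holding the toe aligned with the paw
    #: (N*m/rad about the paw joint); real toes do not swing freely.
    paw_stiffness: float = 0.030
    release_time: float = 0.040  # s over which the standing hold decays

    def __post_init__(self) -> None:
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        lo, hi = self.distance_range
        if not (0.0 < lo < hi < 0.4):
            raise ValueError("distance_range must lie within (0, 0.4) m")


@dataclass
class GroundTruth:
    """What the generator actually did, for recovery tests."""

    distance: float
    initial_state: LegState
    torque_profile: TorqueProfile  # command; t = 0 at torque onset
    torque_onset: float  # s from trial start
    knee_modulation: float  # N*m of extra knee flexion drive (magnitude)
    trajectory: KinematicTrajectory  # noiseless plant motion, from torque onset
    emg_envelopes: dict  # channel -> (T,) AU at EMG_SAMPLE_RATE, trial clock
    emg_expected_magnitudes: dict  # channel -> AU*s over 150 ms from burst onset
    emg_realized_magnitudes: dict  # channel -> AU*s, noise-free rectified signal


# ---------------------------------------------------------------------------
# Posture family


#: Ankle dorsiflexion of the standing posture family, linear in distance:
#: a toe 5 cm from the barrier stands on a tightly folded foot, a toe 25 cm
#: away on a nearly shank-aligned (trailing) foot.
_FOOT_FOLD_INTERCEPT_DEG = 135.0
_FOOT_FOLD_SLOPE_DEG_PER_M = -500.0
_FOOT_FOLD_RANGE_DEG = (10.0, 110.0)


def foot_fold_angle(distance: float) -> float:
    """Ankle dorsiflexion (rad, foot relative to shank) of the posture family."""
    deg = _FOOT_FOLD_INTERCEPT_DEG + _FOOT_FOLD_SLOPE_DEG_PER_M * distance
    return float(np.radians(np.clip(deg, *_FOOT_FOLD_RANGE_DEG)))


def posture_for_toe(
    geometry: LegGeometry, toe_target: np.ndarray, fold_angle: float
) -> np.ndarray:
    """Segment angles (4,) placing the toe tip at ``toe_target`` (ground
    frame) with the foot (paw + toe collinear) dorsiflexed by
    ``fold_angle`` relative to the shank.

    The chain reduces to a two-link problem: the thigh, plus a rigid bent
    distal unit (shank + folded foot).  The knee takes the anterior
    (larger-x) of the two circle intersections.  Raises
    :class:`PostureError` outside the reachable annulus.
    """
    hip = np.asarray(geometry.hip_origin, dtype=float)
    toe = np.asarray(toe_target, dtype=float)
    r1 = geometry.segments[0].length
    shank = geometry.segments[1].length
    foot = geometry.segments[2].length + geometry.segments[3].length
    unit = np.array([shank + foot * np.cos(fold_angle), foot * np.sin(fold_angle)])
    r2 = float(np.linalg.norm(unit))
    psi = float(np.arctan2(unit[1], unit[0]))
    p = toe - hip
    d = float(np.linalg.norm(p))
    if not (abs(r1 - r2) + 1e-12 < d < r1 + r2 - 1e-12):
        raise PostureError(
            f"toe target {toe} at {d:.4f} m from hip outside reachable "
            f"annulus ({abs(r1 - r2):.3f}, {r1 + r2:.3f}) m of the posture family"
        )
    u = p / d
    t = (d**2 + r1**2 - r2**2) / (2.0 * d)
    h = np.sqrt(max(r1**2 - t**2, 0.0))
    n = np.array([-u[1], u[0]])
    plus = t * u + h * n
    minus = t * u - h * n
    knee_rel = plus if plus[0] >= minus[0] else minus  # anterior knee
    theta1 = float(np.arctan2(knee_rel[1], knee_rel[0]))
    distal = p - knee_rel
    theta2 = float(np.arctan2(distal[1], distal[0])) - psi
    theta_foot = theta2 + fold_angle
    return np.array([theta1, theta2, theta_foot, theta_foot])


def make_initial_state(geometry: LegGeometry, distance: float) -> LegState:
    """Standing posture with the toe on the ground ``distance`` metres
    behind the barrier, foot folded per :func:`foot_fold_angle`, zero
    velocities (standing start)."""
    toe = np.array([geometry.barrier_x - distance, 0.0])
    theta = posture_for_toe(geometry, toe, foot_fold_angle(distance))
    return LegState(theta, np.zeros(4))


# ---------------------------------------------------------------------------
# Command profiles


def gravity_baseline(geometry: LegGeometry, state: LegState) -> np.ndarray:
    """Static joint torques holding a posture against gravity (N*m, (4,))."""
    still = LegState(state.theta, np.zeros(4))
    return inverse_joint_torques(geometry, still, np.zeros(4)).torques


def _pulse_shape(t: np.ndarray, rise: float, duration: float) -> np.ndarray:
    """Raised-cosine-edged plateau: cosine rise, hold, cosine fall; 0 outside."""
    t = np.asarray(t, dtype=float)
    y = np.zeros_like(t)
    up = (t >= 0) & (t < rise)
    hold = (t >= rise) & (t <= duration - rise)
    down = (t > duration - rise) & (t <= duration)
    y[up] = 0.5 * (1 - np.cos(np.pi * t[up] / rise))
    y[hold] = 1.0
    y[down] = 0.5 * (1 - np.cos(np.pi * (duration - t[down]) / rise))
    return y


def knee_modulation_amplitude(spec: CohortSpec, distance: float) -> float:
    """Magnitude (N*m) of the knee modulation pulse at a given distance."""
    return spec.knee_modulation_gain * (spec.distance_range[1] - distance)


def command_baseline(spec: CohortSpec, geometry: LegGeometry) -> np.ndarray:
    """Distance-independent anti-gravity baseline of the command (N*m, (4,)).

    Hip, ankle and paw columns hold the most crouched stance
    (``baseline_distance``); the knee column holds the slightly less
    crouched ``knee_baseline_distance`` stance (see :class:`CohortSpec`).
    """
    near = gravity_baseline(geometry, make_initial_state(geometry, spec.baseline_distance))
    knee = gravity_baseline(
        geometry, make_initial_state(geometry, spec.knee_baseline_distance)
    )
    return np.array([near[0], knee[1], near[2], near[3]])


def make_torque_profile(
    spec: CohortSpec, distance: float, geometry: LegGeometry | None = None
) -> TorqueProfile:
    """Joint-torque command for one trial, on a 1-ms grid from torque onset.

    Distance-independent base (the stance anti-gravity baseline plus the
    hip/ankle plateau pulses) plus the knee flexion modulation pulse
    starting at ``knee_pulse_start``.  With ``knee_modulation_gain = 0``
    the returned profile is identical at every distance.
    """
    if geometry is None:
        from .geometry import make_default_cat_leg

        geometry = make_default_cat_leg()
    lo, hi = spec.distance_range
    if not (lo - 1e-9 <= distance <= hi + 1e-9):
        raise ValueError(f"distance {distance} outside cohort range {spec.distance_range}")
    dt = 1e-3
    t = np.arange(0.0, spec.sim_duration, dt)
    tau = np.tile(command_baseline(spec, geometry), (len(t), 1))
    for j, joint in enumerate(("hip", "knee", "ankle", "paw_joint")):
        p = spec.base_profile_params[joint]
        tau[:, j] += p["amplitude"] * _pulse_shape(t, p["rise"], p["duration"])
    amplitude = knee_modulation_amplitude(spec, distance)
    if amplitude != 0.0:
        # Knee flexion is clockwise (negative) for this leg geometry.
        tau[:, 1] -= amplitude * _pulse_shape(
            t - spec.knee_pulse_start, spec.knee_pulse_rise, spec.knee_pulse_duration
        )
    return TorqueProfile(t=t, tau=tau, forces=np.zeros((len(t), 4, 2)), dt=dt)


# ---------------------------------------------------------------------------
# Plant simulation and onset calibration


def _plant_trajectory(
    geometry: LegGeometry, spec: CohortSpec, distance: float, profile: TorqueProfile
) -> tuple[LegState, KinematicTrajectory]:
    """Simulate the plant (command + hold release + distal damping) for one
    trial; returns the standing state and the noiseless motion."""
    state0 = make_initial_state(geometry, distance)
    hold = gravity_baseline(geometry, state0) - profile.tau[0]
    damping = np.array([0.0, 0.0, spec.ankle_damping, spec.paw_damping])
    toe_rest = state0.theta[3] - state0.theta[2]

    def plant_torque(t: float, state: LegState) -> np.ndarray:
        rel_vel = np.diff(state.theta_dot, prepend=0.0)
        tau = -damping * rel_vel
        tau[3] -= spec.paw_stiffness * ((state.theta[3] - state.theta[2]) - toe_rest)
        if t < spec.release_time:
            tau = tau + hold * (1.0 - t / spec.release_time)
        return tau

    traj = simulate_swing(
        geometry,
        SimulationConfig(
            initial_state=state0.copy(), torque_source=profile, extra_torque=plant_torque
        ),
        origin=geometry.hip_origin,
    )
    return state0, traj


# ---------------------------------------------------------------------------
# Trial synthesis


def _sample_markers(
    geometry: LegGeometry,
    state0: LegState,
    traj: KinematicTrajectory,
    spec: CohortSpec,
    rng: np.random.Generator,
) -> dict:
    """Markers at 60 Hz over standing pre-phase + swing, with noise."""
    total = spec.pre_swing_duration + spec.sim_duration
    t60 = np.arange(0.0, total + 1e-9, 1.0 / MARKER_SAMPLE_RATE)
    origin = geometry.hip_origin
    angle_spline = CubicSpline(traj.t + spec.pre_swing_duration, traj.theta, axis=0)
    theta60 = np.empty((len(t60), 4))
    pre = t60 < spec.pre_swing_duration
    theta60[pre] = state0.theta
    t_swing = np.clip(t60[~pre], None, traj.t[-1] + spec.pre_swing_duration)
    theta60[~pre] = angle_spline(t_swing)
    joints, _ = joint_and_com_positions(geometry, theta60, origin=origin)
    markers = {
        "iliac_crest": np.tile(np.asarray(origin) + ILIAC_OFFSET, (len(t60), 1)),
        "hip": np.tile(np.asarray(origin, dtype=float), (len(t60), 1)),
        "ankle": joints[:, 2].copy(),
        "paw_joint": joints[:, 3].copy(),
        "toe": joints[:, 4].copy(),
    }
    if spec.marker_noise_sd > 0:
        for name in markers:
            markers[name] = markers[name] + rng.normal(
                0.0, spec.marker_noise_sd, markers[name].shape
            )
    return markers


def _synthesize_emg(
    spec: CohortSpec, knee_modulation: float, burst_start: float, rng: np.random.Generator
) -> tuple[dict, dict, dict]:
    """EMG channels as envelope-modulated Gaussian carriers plus noise.

    Knee flexors (ST, Sart_m) scale linearly with the modulated knee
    drive; the hip flexor (IP) is distance-independent.  Bursts start at
    ``burst_start`` on the trial clock (aligned with the knee modulation
    pulse).  Returns (traces, true envelopes, expected burst magnitudes):
    the expected rectified mean of a Gaussian carrier of SD ``env`` is
    ``env * sqrt(2/pi)``, integrated over the 150-ms window from burst
    onset.
    """
    total = spec.pre_swing_duration + spec.sim_duration
    n = int(round(total * EMG_SAMPLE_RATE))
    t = np.arange(n) / EMG_SAMPLE_RATE
    knee_drive = EMG_BASE_DRIVE_NM + knee_modulation
    channel_amps = {
        "ST": knee_drive * EMG_GAIN_AU_PER_NM,
        "Sart_m": 0.7 * knee_drive * EMG_GAIN_AU_PER_NM,
        "IP": EMG_BASE_DRIVE_NM * EMG_GAIN_AU_PER_NM,
    }
    traces, envelopes, expected, realized = {}, {}, {}, {}
    for ch, amp in channel_amps.items():
        env = amp * _pulse_shape(t - burst_start, spec.knee_pulse_rise, spec.knee_pulse_duration)
        carrier = rng.standard_normal(n)
        noise = spec.emg_noise_sd * rng.standard_normal(n)
        traces[ch] = EMGTrace(v=env * carrier + noise, sample_rate=EMG_SAMPLE_RATE, channel=ch)
        envelopes[ch] = env
        w0 = int(round(burst_start * EMG_SAMPLE_RATE))
        w1 = w0 + int(round(0.150 * EMG_SAMPLE_RATE))
        expected[ch] = float(
            np.sqrt(2.0 / np.pi) * np.trapezoid(env[w0 : w1 + 1], dx=1.0 / EMG_SAMPLE_RATE)
        )
        # what the rectify-integrate pipeline would see with zero added noise
        realized[ch] = float(
            np.trapezoid(np.abs(env * carrier)[w0 : w1 + 1], dx=1.0 / EMG_SAMPLE_RATE)
        )
    return traces, envelopes, expected, realized


def generate_trial(
    geometry: LegGeometry,
    spec: CohortSpec,
    distance: float,
    rng: np.random.Generator,
    trial_id: str = "synthetic",
    animal_id: str = "synthetic-animal",
) -> tuple[Trial, GroundTruth]:
    """One complete synthetic trial plus its ground truth.

    Forward-simulates the swing from the distance-specific standing
    posture under the command profile (base + knee modulation), with the
    plant-only hold release and distal damping, prepends a static standing
    phase, and samples markers (60 Hz) and EMG (1 kHz).
    """
    profile = make_torque_profile(spec, distance, geometry)
    state0, traj = _plant_trajectory(geometry, spec, distance, profile)
    markers = _sample_markers(geometry, state0, traj, spec, rng)
    knee_mod = knee_modulation_amplitude(spec, distance)
    burst_start = spec.pre_swing_duration + spec.knee_pulse_start
    emg_traces, envelopes, expected, realized = _synthesize_emg(spec, knee_mod, burst_start, rng)
    trial = Trial(
        trial_id=trial_id,
        markers=markers,
        sample_rate=MARKER_SAMPLE_RATE,
        barrier_x=geometry.barrier_x,
        emg=emg_traces,
        meta={"distance": float(distance), "animal_id": animal_id},
    )
    truth = GroundTruth(
        distance=float(distance),
        initial_state=state0,
        torque_profile=profile,
        torque_onset=spec.pre_swing_duration,
        knee_modulation=knee_mod,
        trajectory=traj,
        emg_envelopes=envelopes,
        emg_expected_magnitudes=expected,
        emg_realized_magnitudes=realized,
    )
    return trial, truth


def generate_cohort(
    geometry: LegGeometry, spec: CohortSpec, animal_id: str = "synthetic-animal"
) -> tuple[list[Trial], list[GroundTruth]]:
    """A full cohort: distances uniform over ``spec.distance_range``, one
    trial each, fully reproducible from ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    distances = rng.uniform(*spec.distance_range, size=spec.n_trials)
    trials, truths = [], []
    for i, d in enumerate(distances):
        trial, truth = generate_trial(
            geometry, spec, float(d), rng, trial_id=f"{animal_id}-{i:03d}", animal_id=animal_id
        )
        trials.append(trial)
        truths.append(truth)
    return trials, truths
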