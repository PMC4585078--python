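"""Marker time series to 1-ms segment kinematics and trial-level metrics.

The processing chain mirrors a standard motion-capture workflow for a
sagittal-plane leg: the knee centre is reconstructed by two-circle
triangulation from the hip and ankle markers (skin movement makes a knee
marker unreliable), segment angles are taken as atan2 of each proximal->
distal marker vector and unwrapped in time, low-pass filtered with a
zero-phase 2nd-order Butterworth at 10 Hz, cubic-spline interpolated to a
1-ms grid, and differentiated by forward first differences (applied twice
for angular acceleration).

Trial-level metrics: swing onset (sustained toe elevation above standing
baseline), the toe-trajectory slope (rise/run between 3 cm and 5 cm toe
height), and the initial toe-to-barrier distance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.signal import butter, filtfilt

from .errors import (
    DegenerateMarkerError,
    InsufficientElevationError,
    NoSwingError,
    ReachabilityError,
)
from .geometry import LegGeometry, joint_and_com_positions

MARKER_NAMES = ("iliac_crest", "hip", "ankle", "paw_joint", "toe")

DT_OUT = 0.001  # s, analysis time resolution
ANGLE_CUTOFF_HZ = 10.0


@dataclass
class Trial:
    """One recorded (or synthesised) stepping trial.

    Marker positions are ground-frame metres; ``markers[name]`` has shape
    (T, 2).  The knee is deliberately absent and is reconstructed by
    triangulation.  ``emg`` optionally maps channel labels to
    :class:`fourlink.emg.EMGTrace`.
    """

    trial_id: str
    markers: Mapping[str, np.ndarray]
    sample_rate: float = 60.0
    barrier_x: float = 0.04
    emg: dict | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be > 0")
        lengths = {name: len(np.asarray(m)) for name, m in self.markers.items()}
        if len(set(lengths.values())) > 1:
            raise ValueError(f"marker series lengths differ: {lengths}")
        missing = [m for m in MARKER_NAMES if m not in self.markers]
        if missing:
            raise ValueError(f"missing markers: {missing}")

    @property
    def n_samples(self) -> int:
        return len(np.asarray(self.markers["toe"]))

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sample_rate


@dataclass
class KinematicTrajectory:
    """Segment kinematics on a uniform 1-ms grid plus the toe path."""

    t: np.ndarray  # (T,), s
    theta: np.ndarray  # (T, 4), rad
    theta_dot: np.ndarray  # (T, 4), rad/s
    theta_ddot: np.ndarray  # (T, 4), rad/s^2
    toe_path: np.ndarray  # (T, 2), m, ground frame
    swing_onset_index: int
    dt: float = DT_OUT

    def __len__(self) -> int:
        return len(self.t)


def triangulate_knee(
    hip: np.ndarray,
    ankle: np.ndarray,
    thigh_len: float,
    shank_len: float,
    tol: float = 1e-6,
) -> np.ndarray:
    """Knee centre from two-circle intersection.

    Of the two intersections of the circle of radius ``thigh_len`` about
    the hip with the circle of radius ``shank_len`` about the ankle, the
    anatomical one is returned: the knee lies anterior (larger x, walking
    direction +x) of the hip-ankle line.  A hip-ankle distance outside the
    reachable annulus by more than ``tol`` raises
    :class:`ReachabilityError`; within ``tol`` the collinear boundary
    solution is returned.  Accepts single points (2,) or series (T, 2).
    """
    hip = np.asarray(hip, dtype=float)
    ankle = np.asarray(ankle, dtype=float)
    single = hip.ndim == 1
    h = np.atleast_2d(hip)
    k = np.atleast_2d(ankle)
    d = np.linalg.norm(k - h, axis=1)
    lo, hi = abs(thigh_len - shank_len), thigh_len + shank_len
    if np.any(d > hi + tol) or np.any(d < lo - tol):
        bad = int(np.argmax((d > hi + tol) | (d < lo - tol)))
        raise ReachabilityError(
            f"hip-ankle distance {d[bad]:.6f} m outside reachable annulus "
            f"[{lo:.6f}, {hi:.6f}] m at sample {bad}"
        )
    d = np.clip(d, lo, hi)
    u = (k - h) / d[:, None]
    t = (d**2 + thigh_len**2 - shank_len**2) / (2.0 * d)
    half = np.sqrt(np.maximum(thigh_len**2 - t**2, 0.0))
    n = np.stack([-u[:, 1], u[:, 0]], axis=1)  # left normal of hip->ankle
    plus = h + t[:, None] * u + half[:, None] * n
    minus = h + t[:, None] * u - half[:, None] * n
    # Anterior solution: larger x; fall back to larger y on exact ties.
    pick_plus = (plus[:, 0] > minus[:, 0]) | (
        (plus[:, 0] == minus[:, 0]) & (plus[:, 1] >= minus[:, 1])
    )
    knee = np.where(pick_plus[:, None], plus, minus)
    return knee[0] if single else knee


#: Annulus clamp tolerance used by the trial pipeline: marker noise routinely
#: pushes the hip-ankle distance a little past full knee extension/flexion,
#: and such samples are clamped to the collinear boundary rather than
#: rejected.  (The stricter 1e-6 m default of `triangulate_knee` still guards
#: direct calls against genuinely inconsistent inputs.)
PIPELINE_CLAMP_TOL = 3.0e-3  # m


def segment_angles(
    trial: Trial, geometry: LegGeometry, clamp_tol: float = PIPELINE_CLAMP_TOL
) -> np.ndarray:
    """Segment angles (T, 4) at the capture rate, unwrapped in time.

    The knee is triangulated from the hip and ankle markers using the
    model thigh/shank lengths; each angle is the atan2 direction of the
    segment's proximal->distal vector.
    """
    hip = np.asarray(trial.markers["hip"], dtype=float)
    ankle = np.asarray(trial.markers["ankle"], dtype=float)
    paw_joint = np.asarray(trial.markers["paw_joint"], dtype=float)
    toe = np.asarray(trial.markers["toe"], dtype=float)
    knee = triangulate_knee(
        hip, ankle, geometry.segments[0].length, geometry.segments[1].length, tol=clamp_tol
    )
    angles = np.empty((len(hip), 4))
    for i, (p, q) in enumerate(
        [(hip, knee), (knee, ankle), (ankle, paw_joint), (paw_joint, toe)]
    ):
        v = q - p
        norms = np.linalg.norm(v, axis=1)
        if np.any(norms == 0.0):
            raise DegenerateMarkerError(
                f"zero-length vector for segment {i} at sample {int(np.argmax(norms == 0))}"
            )
        angles[:, i] = np.unwrap(np.arctan2(v[:, 1], v[:, 0]))
    return angles


def filter_and_resample(
    values: np.ndarray,
    sample_rate: float,
    cutoff_hz: float = ANGLE_CUTOFF_HZ,
    dt_out: float = DT_OUT,
) -> tuple[np.ndarray, np.ndarray]:
    """Zero-phase Butterworth low-pass at the capture rate, then cubic
    spline onto a uniform ``dt_out`` grid.

    The 2nd-order filter is applied forward and backward (no phase lag;
    -6 dB rather than -3 dB at the cutoff).  Returns ``(t_out, resampled)``;
    ``values`` may be (T,) or (T, K).
    """
    values = np.asarray(values, dtype=float)
    b, a = butter(2, cutoff_hz, fs=sample_rate)
    padlen = 3 * max(len(a), len(b))
    if values.shape[0] <= padlen:
        raise ValueError(
            f"series of length {values.shape[0]} too short for zero-phase "
            f"filtering (need > {padlen} samples)"
        )
    smoothed = filtfilt(b, a, values, axis=0)
    t_in = np.arange(values.shape[0]) / sample_rate
    t_out = np.arange(0.0, t_in[-1] + 0.5 * dt_out, dt_out)
    t_out = t_out[t_out <= t_in[-1] + 1e-12]
    spline = CubicSpline(t_in, smoothed, axis=0)
    return t_out, spline(t_out)


def differentiate(series: np.ndarray, dt: float = DT_OUT) -> np.ndarray:
    """Forward first-difference derivative, last value repeated.

    ``d[k] = (x[k+1] - x[k]) / dt``; applying this twice yields the
    angular acceleration used by the inverse analysis.
    """
    series = np.asarray(series, dtype=float)
    if series.shape[0] < 2:
        raise ValueError("need at least 2 samples to differentiate")
    d = np.diff(series, axis=0) / dt
    return np.concatenate([d, d[-1:]], axis=0)


def detect_swing_onset(
    toe_path: np.ndarray,
    dt: float = DT_OUT,
    baseline_duration: float = 0.100,
    rise_threshold: float = 0.005,
    persistence: float = 0.050,
) -> int:
    """First sample where toe height exceeds baseline + ``rise_threshold``
    and stays above it for at least ``persistence`` seconds.

    Baseline is the median toe height over the first ``baseline_duration``.
    Raises :class:`NoSwingError` when no sustained elevation exists.
    """
    toe_path = np.asarray(toe_path, dtype=float)
    y = toe_path[:, 1] if toe_path.ndim == 2 else toe_path
    n_base = max(1, int(round(baseline_duration / dt)))
    baseline = float(np.median(y[:n_base]))
    above = y > baseline + rise_threshold
    n_persist = max(1, int(round(persistence / dt)))
    # Candidate onsets: rising edges of the boolean series.
    idx = np.flatnonzero(above & ~np.r_[False, above[:-1]])
    for i in idx:
        if i + n_persist <= len(above) and np.all(above[i : i + n_persist]):
            return int(i)
    raise NoSwingError(
        f"toe never rose {rise_threshold*100:.1f} cm above baseline "
        f"({baseline:.4f} m) for {persistence*1e3:.0f} ms"
    )


def _first_upward_crossing(x: np.ndarray, y: np.ndarray, level: float) -> float:
    """x-position of the first upward crossing of ``level`` by y, linearly
    interpolated between samples; NaN when never crossed."""
    below = y < level
    hits = np.flatnonzero(below[:-1] & (y[1:] >= level))
    if len(hits) == 0:
        return float("nan")
    k = int(hits[0])
    frac = (level - y[k]) / (y[k + 1] - y[k])
    return float(x[k] + frac * (x[k + 1] - x[k]))


def toe_trajectory_slope(
    toe_path: np.ndarray,
    onset_index: int = 0,
    lower: float = 0.03,
    upper: float = 0.05,
) -> float:
    """Rise/run of the toe path between toe heights ``lower`` and ``upper``.

    Heights are ground-frame (y = 0 at the standing toe).  The slope is
    ``(upper - lower)`` divided by the horizontal distance between the
    first upward crossings of the two heights after ``onset_index``; a
    backward-moving toe yields a negative value (with a warning).  Raises
    :class:`InsufficientElevationError` when either height is never
    reached.
    """
    toe_path = np.asarray(toe_path, dtype=float)
    seg = toe_path[onset_index:]
    x, y = seg[:, 0], seg[:, 1]
    x_lo = _first_upward_crossing(x, y, lower)
    x_hi = _first_upward_crossing(x, y, upper)
    if np.isnan(x_lo) or np.isnan(x_hi):
        raise InsufficientElevationError(
            f"toe never ascends through both {lower*100:.0f} cm and {upper*100:.0f} cm"
        )
    run = x_hi - x_lo
    if run <= 0:
        warnings.warn("toe moved backward between slope heights; slope sign flagged")
        if run == 0:
            return float("inf")
    return (upper - lower) / run


def trial_to_trajectory(
    trial: Trial, geometry: LegGeometry, onset_threshold: float = 0.005
) -> KinematicTrajectory:
    """Full per-trial kinematics pipeline.

    Triangulates the knee, computes segment angles at the capture rate,
    filters and resamples them to 1 ms, differentiates twice, rebuilds the
    toe path by forward kinematics about the (fixed) mean hip-marker
    position, and detects swing onset (5 mm of sustained toe elevation;
    configurable, and kept well above the marker-noise floor).
    """
    angles = segment_angles(trial, geometry)
    t, theta = filter_and_resample(angles, trial.sample_rate)
    theta_dot = differentiate(theta)
    theta_ddot = differentiate(theta_dot)
    hip_pos = np.asarray(trial.markers["hip"], dtype=float).mean(axis=0)
    joints, _ = joint_and_com_positions(geometry, theta, origin=tuple(hip_pos))
    toe_path = joints[:, 4]
    onset = detect_swing_onset(toe_path, rise_threshold=onset_threshold)
    return KinematicTrajectory(
        t=t,
        theta=theta,
        theta_dot=theta_dot,
        theta_ddot=theta_ddot,
        toe_path=toe_path,
        swing_onset_index=onset,
    )


def initial_toe_to_barrier_distance(
    trial: Trial, geometry: LegGeometry | None = None, trajectory: KinematicTrajectory | None = None
) -> float:
    """Horizontal toe-to-barrier distance at swing onset (m, positive when
    the toe is behind the barrier).

    Uses a precomputed trajectory when given; otherwise runs the pipeline
    (``geometry`` required).
    """
    if trajectory is None:
        if geometry is None:
            raise ValueError("supply geometry or a precomputed trajectory")
        trajectory = trial_to_trajectory(trial, geometry)
    toe_x = trajectory.toe_path[trajectory.swing_onset_index, 0]
    return float(trial.barrier_x - toe_x)
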