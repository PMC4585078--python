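"""The slope-vs-distance analyses over a set of trials.

For every trial: kinematics -> inverse dynamics -> trial metrics (actual
toe-trajectory slope, initial joint torques, EMG burst magnitudes).  The
torque profiles of the long-distance subset (16-25 cm by default) are
averaged and, together with that subset's average swing-onset angular
velocities, drive one forward simulation per trial from the trial's own
swing-onset geometry.  Ordinary least-squares regressions then relate
actual slope, simulated slope, initial torques and EMG magnitudes to the
initial toe-to-barrier distance, and simulated to actual slope.

If limb mechanics alone shaped the trajectories, the simulated-vs-actual
slope regression would sit on the identity line; a slope below one is the
signature of distance-dependent neural modulation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .emg import burst_magnitude, detect_burst_onset, emg_envelope
from .errors import DegenerateRegressionError, FourlinkError
from .forward import run_fixed_command_experiment
from .geometry import LegGeometry, LegState
from .inverse import TorqueProfile, average_torque_profiles, initial_torques, solve_trial_torques
from .kinematics import Trial, toe_trajectory_slope, trial_to_trajectory

logger = logging.getLogger(__name__)


@dataclass
class TrialMetrics:
    """Per-trial quantities entering the regressions."""

    trial_id: str
    distance: float  # m
    actual_slope: float
    simulated_slope: float | None
    hip_tau0: float
    knee_tau0: float
    ankle_tau0: float
    emg_magnitudes: dict = field(default_factory=dict)


@dataclass
class RegressionResult:
    """OLS line with the two-sided t-test on its slope (n - 2 df)."""

    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int
    slope_stderr: float

    def __post_init__(self) -> None:
        if self.n < 3:
            raise ValueError("regression needs n >= 3")
        if not (-1e-12 <= self.r_squared <= 1 + 1e-12):
            raise ValueError("r_squared outside [0, 1]")

    def slope_ci(self, alpha: float = 0.05) -> tuple[float, float]:
        """Two-sided (1 - alpha) confidence interval for the slope."""
        half = stats.t.ppf(1 - alpha / 2, self.n - 2) * self.slope_stderr
        return (self.slope - half, self.slope + half)


@dataclass
class AnalysisConfig:
    """Knobs of the full analysis (defaults follow the study design)."""

    long_distance_range: tuple[float, float] = (0.16, 0.25)  # m, inclusive
    average_duration: float = 0.200  # s of profile retained for averaging
    initial_torque_window: float = 0.030  # s
    emg_channels: tuple[str, ...] = ("ST", "Sart_m", "IP")


@dataclass
class AnalysisReport:
    """Everything `run_full_analysis` produces."""

    metrics: pd.DataFrame
    regressions: dict  # name -> RegressionResult | None (not estimable)
    excluded: dict  # trial_id -> reason
    subset_size: int
    average_profile: TorqueProfile
    average_initial_velocities: np.ndarray


def select_subset(
    metrics: list, min_distance: float, max_distance: float
) -> list:
    """Items whose ``distance`` lies in [min_distance, max_distance]
    (inclusive at both ends); empty result warrants only a log warning."""
    subset = [m for m in metrics if min_distance <= m.distance <= max_distance]
    if not subset:
        logger.warning(
            "no trials in distance range [%.3f, %.3f] m", min_distance, max_distance
        )
    return subset


def linear_regression(x: np.ndarray, y: np.ndarray) -> RegressionResult:
    """Ordinary least squares of y on x with a slope t-test."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3:
        raise DegenerateRegressionError(f"need n >= 3 points, got {len(x)}")
    if np.ptp(x) == 0.0:
        raise DegenerateRegressionError("regressor is constant")
    if np.ptp(y) == 0.0:
        # a constant response carries no trend: slope 0, R^2 = 0
        return RegressionResult(
            slope=0.0, intercept=float(y[0]), r_squared=0.0, p_value=1.0,
            n=len(x), slope_stderr=0.0,
        )
    fit = stats.linregress(x, y)
    return RegressionResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        p_value=float(fit.pvalue),
        n=len(x),
        slope_stderr=float(fit.stderr),
    )


def _regress_or_none(name: str, x, y, regressions: dict) -> None:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    if keep.sum() < len(x):
        logger.info("regression %s: dropped %d non-finite pair(s)", name, int(len(x) - keep.sum()))
    try:
        regressions[name] = linear_regression(x[keep], y[keep])
    except DegenerateRegressionError as exc:
        logger.warning("regression %s not estimable: %s", name, exc)
        regressions[name] = None


def run_full_analysis(
    trials: list[Trial],
    geometry: LegGeometry,
    config: AnalysisConfig | None = None,
) -> AnalysisReport:
    """Run the complete pipeline over a set of trials.

    Trials failing any stage are logged and excluded (their ids and
    reasons appear in ``report.excluded``).  Regressions that are not
    estimable (constant regressor) are reported as ``None``.
    """
    config = config or AnalysisConfig()
    if len(trials) < 2:
        raise ValueError("need at least 2 trials to analyse")

    rows: list[dict] = []
    profiles: dict[str, TorqueProfile] = {}
    onset_states: dict[str, LegState] = {}
    onset_velocities: dict[str, np.ndarray] = {}
    excluded: dict[str, str] = {}
    for trial in trials:
        try:
            traj = trial_to_trajectory(trial, geometry)
            onset = traj.swing_onset_index
            distance = float(trial.barrier_x - traj.toe_path[onset, 0])
            actual_slope = toe_trajectory_slope(traj.toe_path, onset)
            profile = solve_trial_torques(geometry, traj)
            tau0 = initial_torques(profile, config.initial_torque_window)
            emg_mags: dict[str, float] = {}
            for ch in config.emg_channels:
                if trial.emg and ch in trial.emg:
                    trace = trial.emg[ch]
                    env = emg_envelope(trace)
                    burst_t = detect_burst_onset(env, trace.sample_rate)
                    emg_mags[ch] = burst_magnitude(env, burst_t, trace.sample_rate)
        except FourlinkError as exc:
            logger.warning("trial %s excluded: %s", trial.trial_id, exc)
            excluded[trial.trial_id] = str(exc)
            continue
        profiles[trial.trial_id] = profile
        onset_states[trial.trial_id] = LegState(traj.theta[onset], traj.theta_dot[onset])
        onset_velocities[trial.trial_id] = traj.theta_dot[onset]
        rows.append(
            {
                "trial_id": trial.trial_id,
                "distance": distance,
                "actual_slope": actual_slope,
                "hip_tau0": tau0.hip_tau0,
                "knee_tau0": tau0.knee_tau0,
                "ankle_tau0": tau0.ankle_tau0,
                **{f"emg_{ch}": v for ch, v in emg_mags.items()},
            }
        )
    if excluded:
        logger.info("excluded %d of %d trials", len(excluded), len(trials))
    if len(rows) < 2:
        raise ValueError("fewer than 2 trials survived the pipeline")

    metrics = pd.DataFrame(rows)
    lo, hi = config.long_distance_range
    subset_ids = metrics.loc[
        (metrics.distance >= lo) & (metrics.distance <= hi), "trial_id"
    ].tolist()
    if not subset_ids:
        raise ValueError(f"no trials in the long-distance subset [{lo}, {hi}] m")
    avg_profile = average_torque_profiles(
        [profiles[t] for t in subset_ids], duration=config.average_duration
    )
    avg_velocities = np.mean([onset_velocities[t] for t in subset_ids], axis=0)

    ordered_ids = metrics.trial_id.tolist()
    sim = run_fixed_command_experiment(
        geometry,
        avg_profile,
        avg_velocities,
        [onset_states[t] for t in ordered_ids],
        barrier_x=trials[0].barrier_x,
    )
    metrics["simulated_slope"] = [slope for _, slope in sim]

    regressions: dict[str, RegressionResult | None] = {}
    d = metrics.distance.to_numpy()
    _regress_or_none("actual_slope_vs_distance", d, metrics.actual_slope, regressions)
    _regress_or_none("simulated_slope_vs_distance", d, metrics.simulated_slope, regressions)
    _regress_or_none(
        "simulated_vs_actual_slope",
        metrics.actual_slope.to_numpy(),
        metrics.simulated_slope,
        regressions,
    )
    for joint in ("hip", "knee", "ankle"):
        _regress_or_none(f"{joint}_tau0_vs_distance", d, metrics[f"{joint}_tau0"], regressions)
    for ch in config.emg_channels:
        col = f"emg_{ch}"
        if col in metrics:
            _regress_or_none(f"{col}_vs_distance", d, metrics[col], regressions)

    return AnalysisReport(
        metrics=metrics,
        regressions=regressions,
        excluded=excluded,
        subset_size=len(subset_ids),
        average_profile=avg_profile,
        average_initial_velocities=avg_velocities,
    )


def plot_report(report: AnalysisReport, outdir) -> list:
    """Scatter plots of the three headline relationships as PNG files."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    m = report.metrics
    panels = [
        ("slope_vs_distance", "distance", ["actual_slope", "simulated_slope"],
         "initial toe-to-barrier distance (m)", "toe-trajectory slope"),
        ("simulated_vs_actual", "actual_slope", ["simulated_slope"],
         "observed slope", "simulated slope"),
        ("knee_tau0_vs_distance", "distance", ["knee_tau0"],
         "initial toe-to-barrier distance (m)", "initial knee torque (N m)"),
    ]
    paths = []
    for name, xcol, ycols, xlabel, ylabel in panels:
        fig, ax = plt.subplots(figsize=(4.5, 3.5))
        for ycol in ycols:
            ax.scatter(m[xcol], m[ycol], s=14, label=ycol.replace("_", " "))
        if name == "simulated_vs_actual":
            lims = [m.actual_slope.min(), m.actual_slope.max()]
            ax.plot(lims, lims, "k--", lw=0.8, label="identity")
        ax.set_xlabel(xlabel)
        ax.set_ylabel(ylabel)
        if len(ycols) > 1 or name == "simulated_vs_actual":
            ax.legend(frameon=False, fontsize=8)
        fig.tight_layout()
        path = outdir / f"{name}.png"
        fig.savefig(path, dpi=150)
        plt.close(fig)
        paths.append(path)
    return paths
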