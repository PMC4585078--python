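"""Reading and writing trials, geometry configs and torque profiles.

On-disk conventions follow the motion-capture habit of centimetre units;
everything is converted to SI on read and back to cm on write.  Trials are
stored either as one JSON object per trial or as a long-form CSV
(``time_s, marker, x_cm, y_cm``) with EMG in a companion CSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .emg import EMGTrace
from .geometry import LegGeometry, SegmentParams, make_default_cat_leg
from .inverse import TorqueProfile
from .kinematics import MARKER_NAMES, Trial

CM = 0.01


def write_trial_json(trial: Trial, path) -> Path:
    """Write one trial as JSON (positions in cm on disk)."""
    path = Path(path)
    obj = {
        "trial_id": trial.trial_id,
        "sample_rate_hz": trial.sample_rate,
        "barrier_x_cm": trial.barrier_x / CM,
        "markers_cm": {
            name: (np.asarray(m) / CM).round(6).tolist() for name, m in trial.markers.items()
        },
        "meta": dict(trial.meta),
    }
    if trial.emg:
        obj["emg"] = {
            ch: {"sample_rate_hz": tr.sample_rate, "v_au": np.round(tr.v, 6).tolist()}
            for ch, tr in trial.emg.items()
        }
    path.write_text(json.dumps(obj))
    return path


def read_trial_json(path) -> Trial:
    """Read a trial written by :func:`write_trial_json`."""
    obj = json.loads(Path(path).read_text())
    markers = {name: np.asarray(m, dtype=float) * CM for name, m in obj["markers_cm"].items()}
    emg = None
    if "emg" in obj:
        emg = {
            ch: EMGTrace(
                v=np.asarray(d["v_au"], dtype=float),
                sample_rate=float(d["sample_rate_hz"]),
                channel=ch,
            )
            for ch, d in obj["emg"].items()
        }
    return Trial(
        trial_id=obj["trial_id"],
        markers=markers,
        sample_rate=float(obj["sample_rate_hz"]),
        barrier_x=float(obj["barrier_x_cm"]) * CM,
        emg=emg,
        meta=obj.get("meta", {}),
    )


def write_trial_csv(trial: Trial, path) -> Path:
    """Write marker series as long-form CSV (time_s, marker, x_cm, y_cm)."""
    path = Path(path)
    t = trial.times
    frames = []
    for name in MARKER_NAMES:
        m = np.asarray(trial.markers[name])
        frames.append(
            pd.DataFrame(
                {"time_s": t, "marker": name, "x_cm": m[:, 0] / CM, "y_cm": m[:, 1] / CM}
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
    return path


def read_trial_csv(path, trial_id=None, sample_rate=60.0, barrier_x_cm=4.0) -> Trial:
    """Read a long-form marker CSV into a Trial (no EMG)."""
    path = Path(path)
    df = pd.read_csv(path)
    markers = {}
    for name, g in df.groupby("marker"):
        g = g.sort_values("time_s")
        markers[name] = np.column_stack([g.x_cm.to_numpy(), g.y_cm.to_numpy()]) * CM
    return Trial(
        trial_id=trial_id or path.stem,
        markers=markers,
        sample_rate=sample_rate,
        barrier_x=barrier_x_cm * CM,
    )


def write_geometry_yaml(geometry: LegGeometry, path) -> Path:
    """Write a geometry config: masses/lengths in g and cm, g in m/s^2."""
    path = Path(path)
    obj = {
        "segments": {
            s.name: {"mass_g": s.mass * 1e3, "length_cm": s.length / CM}
            for s in geometry.segments
        },
        "g_m_s2": geometry.g,
        "hip_origin_cm": [c / CM for c in geometry.hip_origin],
        "barrier_x_cm": geometry.barrier_x / CM,
        "barrier_height_cm": geometry.barrier_height / CM,
    }
    path.write_text(yaml.safe_dump(obj))
    return path


def read_geometry_yaml(path) -> LegGeometry:
    """Read a geometry config; missing keys fall back to the defaults."""
    obj = yaml.safe_load(Path(path).read_text())
    default = make_default_cat_leg()
    segments = []
    for seg in default.segments:
        entry = obj.get("segments", {}).get(seg.name, {})
        segments.append(
            SegmentParams(
                seg.name,
                entry.get("mass_g", seg.mass * 1e3) * 1e-3,
                entry.get("length_cm", seg.length / CM) * CM,
            )
        )
    return LegGeometry(
        segments=tuple(segments),
        g=obj.get("g_m_s2", default.g),
        hip_origin=tuple(c * CM for c in obj.get("hip_origin_cm", [x / CM for x in default.hip_origin])),
        barrier_x=obj.get("barrier_x_cm", default.barrier_x / CM) * CM,
        barrier_height=obj.get("barrier_height_cm", default.barrier_height / CM) * CM,
    )


def write_torque_profile_csv(profile: TorqueProfile, path) -> Path:
    """Torque profile as CSV: t_ms, per-joint torques, joint forces."""
    path = Path(path)
    cols = {"t_ms": profile.t * 1e3}
    for j, joint in enumerate(("hip", "knee", "ankle", "paw")):
        cols[f"tau_{joint}"] = profile.tau[:, j]
    for j, joint in enumerate(("hip", "knee", "ankle", "paw")):
        cols[f"fx_{joint}"] = profile.forces[:, j, 0]
        cols[f"fy_{joint}"] = profile.forces[:, j, 1]
    pd.DataFrame(cols).to_csv(path, index=False)
    return path


def read_torque_profile_csv(path) -> TorqueProfile:
    df = pd.read_csv(path)
    t = df.t_ms.to_numpy() * 1e-3
    tau = df[[f"tau_{j}" for j in ("hip", "knee", "ankle", "paw")]].to_numpy()
    forces = np.zeros((len(df), 4, 2))
    for j, joint in enumerate(("hip", "knee", "ankle", "paw")):
        forces[:, j, 0] = df[f"fx_{joint}"].to_numpy()
        forces[:, j, 1] = df[f"fy_{joint}"].to_numpy()
    dt = float(np.median(np.diff(t))) if len(t) > 1 else 0.001
    return TorqueProfile(t=t, tau=tau, forces=forces, dt=dt)
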