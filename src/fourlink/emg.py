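"""EMG burst quantification: rectify, low-pass, integrate.

The burst magnitude of a flexor channel is the time integral of the
full-wave-rectified, 50-Hz low-pass-filtered signal over a 150-ms window
from burst onset.  Filtering is zero-phase (2nd-order Butterworth applied
forward and backward) so detected onsets are not biased by phase lag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, filtfilt

from .errors import NoBurstError, NyquistError, TruncationError

ENVELOPE_CUTOFF_HZ = 50.0
BURST_WINDOW = 0.150  # s


@dataclass
class EMGTrace:
    """One EMG channel: uniformly sampled voltage in arbitrary units."""

    v: np.ndarray  # (T,), AU
    sample_rate: float  # Hz
    channel: str = ""

    def __post_init__(self) -> None:
        self.v = np.asarray(self.v, dtype=float).reshape(-1)
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be > 0")

    @property
    def t(self) -> np.ndarray:
        return np.arange(len(self.v)) / self.sample_rate

    def __len__(self) -> int:
        return len(self.v)


@dataclass
class BurstMagnitude:
    """Integrated envelope over a fixed window from burst onset."""

    onset: float  # s
    window: float  # s
    magnitude: float  # AU*s

    def __post_init__(self) -> None:
        if self.magnitude < 0:
            raise ValueError("burst magnitude must be >= 0")


def emg_envelope(trace: EMGTrace, cutoff_hz: float = ENVELOPE_CUTOFF_HZ) -> np.ndarray:
    """Full-wave rectified, zero-phase 2nd-order Butterworth low-passed signal."""
    if trace.sample_rate <= 2 * cutoff_hz:
        raise NyquistError(
            f"sample rate {trace.sample_rate} Hz too low for a {cutoff_hz} Hz cutoff"
        )
    b, a = butter(2, cutoff_hz, fs=trace.sample_rate)
    return filtfilt(b, a, np.abs(trace.v))


def burst_magnitude(
    envelope: np.ndarray,
    onset: float,
    sample_rate: float,
    window: float = BURST_WINDOW,
) -> float:
    """Trapezoidal integral of the envelope over [onset, onset + window] (AU*s)."""
    envelope = np.asarray(envelope, dtype=float)
    i0 = int(round(onset * sample_rate))
    i1 = int(round((onset + window) * sample_rate))
    if i0 < 0 or i1 >= len(envelope):
        raise TruncationError(
            f"window [{onset}, {onset + window}] s extends past the "
            f"{len(envelope) / sample_rate:.3f}-s trace"
        )
    return float(np.trapezoid(envelope[i0 : i1 + 1], dx=1.0 / sample_rate))


def detect_burst_onset(
    envelope: np.ndarray,
    sample_rate: float,
    baseline_duration: float = 0.100,
    n_sd: float = 3.0,
    persistence: float = 0.020,
) -> float:
    """First time (s) the envelope exceeds baseline mean + ``n_sd`` x SD for
    at least ``persistence`` seconds.

    Baseline statistics come from the first ``baseline_duration`` of the
    trace.  Raises :class:`NoBurstError` when no sustained excursion is
    found.
    """
    envelope = np.asarray(envelope, dtype=float)
    n_base = max(1, int(round(baseline_duration * sample_rate)))
    threshold = envelope[:n_base].mean() + n_sd * envelope[:n_base].std()
    above = envelope > threshold
    n_persist = max(1, int(round(persistence * sample_rate)))
    idx = np.flatnonzero(above & ~np.r_[False, above[:-1]])
    for i in idx:
        if i + n_persist <= len(above) and np.all(above[i : i + n_persist]):
            return float(i / sample_rate)
    raise NoBurstError("no sustained burst above baseline threshold")
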