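"""Spontaneous EPSC event detection and per-neuron summaries.

Events are inward (negative-going) current deflections in a voltage-clamp
trace held at a fixed potential.  Detection: 1 kHz low-pass, rolling-median
baseline subtraction, threshold at ``max(amp_floor, k * sigma)`` with sigma
from the median absolute deviation, and a minimum inter-event interval.
Amplitudes are reported as positive magnitudes (baseline-to-peak on the
filtered trace).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, signal

from .core import VOLTAGE_CLAMP, ClampModeError, InvalidParameterError, Sweep

__all__ = ["EventTrain", "EpscDetectConfig", "detect_epscs", "summarize_events"]


@dataclass
class EventTrain:
    """Detected (or ground-truth) synaptic events on one trace."""

    times: np.ndarray          # s, sorted
    amplitudes: np.ndarray     # pA, positive magnitudes
    duration: float            # s

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        if self.times.size != self.amplitudes.size:
            raise InvalidParameterError("times and amplitudes must align")
        if self.times.size and (np.any(np.diff(self.times) < 0)
                                or self.times[0] < 0
                                or self.times[-1] > self.duration + 1e-9):
            raise InvalidParameterError("times must be sorted within [0, duration]")
        if np.any(self.amplitudes <= 0):
            raise InvalidParameterError("amplitudes must be positive magnitudes")

    @property
    def n_events(self) -> int:
        return int(self.times.size)

    @property
    def rate(self) -> float:
        """Events per second."""
        return self.n_events / self.duration

    @property
    def mean_amplitude(self) -> float:
        """Mean event magnitude in pA; NaN for an empty train."""
        return float(np.mean(self.amplitudes)) if self.n_events else float("nan")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_s": self.times, "amplitude_pA": self.amplitudes})


@dataclass(frozen=True)
class EpscDetectConfig:
    lowpass_hz: float = 1000.0
    baseline_window_s: float = 0.2
    threshold_k: float = 3.5       # multiples of the MAD-derived sigma
    amp_floor: float = 5.0         # pA, absolute minimum amplitude
    min_interval_s: float = 0.005  # refractory merging of double counts
    min_trace_s: float = 1.0


def _lowpass(y: np.ndarray, fs: float, cutoff: float) -> np.ndarray:
    if cutoff >= fs / 2:
        return y
    sos = signal.butter(4, cutoff, btype="low", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, y)


def detect_epscs(trace: Sweep, config: EpscDetectConfig | None = None) -> EventTrain:
    """Detect inward synaptic events in a voltage-clamp trace."""
    if config is None:
        config = EpscDetectConfig()
    if trace.mode != VOLTAGE_CLAMP:
        raise ClampModeError("EPSC detection requires a voltage-clamp trace")
    if trace.duration < config.min_trace_s:
        raise InvalidParameterError(
            f"trace of {trace.duration:.3f} s is shorter than the "
            f"{config.min_trace_s} s minimum")

    fs = trace.fs
    filt = _lowpass(trace.y, fs, config.lowpass_hz)
    win = max(3, int(round(config.baseline_window_s * fs)) | 1)
    baseline = ndimage.median_filter(filt, size=win, mode="nearest")
    # inward deflection as a positive signal
    d = baseline - filt
    sigma = 1.4826 * np.median(np.abs(d - np.median(d)))
    thr = max(config.amp_floor, config.threshold_k * sigma)
    distance = max(1, int(round(config.min_interval_s * fs)))
    # prominence guards against ripples on the decay shoulder of a real
    # event, which sit below baseline (high d) without being peaks themselves
    peaks, props = signal.find_peaks(d, height=thr, prominence=thr,
                                     distance=distance)
    t0 = trace.t[0]
    duration = trace.duration
    return EventTrain(times=trace.t[peaks] - t0,
                      amplitudes=props["peak_heights"],
                      duration=duration)


def summarize_events(train: EventTrain) -> tuple[float, float]:
    """(rate in Hz, mean amplitude in pA; amplitude NaN if no events)."""
    return train.rate, train.mean_amplitude


def match_events(truth: EventTrain, detected: EventTrain,
                 tol_s: float = 0.002) -> tuple[int, int, int]:
    """Greedy one-to-one matching of detected to ground-truth events.

    Returns (n_matched, n_false_positive, n_missed); used to score detector
    recall and precision against generator ground truth.
    """
    used = np.zeros(truth.n_events, dtype=bool)
    matched = 0
    for td in detected.times:
        if truth.n_events == 0:
            break
        d = np.abs(truth.times - td)
        d[used] = np.inf
        j = int(np.argmin(d))
        if d[j] <= tol_s:
            used[j] = True
            matched += 1
    return matched, detected.n_events - matched, truth.n_events - matched
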