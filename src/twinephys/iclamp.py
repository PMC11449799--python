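"""Intrinsic current-clamp phenotypes: evoked action-potential counts,
spike-shape features, and passive membrane properties.

Spike shape follows the conventions used for patch-clamp analysis of
immature human neurons:

* threshold — membrane potential at the first local maximum of the second
  time-derivative of voltage preceding the spike peak;
* amplitude — peak voltage minus threshold;
* width — full width at half amplitude (between the two crossings of
  threshold + amplitude / 2);
* fAHP — threshold minus the voltage 5 ms after the downward re-crossing
  of threshold.

Passive properties: membrane resistance from the two-point rule
``Rm = 20 mV / (I(-50 mV) - I(-70 mV))``; input conductance as its
reciprocal; capacitance by charge integration of a small voltage-clamp
test transient; resting potential as the median over a zero-injection
epoch.  Neurons needing more than 50 pA of holding current are excluded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .core import (
    CURRENT_CLAMP,
    VOLTAGE_CLAMP,
    AnalysisWindowError,
    ClampModeError,
    InvalidParameterError,
    NoSpikeError,
    ProtocolMismatchError,
    StepProtocol,
    Sweep,
    SweepSet,
    UndefinedThresholdError,
)

__all__ = [
    "SpikeDetectConfig", "SpikeFeatures", "PassiveProperties",
    "detect_spikes", "count_total_evoked_aps", "first_evoked_ap",
    "spike_threshold", "spike_shape", "input_conductance",
    "resting_potential", "capacitance", "steady_state_current",
]

HOLDING_CURRENT_LIMIT_PA = 50.0


@dataclass(frozen=True)
class SpikeDetectConfig:
    min_peak_mV: float = -10.0     # absolute peak height
    min_prominence_mV: float = 20.0
    refractory_ms: float = 2.0


@dataclass(frozen=True)
class SpikeFeatures:
    threshold: float      # mV
    amplitude: float      # mV
    width: float          # ms
    fahp: float           # mV
    peak_v: float         # mV
    spike_time: float     # s

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise InvalidParameterError("amplitude must be >= 0")
        if self.width <= 0:
            raise InvalidParameterError("width must be > 0")


@dataclass(frozen=True)
class PassiveProperties:
    input_resistance: float = float("nan")   # GOhm
    input_conductance: float = float("nan")  # nS
    capacitance: float = float("nan")        # pF
    resting_potential: float = float("nan")  # mV
    holding_current: float = float("nan")    # pA
    excluded: bool = False
    exclusion_reason: str = ""


# -- spike detection -------------------------------------------------------

def detect_spikes(sweep: Sweep, config: SpikeDetectConfig | None = None
                  ) -> np.ndarray:
    """Indices of action-potential peaks in a current-clamp sweep."""
    if config is None:
        config = SpikeDetectConfig()
    if sweep.mode != CURRENT_CLAMP:
        raise ClampModeError("spike detection requires a current-clamp sweep")
    distance = max(1, int(round(config.refractory_ms / sweep.dt_ms)))
    peaks, _ = signal.find_peaks(sweep.y, height=config.min_peak_mV,
                                 prominence=config.min_prominence_mV,
                                 distance=distance)
    return peaks


def count_total_evoked_aps(sweeps: SweepSet,
                           protocol: StepProtocol | None = None,
                           config: SpikeDetectConfig | None = None
                           ) -> tuple[int | None, PassiveProperties | None]:
    """Total spikes over the protocol's depolarization steps.

    Returns ``(count, None)`` or ``(None, excluded_record)`` when the
    holding current exceeds the 50 pA exclusion limit.
    """
    if protocol is None:
        protocol = sweeps.protocol
    if protocol is None:
        raise ProtocolMismatchError("no protocol attached to sweep set")
    if len(sweeps) != protocol.n_steps:
        raise ProtocolMismatchError(
            f"protocol declares {protocol.n_steps} steps but "
            f"{len(sweeps)} sweeps provided")
    if abs(protocol.holding_current) > HOLDING_CURRENT_LIMIT_PA:
        return None, PassiveProperties(
            holding_current=protocol.holding_current, excluded=True,
            exclusion_reason="holding>50pA")
    total = 0
    for sw in sweeps:
        win = sw.metadata.get("step_window_s")
        target = sw if win is None else sw.window(win[0], win[1])
        total += len(detect_spikes(target, config))
    return total, None


def first_evoked_ap(sweeps: SweepSet, config: SpikeDetectConfig | None = None,
                    pre_ms: float = 10.0, post_ms: float = 10.0) -> Sweep:
    """Waveform window around the first spike of the lowest-current sweep
    containing any spike (the rheobase sweep); ties by sweep order."""
    order = sorted(range(len(sweeps)),
                   key=lambda i: (sweeps[i].command_level, i))
    for i in order:
        sw = sweeps[i]
        peaks = detect_spikes(sw, config)
        if peaks.size:
            tp = sw.t[peaks[0]]
            win = sw.window(tp - pre_ms * 1e-3, tp + post_ms * 1e-3)
            win.metadata["peak_time_s"] = float(tp)
            win.metadata["source_sweep"] = i
            return win
    raise NoSpikeError("no action potential in any sweep")


# -- spike shape -----------------------------------------------------------

def _boxcar_smooth(y: np.ndarray, width_samples: int) -> np.ndarray:
    if width_samples <= 1:
        return y
    from scipy import ndimage
    return ndimage.uniform_filter1d(y, size=width_samples, mode="nearest")


def spike_threshold(wave: Sweep, smooth_ms: float = 0.2,
                    search_ms: float = 10.0, rel_floor: float = 0.2,
                    min_curvature: float = 0.5) -> float:
    """Voltage at the first local maximum of d2V/dt2 before the spike peak.

    The second derivative is taken by central finite differences after a
    short boxcar smoothing; candidate maxima below ``rel_floor`` of the
    window's global maximum are ignored as noise, and the global maximum
    must exceed ``min_curvature`` mV/ms^2 (a linear ramp or flat trace has
    none).  A guard band of the smoothing width is dropped at the window
    edge where finite differences are unreliable.
    """
    dt = wave.dt_ms
    w = max(1, int(round(smooth_ms / dt)))
    y = _boxcar_smooth(wave.y, w)
    d2 = np.gradient(np.gradient(y, dt), dt)
    ipk = int(np.argmax(y))
    i0 = max(1, ipk - int(round(search_ms / dt)))
    seg = d2[i0:ipk + 1]
    guard = w + 2
    if seg.size < 2 * guard + 3:
        raise UndefinedThresholdError("window too short before peak")
    seg = seg[guard:]
    i0 += guard
    gmax = float(np.max(seg))
    if gmax < min_curvature or not np.isfinite(gmax):
        raise UndefinedThresholdError("no positive curvature before peak")
    # local maxima of the second derivative within the search window
    cand = np.flatnonzero((seg[1:-1] > seg[:-2]) & (seg[1:-1] >= seg[2:])) + 1
    cand = cand[seg[cand] >= rel_floor * gmax]
    if cand.size == 0:
        raise UndefinedThresholdError(
            "no local maximum of d2V/dt2 before the peak")
    return float(wave.y[i0 + int(cand[0])])


def spike_shape(wave: Sweep, threshold: float,
                fahp_delay_ms: float = 5.0) -> SpikeFeatures:
    """Amplitude, FWHM width and fAHP of a single-spike window."""
    t_ms = (wave.t - wave.t[0]) * 1e3
    y = wave.y
    ipk = int(np.argmax(y))
    peak_v = float(y[ipk])
    amplitude = peak_v - threshold
    if amplitude < 0:
        raise InvalidParameterError("peak below threshold")
    half = threshold + amplitude / 2.0

    def cross_time(i_lo: int, i_hi: int, level: float, rising: bool) -> float:
        seg = y[i_lo:i_hi + 1]
        if rising:
            above = np.flatnonzero(seg >= level)
            if above.size == 0:
                raise AnalysisWindowError("no rising half-amplitude crossing")
            j = i_lo + int(above[0])
            if j == 0:
                return t_ms[0]
            j0 = j - 1
        else:
            below = np.flatnonzero(seg <= level)
            if below.size == 0:
                raise AnalysisWindowError("no falling half-amplitude crossing")
            j = i_lo + int(below[0])
            if j == i_lo:
                return t_ms[j]
            j0 = j - 1
        # linear interpolation between bracketing samples
        y0, y1 = y[j0], y[j]
        if y1 == y0:
            return t_ms[j]
        frac = (level - y0) / (y1 - y0)
        return t_ms[j0] + frac * (t_ms[j] - t_ms[j0])

    t_up = cross_time(0, ipk, half, rising=True)
    t_down = cross_time(ipk, y.size - 1, half, rising=False)
    width = t_down - t_up
    if width <= 0:
        raise AnalysisWindowError("non-positive half-width")

    # downward threshold re-crossing after the peak
    post = y[ipk:]
    below_thr = np.flatnonzero(post <= threshold)
    if below_thr.size == 0:
        raise AnalysisWindowError("membrane never re-crosses threshold")
    i_re = ipk + int(below_thr[0])
    t_lookup = t_ms[i_re] + fahp_delay_ms
    if t_lookup > t_ms[-1] + 1e-9:
        raise AnalysisWindowError(
            f"window ends {t_ms[-1] - t_ms[i_re]:.2f} ms after re-crossing; "
            f"{fahp_delay_ms} ms needed for fAHP")
    v_after = float(np.interp(t_lookup, t_ms, y))
    fahp = threshold - v_after

    return SpikeFeatures(threshold=threshold, amplitude=amplitude,
                         width=width, fahp=fahp, peak_v=peak_v,
                         spike_time=float(wave.t[ipk]))


# -- passive properties ----------------------------------------------------

def input_conductance(i_at_minus70: float, i_at_minus50: float
                      ) -> PassiveProperties:
    """Two-point membrane resistance: Rm = 20 mV / (I(-50) - I(-70)).

    Currents in pA; Rm in GOhm, Gin = 1/Rm in nS (Gin = dI/20 directly).
    """
    d_i = i_at_minus50 - i_at_minus70
    if d_i <= 0:
        raise InvalidParameterError(
            f"non-physical current difference {d_i:.3g} pA "
            "(requires I(-50) > I(-70))")
    rm = 20.0 / d_i           # GOhm (mV / pA)
    return PassiveProperties(input_resistance=rm, input_conductance=1.0 / rm)


def steady_state_current(sweep: Sweep, tail_ms: float = 50.0) -> float:
    """Mean clamp current (pA) over the last ``tail_ms`` of a VC sweep."""
    if sweep.mode != VOLTAGE_CLAMP:
        raise ClampModeError("steady-state current needs a voltage-clamp sweep")
    t1 = sweep.t[-1]
    return float(np.mean(sweep.window(t1 - tail_ms * 1e-3, t1).y))


def resting_potential(sweep: Sweep, epoch_ms: float = 500.0) -> float:
    """Median membrane potential over a zero-injection epoch."""
    if sweep.mode != CURRENT_CLAMP:
        raise ClampModeError("resting potential needs a current-clamp sweep")
    i_pre = sweep.metadata.get("i_pre_pA", 0.0 if sweep.command_level == 0 else None)
    i_step = sweep.metadata.get("i_step_pA", sweep.command_level)
    if (i_pre is None or i_pre != 0.0) or i_step != 0.0:
        raise InvalidParameterError(
            "no zero-injection baseline epoch in this sweep")
    t1 = sweep.t[-1]
    epoch = sweep.window(max(sweep.t[0], t1 - epoch_ms * 1e-3), t1)
    return float(np.median(epoch.y))


def capacitance(test_sweep: Sweep, dV: float | None = None) -> float:
    """Charge-integration capacitance from a small VC test step.

    C = Q / |dV| with Q the integral of the capacitive transient above the
    post-step steady-state current; returns pF (pA * ms / mV).
    """
    if test_sweep.mode != VOLTAGE_CLAMP:
        raise ClampModeError("capacitance test must be a voltage-clamp sweep")
    if dV is None:
        dV = test_sweep.metadata.get("dV_mV", test_sweep.command_level)
    if dV == 0:
        raise InvalidParameterError("test step dV must be nonzero")
    onset = test_sweep.metadata.get("onset_s", test_sweep.t[0])
    t_ms = (test_sweep.t - onset) * 1e3
    post = t_ms >= 0
    y = test_sweep.y[post]
    tm = t_ms[post]
    # steady state from the final quarter of the step
    i_ss = float(np.mean(y[tm >= tm[-1] * 0.75]))
    q = float(np.trapezoid(y - i_ss, tm))  # pA * ms
    return abs(q / dV)
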