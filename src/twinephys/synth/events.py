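"""Synthetic EPSC traces and MEA spike trains with ground truth."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..core import VOLTAGE_CLAMP, InvalidParameterError, Sweep
from ..epsc import EventTrain
from ..mea import Burst, BurstSet, SpikeTrainSet

__all__ = ["EpscGenParams", "generate_epsc_trace",
           "MeaGenParams", "generate_mea_trains"]


@dataclass(frozen=True)
class EpscGenParams:
    rate: float = 1.0          # events/s (Poisson)
    amp_mean: float = 20.0     # pA, mean of the lognormal amplitude law
    amp_sd: float = 5.0        # pA, sd of the lognormal amplitude law
    tau_rise: float = 1.0      # ms
    tau_decay: float = 5.0     # ms
    noise_sd: float = 2.0      # pA Gaussian
    duration: float = 60.0     # s
    sampling_rate: float = 20000.0  # Hz
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tau_decay <= self.tau_rise or self.tau_rise <= 0:
            raise InvalidParameterError("need tau_decay > tau_rise > 0")
        if self.rate < 0:
            raise InvalidParameterError("rate must be >= 0")
        if self.duration <= 0:
            raise InvalidParameterError("duration must be > 0")
        if self.amp_mean <= 0 or self.amp_sd < 0:
            raise InvalidParameterError("amplitude parameters out of range")


def _biexp_kernel(t_ms: np.ndarray, tau_rise: float, tau_decay: float
                  ) -> np.ndarray:
    """exp(-t/tau_decay) - exp(-t/tau_rise), normalized to unit peak."""
    t_peak = (tau_rise * tau_decay / (tau_decay - tau_rise)
              * np.log(tau_decay / tau_rise))
    peak = np.exp(-t_peak / tau_decay) - np.exp(-t_peak / tau_rise)
    k = np.exp(-t_ms / tau_decay) - np.exp(-t_ms / tau_rise)
    return k / peak


def generate_epsc_trace(params: EpscGenParams) -> tuple[Sweep, EventTrain]:
    """Poisson train of inward bi-exponential events plus Gaussian noise.

    Event times mark kernel onsets; ground-truth times are the event peak
    times (onset + kernel time-to-peak), matching what a detector sees.
    """
    rng = np.random.default_rng(params.seed)
    fs = params.sampling_rate
    n = int(round(params.duration * fs))
    t = np.arange(n) / fs

    n_events = rng.poisson(params.rate * params.duration)
    onsets = np.sort(rng.uniform(0.0, params.duration, size=n_events))
    if params.amp_sd > 0:
        s2 = np.log1p((params.amp_sd / params.amp_mean) ** 2)
        mu = np.log(params.amp_mean) - s2 / 2.0
        amps = rng.lognormal(mean=mu, sigma=np.sqrt(s2), size=n_events)
    else:
        amps = np.full(n_events, params.amp_mean)

    y = np.zeros(n)
    kern_ms = np.arange(0.0, 10.0 * params.tau_decay, 1e3 / fs)
    kern = _biexp_kernel(kern_ms, params.tau_rise, params.tau_decay)
    t_peak_s = (params.tau_rise * params.tau_decay
                / (params.tau_decay - params.tau_rise)
                * np.log(params.tau_decay / params.tau_rise)) * 1e-3
    for onset, amp in zip(onsets, amps):
        i0 = int(round(onset * fs))
        seg = min(kern.size, n - i0)
        if seg > 0:
            y[i0:i0 + seg] -= amp * kern[:seg]
    if params.noise_sd > 0:
        y += rng.normal(0.0, params.noise_sd, size=n)

    peak_times = onsets + t_peak_s
    keep = peak_times <= params.duration
    truth = EventTrain(times=peak_times[keep], amplitudes=amps[keep],
                       duration=params.duration)
    sweep = Sweep(t, y, mode=VOLTAGE_CLAMP, command_level=-60.0,
                  metadata={"generator": "epsc", "seed": params.seed,
                            "rate_hz": params.rate})
    return sweep, truth


@dataclass(frozen=True)
class MeaGenParams:
    n_electrodes: int = 8
    background_rate: float = 1.0    # Hz per electrode
    burst_rate: float = 2.0         # bursts/min per electrode
    burst_len: int = 10             # spikes per inserted burst
    intra_burst_isi: float = 10.0   # ms
    duration: float = 600.0         # s
    well_id: str = "well0"
    recording_day: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_electrodes < 1:
            raise InvalidParameterError("n_electrodes must be >= 1")
        if self.background_rate < 0 or self.burst_rate < 0:
            raise InvalidParameterError("rates must be >= 0")
        if self.burst_len < 2:
            raise InvalidParameterError("burst_len must be >= 2")
        if self.duration <= 0 or self.intra_burst_isi <= 0:
            raise InvalidParameterError("duration and ISI must be > 0")


def generate_mea_trains(params: MeaGenParams
                        ) -> tuple[SpikeTrainSet, BurstSet]:
    """Homogeneous Poisson background with inserted dense spike runs.

    Inserted bursts are the ground truth: ``burst_len`` spikes at a regular
    ``intra_burst_isi`` (duration (burst_len - 1) * isi) at Poisson times.
    """
    rng = np.random.default_rng(params.seed)
    burst_span = (params.burst_len - 1) * params.intra_burst_isi * 1e-3
    trains: dict[str, np.ndarray] = {}
    truth: list[Burst] = []
    for e in range(params.n_electrodes):
        eid = f"e{e}"
        n_bg = rng.poisson(params.background_rate * params.duration)
        spikes = [rng.uniform(0.0, params.duration, size=n_bg)]
        n_bursts = rng.poisson(params.burst_rate / 60.0 * params.duration)
        if n_bursts and params.duration > burst_span:
            starts = np.sort(rng.uniform(0.0, params.duration - burst_span,
                                         size=n_bursts))
            for s in starts:
                bt = s + np.arange(params.burst_len) * params.intra_burst_isi * 1e-3
                spikes.append(bt)
                truth.append(Burst(electrode_id=eid, start=float(bt[0]),
                                   end=float(bt[-1]),
                                   n_spikes=params.burst_len,
                                   surprise=np.inf))
        trains[eid] = np.sort(np.concatenate(spikes))
    return (SpikeTrainSet(trains, duration=params.duration,
                          well_id=params.well_id,
                          recording_day=params.recording_day),
            BurstSet(truth))
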