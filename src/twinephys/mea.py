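"""Multi-electrode array analysis: spike detection on raw voltage,
Poisson-surprise burst detection, network-burst detection, and per-well
longitudinal aggregation.

Burst detection implements the classic Poisson-surprise formulation: a burst
is a maximal run of spikes whose surprise

    S = -log10 P(N >= n | N ~ Poisson(lambda * T))

exceeds ``surprise_min``, where ``lambda`` is the whole-train mean rate and
``T`` the run duration.  Candidate runs are seeded where consecutive
inter-spike intervals are shorter than half the train mean ISI and extended
greedily while S increases.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal, stats

from .core import InvalidParameterError, Sweep

__all__ = [
    "SpikeTrainSet", "Burst", "BurstSet", "WellSummary",
    "MeaSpikeDetectConfig", "BurstConfig", "NetworkBurstConfig",
    "mea_spike_detect", "detect_bursts", "detect_network_bursts",
    "summarize_well", "longitudinal_table", "poisson_surprise",
]


@dataclass
class SpikeTrainSet:
    """Per-electrode sorted spike times for one well at one recording day."""

    trains: dict[str, np.ndarray]   # electrode_id -> spike times (s)
    duration: float = 600.0
    well_id: str = "well0"
    recording_day: int = 0

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise InvalidParameterError("duration must be > 0")
        clean = {}
        for eid, ts in self.trains.items():
            ts = np.sort(np.asarray(ts, dtype=float))
            if ts.size and (ts[0] < 0 or ts[-1] > self.duration + 1e-9):
                raise InvalidParameterError(
                    f"electrode {eid}: spikes outside [0, duration]")
            clean[str(eid)] = ts
        self.trains = clean

    @property
    def n_spikes(self) -> int:
        return int(sum(ts.size for ts in self.trains.values()))

    def to_frame(self) -> pd.DataFrame:
        rows = [(eid, t) for eid, ts in self.trains.items() for t in ts]
        return pd.DataFrame(rows, columns=["electrode_id", "spike_time_s"])

    @classmethod
    def from_frame(cls, df: pd.DataFrame, duration: float = 600.0,
                   well_id: str = "well0", recording_day: int = 0) -> "SpikeTrainSet":
        trains = {str(eid): g["spike_time_s"].to_numpy()
                  for eid, g in df.groupby("electrode_id")}
        return cls(trains, duration=duration, well_id=well_id,
                   recording_day=recording_day)


@dataclass(frozen=True)
class Burst:
    electrode_id: str
    start: float      # s
    end: float        # s
    n_spikes: int
    surprise: float   # -log10 Poisson tail probability

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise InvalidParameterError("burst end must exceed start")


@dataclass
class BurstSet:
    bursts: list[Burst] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.bursts)

    def __iter__(self):
        return iter(self.bursts)

    def for_electrode(self, eid: str) -> list[Burst]:
        return [b for b in self.bursts if b.electrode_id == eid]


@dataclass(frozen=True)
class WellSummary:
    well_id: str
    day: int
    n_spikes: int
    n_bursts: int
    n_network_bursts: int
    mean_firing_rate: float  # Hz, spikes / (duration * n_electrodes)


# -- raw-trace spike detection --------------------------------------------

@dataclass(frozen=True)
class MeaSpikeDetectConfig:
    band_low_hz: float = 10.0
    band_high_hz: float = 2500.0
    threshold_sd: float = 5.5
    dead_time_s: float = 0.001
    detect_positive: bool = False  # negative-going crossings are primary


def mea_spike_detect(raw: Sweep, config: MeaSpikeDetectConfig | None = None
                     ) -> np.ndarray:
    """Threshold-crossing spike times (s) from one electrode's raw voltage."""
    if config is None:
        config = MeaSpikeDetectConfig()
    fs = raw.fs
    if fs < 2.0 * config.band_high_hz:
        raise InvalidParameterError(
            f"sampling rate {fs:.0f} Hz below Nyquist for "
            f"{config.band_high_hz:.0f} Hz high cutoff")
    if np.all(raw.y == 0):
        return np.array([])
    sos = signal.butter(2, [config.band_low_hz, config.band_high_hz],
                        btype="band", fs=fs, output="sos")
    y = signal.sosfiltfilt(sos, raw.y)
    mu, sd = float(np.mean(y)), float(np.std(y))
    if sd == 0:
        return np.array([])
    lo = mu - config.threshold_sd * sd
    hit = y < lo
    if config.detect_positive:
        hit |= y > mu + config.threshold_sd * sd
    idx = np.flatnonzero(hit[1:] & ~hit[:-1]) + 1
    if idx.size == 0:
        return np.array([])
    dead = config.dead_time_s
    times = raw.t[idx]
    keep = [times[0]]
    for tcur in times[1:]:
        if tcur - keep[-1] >= dead:
            keep.append(tcur)
    return np.asarray(keep) - raw.t[0]


# -- Poisson-surprise bursts ----------------------------------------------

@dataclass(frozen=True)
class BurstConfig:
    min_spikes: int = 5
    surprise_min: float = 10.0
    seed_isi_factor: float = 0.5   # seed runs where ISI < factor * mean ISI
    max_extend: int = 50           # greedy extension horizon per side


def poisson_surprise(n: int, t_span: float, rate: float) -> float:
    """-log10 P(N >= n) for N ~ Poisson(rate * t_span)."""
    if n <= 0 or t_span <= 0 or rate <= 0:
        return 0.0
    logsf = stats.poisson.logsf(n - 1, rate * t_span)
    return float(-logsf / np.log(10.0))


def _surprise_of(ts: np.ndarray, i: int, j: int, rate: float) -> float:
    span = ts[j] - ts[i]
    if span <= 0:
        return 0.0
    return poisson_surprise(j - i + 1, span, rate)


def detect_bursts(train: np.ndarray, duration: float,
                  config: BurstConfig | None = None,
                  electrode_id: str = "e0") -> BurstSet:
    """Poisson-surprise burst detection on a single sorted spike train."""
    if config is None:
        config = BurstConfig()
    ts = np.sort(np.asarray(train, dtype=float))
    if ts.size < config.min_spikes:
        return BurstSet([])
    rate = ts.size / duration
    isi = np.diff(ts)
    mean_isi = float(np.mean(isi))
    dense = isi < config.seed_isi_factor * mean_isi

    bursts: list[Burst] = []
    k = config.min_spikes
    i = 0
    n = ts.size
    while i <= n - k:
        # seed: min_spikes consecutive spikes joined by dense ISIs
        if not np.all(dense[i:i + k - 1]):
            i += 1
            continue
        j = i + k - 1
        s = _surprise_of(ts, i, j, rate)
        # greedy forward extension while surprise increases
        improved = True
        while improved:
            improved = False
            for j2 in range(j + 1, min(j + 1 + config.max_extend, n)):
                s2 = _surprise_of(ts, i, j2, rate)
                if s2 > s:
                    j, s = j2, s2
                    improved = True
                    break
        # greedy backward trim/extension at the left edge
        improved = True
        while improved:
            improved = False
            if i + config.min_spikes - 1 < j:
                s2 = _surprise_of(ts, i + 1, j, rate)
                if s2 > s:
                    i, s = i + 1, s2
                    improved = True
        if s >= config.surprise_min:
            bursts.append(Burst(electrode_id=electrode_id,
                                start=float(ts[i]), end=float(ts[j]),
                                n_spikes=j - i + 1, surprise=s))
            i = j + 1
        else:
            # a failed candidate must not swallow a later true burst
            i += 1
    return BurstSet(bursts)


def detect_bursts_set(trainset: SpikeTrainSet,
                      config: BurstConfig | None = None) -> BurstSet:
    all_bursts: list[Burst] = []
    for eid, ts in trainset.trains.items():
        all_bursts.extend(detect_bursts(ts, trainset.duration, config,
                                        electrode_id=eid).bursts)
    return BurstSet(all_bursts)


# -- network bursts --------------------------------------------------------

@dataclass(frozen=True)
class NetworkBurstConfig:
    min_fraction: float = 0.25   # fraction of active electrodes bursting
    merge_gap_s: float = 0.1


def detect_network_bursts(burstset: BurstSet, n_electrodes: int | None = None,
                          config: NetworkBurstConfig | None = None
                          ) -> list[tuple[float, float]]:
    """Intervals where single-electrode bursts overlap on enough electrodes.

    ``n_electrodes`` defaults to the number of electrodes that contributed at
    least one burst ("active" electrodes).
    """
    if config is None:
        config = NetworkBurstConfig()
    if len(burstset) == 0:
        return []
    active = {b.electrode_id for b in burstset}
    n_active = n_electrodes if n_electrodes is not None else len(active)
    need = max(2, int(np.ceil(config.min_fraction * n_active)))

    events = []  # (time, +1/-1, electrode)
    for b in burstset:
        events.append((b.start, 1, b.electrode_id))
        events.append((b.end, -1, b.electrode_id))
    events.sort(key=lambda e: (e[0], -e[1]))

    intervals = []
    per_elec: dict[str, int] = {}
    n_on = 0
    open_t = None
    for t, delta, eid in events:
        prev = per_elec.get(eid, 0)
        per_elec[eid] = prev + delta
        if delta > 0 and prev == 0:
            n_on += 1
        elif delta < 0 and per_elec[eid] == 0:
            n_on -= 1
        if open_t is None and n_on >= need:
            open_t = t
        elif open_t is not None and n_on < need:
            intervals.append((open_t, t))
            open_t = None
    if open_t is not None:
        intervals.append((open_t, events[-1][0]))

    merged: list[tuple[float, float]] = []
    for s, e in intervals:
        if merged and s - merged[-1][1] < config.merge_gap_s:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


# -- aggregation -----------------------------------------------------------

def summarize_well(trainset: SpikeTrainSet,
                   burst_config: BurstConfig | None = None,
                   network_config: NetworkBurstConfig | None = None
                   ) -> WellSummary:
    bursts = detect_bursts_set(trainset, burst_config)
    nbs = detect_network_bursts(bursts, n_electrodes=len(trainset.trains),
                                config=network_config) if len(bursts) else []
    n_elec = max(1, len(trainset.trains))
    return WellSummary(
        well_id=trainset.well_id, day=trainset.recording_day,
        n_spikes=trainset.n_spikes, n_bursts=len(bursts),
        n_network_bursts=len(nbs),
        mean_firing_rate=trainset.n_spikes / (trainset.duration * n_elec))


def longitudinal_table(summaries: list[WellSummary],
                       well_to_subject: dict[str, tuple[str, str]] | None = None
                       ) -> pd.DataFrame:
    """Long table keyed by (group, subject, day), averaging the replicate
    wells of each subject per day.

    ``well_to_subject`` maps well_id -> (group, subject_id); when omitted
    each well is treated as its own subject in group "all".
    """
    rows = []
    for s in summaries:
        group, subject = (well_to_subject or {}).get(
            s.well_id, ("all", s.well_id))
        rows.append({"group": group, "subject_id": subject, "day": s.day,
                     "well_id": s.well_id, "n_spikes": s.n_spikes,
                     "n_bursts": s.n_bursts,
                     "n_network_bursts": s.n_network_bursts,
                     "mean_firing_rate": s.mean_firing_rate})
    df = pd.DataFrame(rows)
    agg = (df.groupby(["group", "subject_id", "day"], as_index=False)
             .agg(n_wells=("well_id", "nunique"),
                  n_spikes=("n_spikes", "mean"),
                  n_bursts=("n_bursts", "mean"),
                  n_network_bursts=("n_network_bursts", "mean"),
                  mean_firing_rate=("mean_firing_rate", "mean")))
    return agg
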