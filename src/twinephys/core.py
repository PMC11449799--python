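"""Core data containers for clamped time-series and acquisition protocols.

Conventions
-----------
* ``Sweep.t`` is in seconds, uniformly spaced; ``Sweep.y`` is in mV
  (current clamp) or pA (voltage clamp).
* Interface units follow electrophysiology practice: mV, pA, ms, and
  GOhm / nS / pF for derived passive properties.  The identity
  ``pA = nS * mV`` and ``mV/ms = pA/pF`` make these self-consistent.
* On-disk format is plain text: one two-column CSV per sweep
  (``time_s,value``) plus a JSON manifest describing the set.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

CURRENT_CLAMP = "current_clamp"
VOLTAGE_CLAMP = "voltage_clamp"


class TwinephysError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(TwinephysError, ValueError):
    """A generator or estimator parameter violates its constraints."""


class ClampModeError(TwinephysError, ValueError):
    """Operation applied to a sweep recorded in the wrong clamp mode."""


class ProtocolMismatchError(TwinephysError, ValueError):
    """Sweep set does not match the declared stimulation protocol."""


class NoSpikeError(TwinephysError, ValueError):
    """No action potential found where one is required."""


class UndefinedThresholdError(TwinephysError, ValueError):
    """Spike-threshold criterion has no solution on this waveform."""


class AnalysisWindowError(TwinephysError, ValueError):
    """Waveform window too short for the requested measurement."""


class DegenerateSampleError(TwinephysError, ValueError):
    """Statistical input is degenerate (e.g. zero variance)."""


@dataclass(frozen=True)
class StepProtocol:
    """Square current-step stimulation protocol for current clamp.

    The default values encode a 20-step family starting 12 pA below the
    holding current, incrementing by 3 pA, each step 400 ms long, with the
    cell held at -60 mV between steps.
    """

    holding_potential: float = -60.0  # mV
    holding_current: float = 0.0      # pA, bias required to hold the cell
    n_steps: int = 20
    step_increment: float = 3.0       # pA
    first_step_offset: float = -12.0  # pA relative to holding current
    step_duration: float = 400.0      # ms
    pre_duration: float = 100.0       # ms of holding before the step
    post_duration: float = 100.0      # ms after the step
    sampling_interval: float = 0.05   # ms (20 kHz)

    def __post_init__(self) -> None:
        if self.n_steps < 1:
            raise InvalidParameterError("n_steps must be >= 1")
        if self.step_duration <= 0:
            raise InvalidParameterError("step_duration must be > 0")
        if self.sampling_interval <= 0:
            raise InvalidParameterError("sampling_interval must be > 0")

    def step_currents(self) -> np.ndarray:
        """Absolute injected current (pA) for each step, in sweep order."""
        offsets = self.first_step_offset + self.step_increment * np.arange(self.n_steps)
        return self.holding_current + offsets


@dataclass
class Sweep:
    """A single uniformly sampled clamp recording."""

    t: np.ndarray                 # s
    y: np.ndarray                 # mV (CC) or pA (VC)
    mode: str = CURRENT_CLAMP
    command_level: float = 0.0    # pA (CC step) or mV (VC step)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.t.shape != self.y.shape:
            raise InvalidParameterError("t and y must have equal length")
        if self.t.size >= 2:
            dt = np.diff(self.t)
            if np.any(dt <= 0):
                raise InvalidParameterError("t must be strictly increasing")
            if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-12):
                raise InvalidParameterError("t must be uniformly spaced")
        if self.mode not in (CURRENT_CLAMP, VOLTAGE_CLAMP):
            raise InvalidParameterError(f"unknown clamp mode {self.mode!r}")

    @property
    def dt(self) -> float:
        """Sampling interval in seconds."""
        return float(self.t[1] - self.t[0]) if self.t.size >= 2 else np.nan

    @property
    def dt_ms(self) -> float:
        return self.dt * 1e3

    @property
    def fs(self) -> float:
        """Sampling rate in Hz."""
        return 1.0 / self.dt

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0]) if self.t.size else 0.0

    def window(self, t0: float, t1: float) -> "Sweep":
        """Sub-sweep on the closed time interval [t0, t1] (seconds)."""
        sel = (self.t >= t0 - 1e-12) & (self.t <= t1 + 1e-12)
        return Sweep(self.t[sel], self.y[sel], mode=self.mode,
                     command_level=self.command_level, metadata=dict(self.metadata))


@dataclass
class SweepSet:
    """An ordered family of sweeps sharing one protocol."""

    sweeps: list[Sweep]
    protocol: StepProtocol | None = None
    metadata: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.sweeps)

    def __iter__(self):
        return iter(self.sweeps)

    def __getitem__(self, i: int) -> Sweep:
        return self.sweeps[i]


# --------------------------------------------------------------------------
# Plain-text persistence: per-sweep CSV + JSON manifest
# --------------------------------------------------------------------------

def write_sweep(sweep: Sweep, path: str | Path) -> None:
    path = Path(path)
    arr = np.column_stack([sweep.t, sweep.y])
    np.savetxt(path, arr, delimiter=",", header="time_s,value", comments="")


def read_sweep(path: str | Path, mode: str = CURRENT_CLAMP,
               command_level: float = 0.0) -> Sweep:
    arr = np.loadtxt(path, delimiter=",", skiprows=1)
    return Sweep(arr[:, 0], arr[:, 1], mode=mode, command_level=command_level)


def write_sweepset(sweepset: SweepSet, out_dir: str | Path, stem: str = "sweep") -> Path:
    """Write one CSV per sweep plus ``manifest.json``; returns manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    entries = []
    for i, sw in enumerate(sweepset):
        fname = f"{stem}_{i:03d}.csv"
        write_sweep(sw, out_dir / fname)
        entries.append({
            "file": fname,
            "mode": sw.mode,
            "command_level": sw.command_level,
            "metadata": sw.metadata,
        })
    manifest = {
        "sweeps": entries,
        "protocol": asdict(sweepset.protocol) if sweepset.protocol else None,
        "metadata": sweepset.metadata,
    }
    mpath = out_dir / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=2))
    return mpath


def read_sweepset(manifest_path: str | Path) -> SweepSet:
    mpath = Path(manifest_path)
    manifest = json.loads(mpath.read_text())
    sweeps = []
    for entry in manifest["sweeps"]:
        sw = read_sweep(mpath.parent / entry["file"], mode=entry["mode"],
                        command_level=entry["command_level"])
        sw.metadata = entry.get("metadata", {})
        sweeps.append(sw)
    proto = StepProtocol(**manifest["protocol"]) if manifest.get("protocol") else None
    return SweepSet(sweeps, protocol=proto, metadata=manifest.get("metadata", {}))


def p_to_stars(p: float) -> str:
    """Significance-star convention: * <0.05, ** <0.01, *** <0.001, **** <0.0001."""
    if not 0 <= p <= 1:
        raise InvalidParameterError(f"p-value {p} outside [0, 1]")
    if p < 1e-4:
        return "****"
    if p < 1e-3:
        return "***"
    if p < 1e-2:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"
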