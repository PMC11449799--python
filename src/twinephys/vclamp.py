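"""Sodium and potassium current extraction from voltage-clamp step families.

Per sweep:

* sodium — stabilized current minus the sweep minimum inside the transient
  window (inward transient reported as a positive amplitude);
* fast potassium — maximal current within ``w_fast`` ms of step onset;
* slow potassium — mean current over the final 10 ms of the step.

Leak subtraction (optional, default on) fits steady current against command
voltage over the hyperpolarized steps (-90 to -70 mV by default), where the
voltage-gated channels stay closed, and removes the extrapolated linear leak
from every measurement.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import (
    VOLTAGE_CLAMP,
    ClampModeError,
    InvalidParameterError,
    ProtocolMismatchError,
    Sweep,
    SweepSet,
)

__all__ = ["VClampConfig", "IVCurve", "sodium_current",
           "fast_potassium_current", "slow_potassium_current", "build_iv"]


@dataclass(frozen=True)
class VClampConfig:
    transient_ms: float = 10.0       # Na transient search window after onset
    stabilized_ms: tuple[float, float] = (20.0, 40.0)
    w_fast_ms: float = 10.0          # fast K search window after onset
    slow_tail_ms: float = 10.0       # slow K averaging window at step end
    leak_subtract: bool = True
    leak_fit_range_mV: tuple[float, float] = (-90.0, -70.0)


def _onset_s(sweep: Sweep) -> float:
    onset = sweep.metadata.get("onset_s")
    if onset is None:
        raise ProtocolMismatchError("sweep lacks step-onset annotation")
    return float(onset)


def _check_vc(sweep: Sweep) -> None:
    if sweep.mode != VOLTAGE_CLAMP:
        raise ClampModeError("extractor requires a voltage-clamp sweep")


def _leak_current(sweep: Sweep, leak_fn) -> float:
    return leak_fn(sweep.command_level) if leak_fn is not None else 0.0


def sodium_current(sweep: Sweep, config: VClampConfig | None = None,
                   leak_fn=None) -> float:
    """Transient inward amplitude: I_stabilized - min(I) in the transient
    window; >= 0 by construction for a true inward transient."""
    if config is None:
        config = VClampConfig()
    _check_vc(sweep)
    onset = _onset_s(sweep)
    trans = sweep.window(onset, onset + config.transient_ms * 1e-3)
    stab = sweep.window(onset + config.stabilized_ms[0] * 1e-3,
                        onset + config.stabilized_ms[1] * 1e-3)
    if trans.t.size == 0 or stab.t.size == 0:
        raise ProtocolMismatchError("sweep too short for the analysis windows")
    i_min = float(np.min(trans.y))
    i_stab = float(np.mean(stab.y))
    return i_stab - i_min


def fast_potassium_current(sweep: Sweep, config: VClampConfig | None = None,
                           leak_fn=None) -> float:
    """Maximal outward current within ``w_fast`` of onset, leak-subtracted."""
    if config is None:
        config = VClampConfig()
    _check_vc(sweep)
    onset = _onset_s(sweep)
    win = sweep.window(onset, onset + config.w_fast_ms * 1e-3)
    if win.t.size == 0:
        raise ProtocolMismatchError("sweep too short for the fast-K window")
    return float(np.max(win.y)) - _leak_current(sweep, leak_fn)


def slow_potassium_current(sweep: Sweep, config: VClampConfig | None = None,
                           leak_fn=None) -> float:
    """Mean current over the final ``slow_tail_ms`` of the step,
    leak-subtracted."""
    if config is None:
        config = VClampConfig()
    _check_vc(sweep)
    end = sweep.metadata.get("step_end_s", sweep.t[-1])
    win = sweep.window(end - config.slow_tail_ms * 1e-3, end)
    if win.t.size == 0:
        raise ProtocolMismatchError("sweep too short for the slow-K window")
    return float(np.mean(win.y)) - _leak_current(sweep, leak_fn)


def _fit_leak(sweepset: SweepSet, config: VClampConfig):
    """Linear fit of steady current vs command V over hyperpolarized steps;
    returns a callable pA(V) or None if too few steps fall in range."""
    vs, isteady = [], []
    lo, hi = config.leak_fit_range_mV
    for sw in sweepset:
        if lo - 1e-9 <= sw.command_level <= hi + 1e-9:
            end = sw.metadata.get("step_end_s", sw.t[-1])
            tail = sw.window(end - config.slow_tail_ms * 1e-3, end)
            vs.append(sw.command_level)
            isteady.append(float(np.mean(tail.y)))
    if len(vs) < 2:
        return None
    slope, intercept = np.polyfit(vs, isteady, 1)
    return lambda v: slope * v + intercept


@dataclass
class IVCurve:
    """Aligned per-step current amplitudes across the command-voltage range."""

    step_v: np.ndarray
    i_na: np.ndarray
    i_k_fast: np.ndarray
    i_k_slow: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.step_v)
        for name in ("i_na", "i_k_fast", "i_k_slow"):
            if len(getattr(self, name)) != n:
                raise InvalidParameterError("IV curve columns must align")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"step_v": self.step_v, "i_na": self.i_na,
                             "i_k_fast": self.i_k_fast,
                             "i_k_slow": self.i_k_slow})


def build_iv(sweepset: SweepSet, config: VClampConfig | None = None) -> IVCurve:
    """Apply the three extractors to every sweep, preserving step order."""
    if config is None:
        config = VClampConfig()
    leak_fn = _fit_leak(sweepset, config) if config.leak_subtract else None
    vs, ina, ikf, iks = [], [], [], []
    for sw in sweepset:
        vs.append(sw.command_level)
        ina.append(sodium_current(sw, config, leak_fn))
        ikf.append(fast_potassium_current(sw, config, leak_fn))
        iks.append(slow_potassium_current(sw, config, leak_fn))
    return IVCurve(np.array(vs), np.array(ina), np.array(ikf), np.array(iks))
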