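"""Single-compartment conductance-based neuron simulator.

The model carries a leak, a transient sodium current (m^3 h), a
delayed-rectifier potassium current (n^4, sustained) and an A-type fast
potassium current (a^4 b, transient), integrated with fixed-step
exponential Euler.  Units: mV, ms, pA, pF, nS (pA = nS * mV and
mV/ms = pA/pF, so no conversion constants appear in the equations).

At a clamped voltage every gating variable relaxes exponentially with a
constant time constant, so :func:`gating_current_at_clamp` provides a
closed-form evaluation of the clamp current that is independent of the
time-stepping loop — tests use it as an oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from ..core import (
    CURRENT_CLAMP,
    VOLTAGE_CLAMP,
    InvalidParameterError,
    StepProtocol,
    Sweep,
    SweepSet,
)

__all__ = [
    "NeuronModelParams",
    "excitable_preset",
    "simulate_current_clamp",
    "simulate_voltage_clamp",
    "simulate_zero_current",
    "simulate_capacitance_test",
    "holding_bias_current",
    "gating_current_at_clamp",
    "steady_state_gates",
]


@dataclass(frozen=True)
class NeuronModelParams:
    """True parameters of a synthetic neuron; the ground truth the
    estimators are expected to recover."""

    C: float = 30.0          # pF
    gL: float = 0.5          # nS
    EL: float = -65.0        # mV
    gNa: float = 0.0         # nS
    gK_fast: float = 0.0     # nS (A-type, transient)
    gK_slow: float = 0.0     # nS (delayed rectifier, sustained)
    ENa: float = 60.0        # mV
    EK: float = -90.0        # mV
    tau_a: float = 1.0       # ms, A-type activation
    tau_b: float = 30.0      # ms, A-type inactivation
    v_shift: float = 0.0     # mV, shifts all gating curves
    noise_sd: float = 0.0    # pA, additive Gaussian current noise
    seed: int = 0

    def __post_init__(self) -> None:
        if self.C <= 0:
            raise InvalidParameterError("capacitance C must be > 0")
        if self.gL < 0 or self.gNa < 0 or self.gK_fast < 0 or self.gK_slow < 0:
            raise InvalidParameterError("conductances must be >= 0")
        if self.tau_a <= 0 or self.tau_b <= 0:
            raise InvalidParameterError("gating time constants must be > 0")
        if self.noise_sd < 0:
            raise InvalidParameterError("noise_sd must be >= 0")


def excitable_preset(**overrides) -> NeuronModelParams:
    """A spiking preset sized like an immature, high-impedance neuron:
    sub-nS leak so a few pA of injected current reaches rheobase."""
    base = dict(C=25.0, gL=0.5, EL=-65.0, gNa=250.0, gK_fast=5.0,
                gK_slow=15.0, ENa=45.0, noise_sd=0.0, seed=0)
    base.update(overrides)
    return NeuronModelParams(**base)


# -- gating kinetics -------------------------------------------------------

def _vtrap(x: np.ndarray, k: float) -> np.ndarray:
    """x / (1 - exp(-x/k)), with the removable singularity at x = 0 filled."""
    x = np.asarray(x, dtype=float)
    out = np.where(np.abs(x) < 1e-7, k * (1.0 + x / (2.0 * k)),
                   x / -np.expm1(-np.where(np.abs(x) < 1e-7, 1.0, x) / k))
    return out


def _rates(v, v_shift):
    v = np.asarray(v, dtype=float) - v_shift
    am = 0.1 * _vtrap(v + 40.0, 10.0)
    bm = 4.0 * np.exp(-(v + 65.0) / 18.0)
    ah = 0.07 * np.exp(-(v + 65.0) / 20.0)
    bh = 1.0 / (1.0 + np.exp(-(v + 35.0) / 10.0))
    an = 0.01 * _vtrap(v + 55.0, 10.0)
    bn = 0.125 * np.exp(-(v + 65.0) / 80.0)
    return am, bm, ah, bh, an, bn


def _atype_steady(v, v_shift):
    v = np.asarray(v, dtype=float) - v_shift
    a_inf = 1.0 / (1.0 + np.exp(-(v + 40.0) / 8.5))
    b_inf = 1.0 / (1.0 + np.exp((v + 70.0) / 6.0))
    return a_inf, b_inf


def steady_state_gates(v: float, params: NeuronModelParams) -> dict[str, float]:
    """Equilibrium values of all gates at a fixed membrane potential."""
    am, bm, ah, bh, an, bn = _rates(v, params.v_shift)
    a_inf, b_inf = _atype_steady(v, params.v_shift)
    return {
        "m": float(am / (am + bm)),
        "h": float(ah / (ah + bh)),
        "n": float(an / (an + bn)),
        "a": float(a_inf),
        "b": float(b_inf),
    }


def _gate_tau_inf(v: float, params: NeuronModelParams):
    """Per-gate (tau, x_inf) at a fixed voltage — basis of clamp dynamics."""
    am, bm, ah, bh, an, bn = _rates(v, params.v_shift)
    a_inf, b_inf = _atype_steady(v, params.v_shift)
    return {
        "m": (1.0 / (am + bm), am / (am + bm)),
        "h": (1.0 / (ah + bh), ah / (ah + bh)),
        "n": (1.0 / (an + bn), an / (an + bn)),
        "a": (params.tau_a, a_inf),
        "b": (params.tau_b, b_inf),
    }


def ionic_currents(v, gates, params: NeuronModelParams):
    """(i_na, i_k_fast, i_k_slow, i_leak) in pA, outward positive."""
    i_na = params.gNa * gates["m"] ** 3 * gates["h"] * (v - params.ENa)
    i_kf = params.gK_fast * gates["a"] ** 4 * gates["b"] * (v - params.EK)
    i_ks = params.gK_slow * gates["n"] ** 4 * (v - params.EK)
    i_l = params.gL * (v - params.EL)
    return i_na, i_kf, i_ks, i_l


def holding_bias_current(params: NeuronModelParams, v_hold: float) -> float:
    """Bias current (pA) that makes ``v_hold`` a steady state of the model."""
    gates = steady_state_gates(v_hold, params)
    return float(sum(ionic_currents(v_hold, gates, params)))


def gating_current_at_clamp(params: NeuronModelParams, v_hold: float,
                            v_step: float, t_ms: np.ndarray) -> np.ndarray:
    """Closed-form clamp current (pA) at times ``t_ms`` after a step from
    ``v_hold`` (gates equilibrated) to ``v_step``.

    Every gate obeys x(t) = x_inf - (x_inf - x0) exp(-t/tau) at constant
    voltage; the ionic currents follow by direct evaluation.
    """
    t = np.asarray(t_ms, dtype=float)
    x0 = steady_state_gates(v_hold, params)
    ti = _gate_tau_inf(v_step, params)
    gates = {}
    for name, (tau, x_inf) in ti.items():
        gates[name] = x_inf - (x_inf - x0[name]) * np.exp(-t / tau)
    i_na, i_kf, i_ks, i_l = ionic_currents(v_step, gates, params)
    return i_na + i_kf + i_ks + i_l


# -- integration -----------------------------------------------------------

def _integrate_cc(params: NeuronModelParams, v0: float, gates0: dict,
                  i_inj: np.ndarray, dt: float, rng) -> np.ndarray:
    """Exponential-Euler current-clamp integration; returns V at each sample.

    Scalar ``math`` calls inside the loop: the update is inherently
    sequential and numpy scalar ufunc dispatch dominates runtime otherwise.
    """
    from math import exp

    n = i_inj.size
    v = np.empty(n)
    v[0] = v0
    if params.noise_sd > 0:
        drive = i_inj + rng.normal(0.0, params.noise_sd, size=n)
    else:
        drive = i_inj
    vs = params.v_shift
    gL, EL, C = params.gL, params.EL, params.C
    gNa_max, gKf_max, gKs_max = params.gNa, params.gK_fast, params.gK_slow
    ENa, EK = params.ENa, params.EK
    tau_a, tau_b = params.tau_a, params.tau_b
    m, h, ng, a, b = (gates0["m"], gates0["h"], gates0["n"],
                      gates0["a"], gates0["b"])
    vc = v0
    for k in range(1, n):
        u = vc - vs
        x = u + 40.0
        am = 0.1 * (x / (1.0 - exp(-x / 10.0)) if abs(x) > 1e-7 else 10.0)
        bm = 4.0 * exp(-(u + 65.0) / 18.0)
        ah = 0.07 * exp(-(u + 65.0) / 20.0)
        bh = 1.0 / (1.0 + exp(-(u + 35.0) / 10.0))
        x = u + 55.0
        an = 0.01 * (x / (1.0 - exp(-x / 10.0)) if abs(x) > 1e-7 else 10.0)
        bn = 0.125 * exp(-(u + 65.0) / 80.0)
        a_inf = 1.0 / (1.0 + exp(-(u + 40.0) / 8.5))
        b_inf = 1.0 / (1.0 + exp((u + 70.0) / 6.0))
        # exact per-step relaxation of each gate at the current voltage
        s = am + bm
        m = am / s + (m - am / s) * exp(-dt * s)
        s = ah + bh
        h = ah / s + (h - ah / s) * exp(-dt * s)
        s = an + bn
        ng = an / s + (ng - an / s) * exp(-dt * s)
        a = a_inf + (a - a_inf) * exp(-dt / tau_a)
        b = b_inf + (b - b_inf) * exp(-dt / tau_b)
        g_na = gNa_max * m * m * m * h
        g_kf = gKf_max * a * a * a * a * b
        g_ks = gKs_max * ng * ng * ng * ng
        g_tot = gL + g_na + g_kf + g_ks
        e_eff = (gL * EL + g_na * ENa + (g_kf + g_ks) * EK + drive[k]) / g_tot
        vc = e_eff + (vc - e_eff) * exp(-g_tot * dt / C)
        v[k] = vc
    return v


def simulate_current_clamp(params: NeuronModelParams,
                           protocol: StepProtocol | None = None) -> SweepSet:
    """Run the full current-step family and return one voltage sweep per step.

    The holding bias current is solved from the model's steady state at the
    protocol's holding potential, then annotated on the protocol so the
    exclusion rule (|holding| > 50 pA) downstream sees the true value.
    """
    if protocol is None:
        protocol = StepProtocol()
    if params.C <= 0:
        raise InvalidParameterError("capacitance C must be > 0")
    if protocol.sampling_interval <= 0:
        raise InvalidParameterError("sampling interval must be > 0")

    i_hold = holding_bias_current(params, protocol.holding_potential)
    protocol = replace(protocol, holding_current=i_hold)
    dt = protocol.sampling_interval
    n_pre = int(round(protocol.pre_duration / dt))
    n_step = int(round(protocol.step_duration / dt))
    n_post = int(round(protocol.post_duration / dt))
    n = n_pre + n_step + n_post
    gates0 = steady_state_gates(protocol.holding_potential, params)
    t = np.arange(n) * dt * 1e-3  # s

    sweeps = []
    for k, i_step in enumerate(protocol.step_currents()):
        rng = np.random.default_rng([params.seed, k])
        i_inj = np.full(n, i_hold)
        i_inj[n_pre:n_pre + n_step] = i_step
        v = _integrate_cc(params, protocol.holding_potential, gates0, i_inj, dt, rng)
        sweeps.append(Sweep(
            t, v, mode=CURRENT_CLAMP, command_level=float(i_step),
            metadata={
                "i_pre_pA": i_hold,
                "i_step_pA": float(i_step),
                "step_window_s": [n_pre * dt * 1e-3, (n_pre + n_step) * dt * 1e-3],
            }))
    return SweepSet(sweeps, protocol=protocol,
                    metadata={"seed": params.seed, "model": "hh_single_compartment"})


def simulate_zero_current(params: NeuronModelParams, duration_ms: float = 1000.0,
                          sampling_interval: float = 0.05) -> Sweep:
    """Free membrane potential at zero injected current (resting epoch)."""
    if duration_ms <= 0 or sampling_interval <= 0:
        raise InvalidParameterError("duration and sampling interval must be > 0")
    dt = sampling_interval
    n = int(round(duration_ms / dt))
    rng = np.random.default_rng([params.seed, 0x7e57])
    gates0 = steady_state_gates(params.EL, params)
    v = _integrate_cc(params, params.EL, gates0, np.zeros(n), dt, rng)
    t = np.arange(n) * dt * 1e-3
    return Sweep(t, v, mode=CURRENT_CLAMP, command_level=0.0,
                 metadata={"i_pre_pA": 0.0, "i_step_pA": 0.0})


def simulate_voltage_clamp(params: NeuronModelParams,
                           steps: list[float] | np.ndarray,
                           holding: float = -60.0,
                           step_duration: float = 400.0,
                           pre_duration: float = 100.0,
                           sampling_interval: float = 0.05) -> SweepSet:
    """Clamp-current sweeps for a family of command voltages.

    The pipette current is evaluated from the closed-form gate relaxation at
    the (constant) clamped voltage; the capacitive transient of an ideal
    clamp is instantaneous and is not modelled here (see
    :func:`simulate_capacitance_test` for the RC transient used by the
    capacitance estimator).
    """
    steps = np.asarray(steps, dtype=float)
    if not np.all(np.isfinite(steps)):
        raise InvalidParameterError("command voltages must be finite")
    if sampling_interval <= 0:
        raise InvalidParameterError("sampling interval must be > 0")
    if params.C <= 0:
        raise InvalidParameterError("capacitance C must be > 0")
    dt = sampling_interval
    n_pre = int(round(pre_duration / dt))
    n_step = int(round(step_duration / dt))
    n = n_pre + n_step
    t = np.arange(n) * dt * 1e-3
    gates_hold = steady_state_gates(holding, params)
    i_hold = float(sum(ionic_currents(holding, gates_hold, params)))

    sweeps = []
    for k, v_step in enumerate(steps):
        rng = np.random.default_rng([params.seed, 0xC1A, k])
        i = np.full(n, i_hold)
        # per-sample exponential-Euler gate updates at the clamped voltage
        # (the closed-form evaluator in gating_current_at_clamp is kept as an
        # independent oracle and is not called here)
        v = float(v_step)
        ti = _gate_tau_inf(v, params)
        step_i = np.empty(n_step)
        m, h, ng, a, b = (gates_hold[x] for x in "mhnab")
        (tau_m, m_inf), (tau_h, h_inf), (tau_n, n_inf) = ti["m"], ti["h"], ti["n"]
        (tau_a, a_inf), (tau_b, b_inf) = ti["a"], ti["b"]
        dm, dh, dn = (np.exp(-dt / tau_m), np.exp(-dt / tau_h),
                      np.exp(-dt / tau_n))
        da, db = np.exp(-dt / ti["a"][0]), np.exp(-dt / ti["b"][0])
        dna, dkf, dks = v - params.ENa, v - params.EK, v - params.EK
        i_leak = params.gL * (v - params.EL)
        for s in range(n_step):
            m = m_inf + (m - m_inf) * dm
            h = h_inf + (h - h_inf) * dh
            ng = n_inf + (ng - n_inf) * dn
            a = a_inf + (a - a_inf) * da
            b = b_inf + (b - b_inf) * db
            step_i[s] = (params.gNa * m * m * m * h * dna
                         + params.gK_fast * a * a * a * a * b * dkf
                         + params.gK_slow * ng * ng * ng * ng * dks
                         + i_leak)
        i[n_pre:] = step_i
        if params.noise_sd > 0:
            i = i + rng.normal(0.0, params.noise_sd, size=n)
        sweeps.append(Sweep(
            t, i, mode=VOLTAGE_CLAMP, command_level=float(v_step),
            metadata={
                "holding_mV": holding,
                "onset_s": n_pre * dt * 1e-3,
                "step_end_s": n * dt * 1e-3,
                "step_duration_ms": step_duration,
            }))
    return SweepSet(sweeps, protocol=None,
                    metadata={"seed": params.seed, "holding_mV": holding,
                              "clamp": "voltage"})


def simulate_capacitance_test(C: float = 30.0, Rm: float = 1.0, dV: float = -5.0,
                              Rs: float = 0.005, duration_ms: float = 20.0,
                              pre_ms: float = 5.0, sampling_interval: float = 0.01,
                              noise_sd: float = 0.0, seed: int = 0) -> Sweep:
    """Analytic RC transient of a small voltage-clamp test step.

    Circuit: series resistance ``Rs`` (GOhm) into membrane ``Rm`` (GOhm)
    parallel with ``C`` (pF).  I(t) = I_ss + (I_0 - I_ss) exp(-t/tau) with
    I_0 = dV/Rs, I_ss = dV/(Rs+Rm), tau = C * Rs*Rm/(Rs+Rm)  [GOhm*pF = ms].
    """
    if C <= 0 or Rm <= 0 or Rs <= 0:
        raise InvalidParameterError("C, Rm, Rs must be > 0")
    dt = sampling_interval
    n_pre = int(round(pre_ms / dt))
    n_step = int(round(duration_ms / dt))
    n = n_pre + n_step
    t_ms = np.arange(n) * dt
    i = np.zeros(n)
    tau = C * Rs * Rm / (Rs + Rm)
    i0 = dV / Rs
    iss = dV / (Rs + Rm)
    t_rel = t_ms[n_pre:] - t_ms[n_pre]
    i[n_pre:] = iss + (i0 - iss) * np.exp(-t_rel / tau)
    if noise_sd > 0:
        i = i + np.random.default_rng(seed).normal(0.0, noise_sd, size=n)
    return Sweep(t_ms * 1e-3, i, mode=VOLTAGE_CLAMP, command_level=dV,
                 metadata={"onset_s": n_pre * dt * 1e-3, "dV_mV": dV,
                           "test": "capacitance"})
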