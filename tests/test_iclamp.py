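import numpy as np
import pytest

from twinephys import iclamp
from twinephys.core import (
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
from twinephys.synth import (
    NeuronModelParams,
    simulate_capacitance_test,
    simulate_current_clamp,
    simulate_voltage_clamp,
    simulate_zero_current,
)

FS = 20_000.0
DT = 1.0 / FS


def make_sweep(y, mode=CURRENT_CLAMP, **meta):
    t = np.arange(len(y)) * DT
    return Sweep(t, np.asarray(y, float), mode=mode, metadata=meta)


def gaussian_spike_sweep(threshold=-45.0, amp=60.0, sigma_ms=0.5,
                         center_ms=10.0, total_ms=30.0):
    t_ms = np.arange(0.0, total_ms, DT * 1e3)
    v = threshold + amp * np.exp(-((t_ms - center_ms) ** 2)
                                 / (2 * sigma_ms ** 2))
    return make_sweep(v)


class TestDetectSpikes:
    def test_flat_trace_no_spikes(self):
        sw = make_sweep(np.full(4000, -60.0))
        assert len(iclamp.detect_spikes(sw)) == 0

    def test_single_synthetic_ap_found_at_peak(self):
        sw = gaussian_spike_sweep(threshold=-50.0, amp=62.0)
        peaks = iclamp.detect_spikes(sw)
        assert len(peaks) == 1
        assert peaks[0] == np.argmax(sw.y)

    def test_voltage_clamp_sweep_rejected(self):
        sw = make_sweep(np.zeros(100), mode=VOLTAGE_CLAMP)
        with pytest.raises(ClampModeError):
            iclamp.detect_spikes(sw)


class TestCountTotalEvokedAps:
    def test_all_subthreshold_counts_zero(self):
        proto = StepProtocol(n_steps=4)
        sweeps = SweepSet([make_sweep(np.full(2000, -60.0)) for _ in range(4)],
                          protocol=proto)
        total, excl = iclamp.count_total_evoked_aps(sweeps)
        assert total == 0 and excl is None

    def test_holding_above_50pA_excluded(self):
        proto = StepProtocol(n_steps=2, holding_current=60.0)
        sweeps = SweepSet([make_sweep(np.full(2000, -60.0)) for _ in range(2)],
                          protocol=proto)
        total, excl = iclamp.count_total_evoked_aps(sweeps)
        assert total is None
        assert excl.excluded and excl.exclusion_reason == "holding>50pA"

    def test_negative_holding_also_excluded(self):
        proto = StepProtocol(n_steps=1, holding_current=-51.0)
        sweeps = SweepSet([make_sweep(np.full(2000, -60.0))], protocol=proto)
        _, excl = iclamp.count_total_evoked_aps(sweeps)
        assert excl is not None

    def test_missing_sweeps_raise(self):
        proto = StepProtocol(n_steps=5)
        sweeps = SweepSet([make_sweep(np.full(100, -60.0))], protocol=proto)
        with pytest.raises(ProtocolMismatchError):
            iclamp.count_total_evoked_aps(sweeps)

    def test_simulated_count_equals_per_sweep_sum(self, excitable_sweepset):
        total, _ = iclamp.count_total_evoked_aps(excitable_sweepset)
        per_sweep = 0
        for sw in excitable_sweepset:
            t0, t1 = sw.metadata["step_window_s"]
            per_sweep += len(iclamp.detect_spikes(sw.window(t0, t1)))
        assert total == per_sweep > 0


class TestFirstEvokedAp:
    @staticmethod
    def _family(spiking_sweeps, n=10):
        sweeps = []
        for i in range(n):
            if i in spiking_sweeps:
                sw = gaussian_spike_sweep(center_ms=15.0)
            else:
                sw = make_sweep(np.full(600, -60.0))
            sw.command_level = float(i)  # ordered injected currents
            sweeps.append(sw)
        return SweepSet(sweeps)

    def test_spikes_only_in_sweep_7(self):
        win = iclamp.first_evoked_ap(self._family({7}))
        assert win.metadata["source_sweep"] == 7

    def test_lowest_current_sweep_wins(self):
        win = iclamp.first_evoked_ap(self._family({5, 9}))
        assert win.metadata["source_sweep"] == 5

    def test_no_spikes_raises(self):
        with pytest.raises(NoSpikeError):
            iclamp.first_evoked_ap(self._family(set()))

    def test_known_rheobase_sweep_selected(self, excitable_sweepset):
        # ground-truth rheobase: first sweep whose voltage reaches above the
        # detector's peak criterion
        rheo = next(i for i, sw in enumerate(excitable_sweepset)
                    if sw.y.max() > -10.0)
        win = iclamp.first_evoked_ap(excitable_sweepset)
        assert win.metadata["source_sweep"] == rheo


class TestSpikeThreshold:
    def test_piecewise_onset_found_within_one_sample(self):
        # flat, then quadratic onset at t_k, then linear rise to a peak:
        # d2V/dt2 has its unique maximum inside the quadratic bend
        t_ms = np.arange(0.0, 20.0, DT * 1e3)
        k_ms, bend_ms = 10.0, 1.0
        v = np.full_like(t_ms, -60.0)
        bend = (t_ms >= k_ms) & (t_ms < k_ms + bend_ms)
        rise = t_ms >= k_ms + bend_ms
        v[bend] = -60.0 + 40.0 * ((t_ms[bend] - k_ms) / bend_ms) ** 2
        slope = 80.0 / bend_ms
        v[rise] = -20.0 + slope * (t_ms[rise] - k_ms - bend_ms)
        v = np.minimum(v, 30.0)
        sw = make_sweep(v)
        thr = iclamp.spike_threshold(sw)
        v_at_onset = -60.0
        assert thr == pytest.approx(v_at_onset, abs=3.0)

    def test_pure_linear_ramp_undefined(self):
        t_ms = np.arange(0.0, 10.0, DT * 1e3)
        sw = make_sweep(-60.0 + 5.0 * t_ms)
        with pytest.raises(UndefinedThresholdError):
            iclamp.spike_threshold(sw)

    def test_flat_trace_undefined(self):
        sw = make_sweep(np.full(1000, -60.0))
        with pytest.raises(UndefinedThresholdError):
            iclamp.spike_threshold(sw)

    def test_simulated_ap_matches_dense_grid_oracle(self):
        # oracle: same criterion on a 5x finer simulation with raw (no
        # smoothing) finite differences
        from twinephys.iclamp import first_evoked_ap
        params = NeuronModelParams(C=25.0, gL=0.5, EL=-65.0, gNa=250.0,
                                   gK_fast=5.0, gK_slow=15.0, ENa=45.0)
        proto = StepProtocol(n_steps=6, first_step_offset=3.0,
                             step_increment=3.0)
        wave = first_evoked_ap(simulate_current_clamp(params, proto))
        thr = iclamp.spike_threshold(wave)

        fine = StepProtocol(n_steps=6, first_step_offset=3.0,
                            step_increment=3.0, sampling_interval=0.01)
        wave_f = first_evoked_ap(simulate_current_clamp(params, fine))
        y = wave_f.y
        dt = wave_f.dt_ms
        d2 = np.diff(y, 2) / dt ** 2
        ipk = int(np.argmax(y))
        seg = d2[:ipk]
        cand = [i for i in range(1, len(seg) - 1)
                if seg[i] >= seg[i - 1] and seg[i] >= seg[i + 1]
                and seg[i] >= 0.2 * seg.max()]
        thr_oracle = y[cand[0] + 1]
        assert thr == pytest.approx(thr_oracle, abs=1.0)


class TestSpikeShape:
    def test_gaussian_fwhm_closed_form(self):
        sigma = 0.5
        sw = gaussian_spike_sweep(threshold=-45.0, amp=60.0, sigma_ms=sigma)
        feats = iclamp.spike_shape(sw, threshold=-45.0)
        expected = 2 * sigma * np.sqrt(2 * np.log(2))
        assert feats.width == pytest.approx(expected, rel=0.01)
        assert feats.amplitude == pytest.approx(60.0, rel=1e-6)

    def test_triangular_spike_width_by_similar_triangles(self):
        t_ms = np.arange(0.0, 40.0, DT * 1e3)
        thr, peak = -50.0, 10.0
        v = np.full_like(t_ms, thr - 5.0)
        up = (t_ms >= 10.0) & (t_ms < 11.0)
        down = (t_ms >= 11.0) & (t_ms < 13.0)
        v[up] = thr + (peak - thr) * (t_ms[up] - 10.0) / 1.0
        v[down] = peak - (peak - thr + 5.0) * (t_ms[down] - 11.0) / 2.0
        v[t_ms >= 13.0] = thr - 5.0
        feats = iclamp.spike_shape(make_sweep(v), threshold=thr)
        # rising 1 ms + falling 2 ms triangle: half-width spans half of each
        assert feats.width == pytest.approx(1.5, abs=2 * DT * 1e3)

    def test_fahp_by_definition(self):
        # V drops to threshold - 10 mV exactly 5 ms after the re-crossing
        t_ms = np.arange(0.0, 30.0, DT * 1e3)
        thr = -45.0
        v = np.full_like(t_ms, thr - 10.0)
        spike = (t_ms >= 5.0) & (t_ms <= 7.0)
        v[spike] = thr + 50.0 * np.sin(np.pi * (t_ms[spike] - 5.0) / 2.0)
        feats = iclamp.spike_shape(make_sweep(v), threshold=thr)
        assert feats.fahp == pytest.approx(10.0, abs=1e-6)

    def test_window_too_short_for_fahp(self):
        sw = gaussian_spike_sweep(center_ms=10.0, total_ms=12.0)
        with pytest.raises(AnalysisWindowError):
            iclamp.spike_shape(sw, threshold=-45.0)

    def test_shape_invariant_to_dc_offset(self):
        sw = gaussian_spike_sweep()
        base = iclamp.spike_shape(sw, threshold=-45.0)
        shifted = Sweep(sw.t, sw.y + 17.3, mode=sw.mode)
        moved = iclamp.spike_shape(shifted, threshold=-45.0 + 17.3)
        assert moved.amplitude == pytest.approx(base.amplitude)
        assert moved.width == pytest.approx(base.width)
        assert moved.fahp == pytest.approx(base.fahp)


class TestInputConductance:
    def test_symmetric_currents_give_1_gohm(self):
        pp = iclamp.input_conductance(-10.0, 10.0)
        assert pp.input_resistance == pytest.approx(1.0)
        assert pp.input_conductance == pytest.approx(1.0)

    def test_delta_4p8_pA_gives_0p24_nS(self):
        pp = iclamp.input_conductance(0.0, 4.8)
        assert pp.input_conductance == pytest.approx(0.24)

    def test_gin_times_rm_is_one(self):
        for d in (0.5, 4.8, 11.2, 30.0):
            pp = iclamp.input_conductance(0.0, d)
            assert pp.input_conductance * pp.input_resistance == pytest.approx(1.0)

    def test_non_physical_difference_rejected(self):
        with pytest.raises(InvalidParameterError):
            iclamp.input_conductance(10.0, 10.0)
        with pytest.raises(InvalidParameterError):
            iclamp.input_conductance(10.0, 5.0)

    def test_leak_only_simulated_cell_recovered(self):
        gL = 0.56
        params = NeuronModelParams(C=30.0, gL=gL, EL=-46.3)
        ss = simulate_voltage_clamp(params, [-70.0, -50.0], step_duration=200.0)
        i70 = iclamp.steady_state_current(ss[0])
        i50 = iclamp.steady_state_current(ss[1])
        pp = iclamp.input_conductance(i70, i50)
        assert pp.input_conductance == pytest.approx(gL, rel=1e-3)


class TestRestingPotential:
    def test_constant_trace(self):
        sw = make_sweep(np.full(20_000, -52.8), i_pre_pA=0.0, i_step_pA=0.0)
        assert iclamp.resting_potential(sw) == pytest.approx(-52.8)

    def test_leak_only_with_noise_within_half_mV(self):
        params = NeuronModelParams(C=30.0, gL=0.5, EL=-46.3, noise_sd=5.0,
                                   seed=3)
        sw = simulate_zero_current(params, duration_ms=800.0)
        assert iclamp.resting_potential(sw) == pytest.approx(-46.3, abs=0.5)

    def test_injected_current_throughout_rejected(self):
        sw = make_sweep(np.full(1000, -50.0), i_pre_pA=20.0, i_step_pA=20.0)
        with pytest.raises(InvalidParameterError):
            iclamp.resting_potential(sw)

    def test_voltage_clamp_rejected(self):
        sw = make_sweep(np.zeros(1000), mode=VOLTAGE_CLAMP)
        with pytest.raises(ClampModeError):
            iclamp.resting_potential(sw)


class TestCapacitance:
    def test_rc_transient_30pF(self):
        sw = simulate_capacitance_test(C=30.0, Rm=1.0, dV=-5.0)
        assert iclamp.capacitance(sw) == pytest.approx(30.0, rel=0.02)

    def test_rc_transient_60pF(self):
        sw = simulate_capacitance_test(C=60.0, Rm=1.0, dV=-5.0)
        assert iclamp.capacitance(sw) == pytest.approx(60.0, rel=0.02)

    def test_zero_transient_gives_zero(self):
        t = np.arange(2000) * DT
        sw = Sweep(t, np.full(2000, -5.0), mode=VOLTAGE_CLAMP,
                   command_level=-5.0, metadata={"onset_s": 0.0, "dV_mV": -5.0})
        assert iclamp.capacitance(sw) == pytest.approx(0.0, abs=1e-9)

    def test_current_clamp_rejected(self):
        sw = make_sweep(np.zeros(100))
        with pytest.raises(ClampModeError):
            iclamp.capacitance(sw, dV=-5.0)


class TestLeakOnlyRecoveryBundle:
    """Joint (Gin, Vrest, C) recovery on leak-only cells."""

    def test_noiseless_relative_error_below_1_percent(self):
        gL, EL, C = 0.24, -52.8, 55.0
        params = NeuronModelParams(C=C, gL=gL, EL=EL)
        ss = simulate_voltage_clamp(params, [-70.0, -50.0], step_duration=200.0)
        pp = iclamp.input_conductance(iclamp.steady_state_current(ss[0]),
                                      iclamp.steady_state_current(ss[1]))
        vrest = iclamp.resting_potential(simulate_zero_current(params, 800.0))
        cap = iclamp.capacitance(simulate_capacitance_test(C=C, Rm=1 / gL))
        assert pp.input_conductance == pytest.approx(gL, rel=0.01)
        assert vrest == pytest.approx(EL, rel=0.01)
        assert cap == pytest.approx(C, rel=0.02)

    def test_physiological_noise_relative_error_below_5_percent(self):
        gL, EL = 0.46, -46.3
        errs_g, errs_v = [], []
        for seed in range(5):
            params = NeuronModelParams(C=45.0, gL=gL, EL=EL, noise_sd=5.0,
                                       seed=seed)
            ss = simulate_voltage_clamp(params, [-70.0, -50.0],
                                        step_duration=200.0)
            pp = iclamp.input_conductance(
                iclamp.steady_state_current(ss[0]),
                iclamp.steady_state_current(ss[1]))
            vrest = iclamp.resting_potential(
                simulate_zero_current(params, 800.0))
            errs_g.append(abs(pp.input_conductance - gL) / gL)
            errs_v.append(abs(vrest - EL) / abs(EL))
        assert np.mean(errs_g) < 0.05
        assert np.mean(errs_v) < 0.05
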