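"""Intrinsic current-clamp measures against constructed traces, closed
forms, and simulator ground truth."""

import math

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from natalmap.intrinsic import (
    ap_waveform_features,
    capacitance,
    detect_spikes,
    fi_curve_and_rheobase,
    fit_membrane_time_constant,
    measure_input_resistance,
    measure_rebound,
    measure_sag,
)
from natalmap.sweeps import StepProtocol, SweepSet
from natalmap.synth import NeuronParams, simulate_current_clamp, spike_waveform_sweep

DT = 1e-4


def _linear_iv_sweeps(rm_mohm=100.0, noise_sd=0.0, seed=None):
    """Constructed sweeps with exactly ohmic steady states (instant steps)."""
    proto = StepProtocol(step_onset=0.2, step_duration=0.5,
                         amplitudes=tuple(float(a) for a in range(-100, -19, 20)),
                         baseline_window=(0.0, 0.2))
    n = round(0.8 / DT)
    i_on, i_off = round(0.2 / DT), round(0.7 / DT)
    data = np.full((len(proto.amplitudes), n), -65.0)
    for i, amp in enumerate(proto.amplitudes):
        data[i, i_on:i_off] += amp * rm_mohm / 1000.0
    if noise_sd:
        data += np.random.default_rng(seed).normal(0, noise_sd, data.shape)
    return SweepSet(dt=DT, data=data, protocol=proto)


class TestInputResistance:
    def test_exact_linear_data(self):
        assert measure_input_resistance(_linear_iv_sweeps()) == pytest.approx(100.0)

    def test_noisy_data_within_2pct(self):
        for seed in range(100):
            rm = measure_input_resistance(_linear_iv_sweeps(noise_sd=0.2, seed=seed))
            assert rm == pytest.approx(100.0, rel=0.02)

    def test_sweep_with_spike_excluded(self):
        sw = _linear_iv_sweeps()
        spiky = sw.data.copy()
        spiky[0, 3000:3005] = 20.0  # fake spike in the -100 pA sweep
        with_spike = SweepSet(dt=DT, data=spiky, protocol=sw.protocol)
        clean_subset = sw.select(range(1, sw.n_sweeps))
        assert measure_input_resistance(with_spike) == pytest.approx(
            measure_input_resistance(clean_subset))

    def test_errors(self):
        sw = _linear_iv_sweeps()
        with pytest.raises(ValueError, match=">= 2"):
            measure_input_resistance(sw.select([0]))
        same_amp = StepProtocol(0.2, 0.5, (-20.0, -20.0), (0.0, 0.2))
        dup = SweepSet(dt=DT, data=np.tile(sw.data[-1], (2, 1)), protocol=same_amp)
        with pytest.raises(ValueError, match="current spread"):
            measure_input_resistance(dup)


class TestMembraneTimeConstant:
    def _pulse_sweeps(self, trace):
        proto = StepProtocol(0.1, 0.5, (-20.0,), (0.0, 0.1))
        return SweepSet(dt=DT, data=trace[None, :], protocol=proto)

    def test_monoexponential_degenerate_case(self):
        t = np.arange(int(0.7 / DT)) * DT
        v = np.full_like(t, -65.0)
        m = t >= 0.1
        v[m] = -67.0 + 2.0 * np.exp(-(t[m] - 0.1) / 0.020)
        tau, diag = fit_membrane_time_constant(self._pulse_sweeps(v))
        assert tau == pytest.approx(20.0, rel=0.02)

    def test_planted_biexponential(self):
        """A1=1 mV/tau1=2 ms fast + A2=4 mV/tau2=25 ms slow -> tau_m = 25 ms."""
        t = np.arange(int(0.7 / DT)) * DT
        v = np.full_like(t, -65.0)
        m = t >= 0.1
        tm = (t[m] - 0.1) * 1e3
        v[m] = -70.0 + 1.0 * np.exp(-tm / 2.0) + 4.0 * np.exp(-tm / 25.0)
        tau, diag = fit_membrane_time_constant(self._pulse_sweeps(v))
        assert tau == pytest.approx(25.0, rel=0.05)
        assert diag["converged"]

    def test_recovers_simulated_rc(self, passive_params):
        proto = StepProtocol(0.2, 0.5, (-20.0,), (0.0, 0.2))
        sw = simulate_current_clamp(passive_params, proto, dt=DT)
        tau, _ = fit_membrane_time_constant(sw)
        assert tau == pytest.approx(passive_params.tau_m, rel=0.02)


class TestCapacitance:
    @pytest.mark.parametrize("tau,rm,expect", [(20.0, 100.0, 200.0), (10.0, 50.0, 200.0)])
    def test_unit_arithmetic(self, tau, rm, expect):
        assert capacitance(tau, rm) == pytest.approx(expect)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            capacitance(-1.0, 100.0)

    def test_recovery_chain(self, subthreshold_protocol):
        """Rm/tau/Cm recovered from a simulated 150 pF cell within 5%."""
        params = NeuronParams(r_m=120.0, c_m=150.0, g_h=0.0)
        proto20 = StepProtocol(0.2, 0.5, (-20.0,), (0.0, 0.2))
        rm = measure_input_resistance(
            simulate_current_clamp(params, subthreshold_protocol, dt=DT))
        tau, _ = fit_membrane_time_constant(
            simulate_current_clamp(params, proto20, dt=DT))
        assert capacitance(tau, rm) == pytest.approx(150.0, rel=0.05)


def _piecewise_sag_trace():
    """Baseline -65, early minimum -90, plateau -80 mV."""
    proto = StepProtocol(0.2, 1.0, (-200.0,), (0.0, 0.2))
    n = round(1.5 / DT)
    v = np.full(n, -65.0)
    i_on, i_off = round(0.2 / DT), round(1.2 / DT)
    v[i_on:i_off] = -80.0
    v[i_on:i_on + round(0.05 / DT)] = -90.0
    return SweepSet(dt=DT, data=v[None, :], protocol=proto)


class TestSagRebound:
    def test_piecewise_formula(self):
        assert measure_sag(_piecewise_sag_trace()) == pytest.approx(10.0)

    def test_passive_cell_has_no_sag_or_rebound(self, passive_params, sag_protocol):
        sw = simulate_current_clamp(passive_params, sag_protocol, dt=DT)
        assert abs(measure_sag(sw)) < 0.05
        assert abs(measure_rebound(sw)) < 0.05

    def test_ih_sag_and_rebound_match_ode_oracle(self, ih_params, sag_protocol):
        """Sag/rebound from the simulator agree with an implicit-solver trace."""
        sw = simulate_current_clamp(ih_params, sag_protocol, dt=DT)
        p = ih_params
        on, off = sag_protocol.step_onset, sag_protocol.step_end

        def rhs(t, y):
            v, h = y
            i_inj = -200.0 if on <= t < off else 0.0
            dv = (-(v - p.v_rest) * p.g_leak - p.g_h * h * (v - p.e_h) + i_inj) / p.c_m
            return [dv * 1e3, (p.h_inf(v) - h) / p.tau_h * 1e3]

        v0, h0 = p.resting_state()
        t_eval = sw.time
        sol = solve_ivp(rhs, (0, t_eval[-1]), [v0, h0], t_eval=t_eval,
                        method="Radau", max_step=DT, rtol=1e-8, atol=1e-10)
        oracle = SweepSet(dt=DT, data=sol.y[0][None, :], protocol=sag_protocol)
        assert measure_sag(sw) == pytest.approx(measure_sag(oracle), rel=0.02)
        assert measure_rebound(sw) == pytest.approx(measure_rebound(oracle), rel=0.02)
        assert measure_sag(sw) > 0.5 and measure_rebound(sw) > 0.2

    def test_sag_monotone_in_gh(self, sag_protocol):
        sags = []
        for g_h in (0.0, 1.0, 2.0, 4.0):
            params = NeuronParams(r_m=100.0, c_m=200.0, g_h=g_h)
            sags.append(measure_sag(simulate_current_clamp(params, sag_protocol, dt=DT)))
        assert all(b > a for a, b in zip(sags, sags[1:]))
        assert abs(sags[0]) < 0.05

    def test_depolarizing_step_rejected(self):
        sw = _piecewise_sag_trace()
        bad = SweepSet(dt=sw.dt, data=sw.data,
                       protocol=StepProtocol(0.2, 1.0, (200.0,), (0.0, 0.2)))
        with pytest.raises(ValueError, match="hyperpolarizing"):
            measure_sag(bad, sweep_index=0)

    def test_rebound_spike_flags_undefined(self):
        sw = _piecewise_sag_trace()
        data = sw.data.copy()
        data[0, int(1.25 / DT):int(1.25 / DT) + 10] = 10.0  # post-step spike
        spiked = SweepSet(dt=DT, data=data, protocol=sw.protocol)
        assert math.isnan(measure_rebound(spiked))


class TestSpikeDetection:
    def test_subthreshold_sweep_empty(self, passive_sweeps):
        assert detect_spikes(passive_sweeps.sweep(0), DT).n_spikes == 0

    def test_refractory_merges_close_crossings(self):
        v = np.full(200, -65.0)
        v[50] = 0.0
        v[55] = 0.0  # 0.5 ms later
        train = detect_spikes(v, DT)
        assert train.n_spikes == 1

    def test_if_simulation_counts_match_ground_truth(self):
        params = NeuronParams(r_m=100.0, c_m=200.0, v_thresh=-50.0, v_reset=-60.0)
        proto = StepProtocol(0.2, 1.0, (300.0,), (0.0, 0.2))  # 2x rheobase
        sw = simulate_current_clamp(params, proto, dt=DT)
        truth = sw.meta["ground_truth"]["spike_times"][0]
        assert detect_spikes(sw.sweep(0), DT).n_spikes == len(truth) > 0


class TestFiRheobase:
    @pytest.fixture()
    def if_sweeps(self):
        params = NeuronParams(v_rest=-65.0, r_m=100.0, c_m=200.0,
                              v_thresh=-50.0, v_reset=-60.0)
        proto = StepProtocol(0.2, 1.0, tuple(float(a) for a in range(40, 501, 40)),
                             baseline_window=(0.0, 0.2))
        return simulate_current_clamp(params, proto, dt=DT)

    def test_rheobase_first_step_above_analytic(self, if_sweeps):
        """Analytic rheobase 150 pA; on a 40 pA grid the measure reads 160."""
        _, rheo = fi_curve_and_rheobase(if_sweeps)
        analytic = if_sweeps.meta["ground_truth"]["analytic_rheobase_pa"]
        assert analytic == pytest.approx(150.0)
        assert rheo == 160.0
        assert analytic <= rheo <= analytic + 40.0

    def test_fi_curve_nondecreasing(self, if_sweeps):
        fi, _ = fi_curve_and_rheobase(if_sweeps)
        counts = [fi[a] for a in sorted(fi)]
        assert all(b >= a for a, b in zip(counts, counts[1:]))

    def test_no_spikes_flags_undefined(self, passive_sweeps):
        fi, rheo = fi_curve_and_rheobase(passive_sweeps)
        assert math.isnan(rheo)
        assert all(c == 0 for c in fi.values())


class TestApFeatures:
    AP_DT = 1e-5  # fine grid so the discrete curvature peak sits at threshold

    def test_threshold_at_constructed_inflection(self):
        v, gt = spike_waveform_sweep(dt=self.AP_DT, v_thresh=-45.0)
        feats = ap_waveform_features(v, self.AP_DT)
        assert feats.threshold_mv == pytest.approx(-45.0, abs=1.0)

    def test_amplitude_is_peak_minus_threshold(self):
        v, gt = spike_waveform_sweep(dt=self.AP_DT, v_thresh=-45.0, v_peak=35.0)
        feats = ap_waveform_features(v, self.AP_DT)
        assert feats.amplitude_mv == pytest.approx(80.0, abs=1.0)

    def test_fahp_depth(self):
        v, gt = spike_waveform_sweep(dt=self.AP_DT, v_fahp_min=-53.0)
        feats = ap_waveform_features(v, self.AP_DT)
        assert feats.fahp_mv == pytest.approx(gt["fahp_mv"], abs=1.0)

    def test_halfwidth_matches_dense_oracle(self):
        """Detector half-width equals interpolated half-level crossings."""
        v, gt = spike_waveform_sweep(dt=self.AP_DT)
        feats = ap_waveform_features(v, self.AP_DT)
        t = np.arange(v.size) * self.AP_DT * 1e3
        half = 0.5 * (feats.threshold_mv + gt["peak_mv"])
        above = np.flatnonzero(v >= half)
        rise = np.interp(half, [v[above[0] - 1], v[above[0]]], [t[above[0] - 1], t[above[0]]])
        j = above[-1]
        fall = np.interp(half, [v[j + 1], v[j]], [t[j + 1], t[j]])
        assert feats.halfwidth_ms == pytest.approx(fall - rise, abs=0.05)

    def test_triangular_spike_halfwidth_geometry(self):
        """Symmetric triangular spike of 2 ms base -> 1 ms half-width."""
        dt = 1e-5
        n_half = int(1e-3 / dt)
        up = np.linspace(-65.0, 35.0, n_half + 1)
        v = np.concatenate([np.full(3000, -65.0), up, up[-2::-1], np.full(3000, -65.0)])
        feats = ap_waveform_features(v, dt, search_ms=0.2)
        # threshold sits at the ramp onset (curvature kink): half level tracks it
        half_expected = (35.0 - 0.5 * (feats.threshold_mv + 35.0)) / 100.0 * 2.0
        assert feats.halfwidth_ms == pytest.approx(half_expected, rel=0.02)

    def test_truncated_spike_flagged(self):
        v = np.concatenate([np.full(500, -65.0), np.linspace(-65, 35, 100),
                            np.full(500, 35.0)])  # never descends
        feats = ap_waveform_features(v, 1e-5)
        assert feats.truncated and math.isnan(feats.halfwidth_ms)

    def test_no_spike_raises(self):
        with pytest.raises(ValueError, match="no spikes"):
            ap_waveform_features(np.full(1000, -65.0), 1e-4)


class TestOffsetInvariance:
    def test_baseline_referenced_measures_offset_invariant(self, ih_params, sag_protocol):
        sw = simulate_current_clamp(ih_params, sag_protocol, dt=DT)
        shifted = SweepSet(dt=DT, data=sw.data + 7.5, protocol=sw.protocol)
        assert measure_sag(shifted) == pytest.approx(measure_sag(sw), abs=1e-9)
        assert measure_rebound(shifted) == pytest.approx(measure_rebound(sw), abs=1e-9)

    def test_rm_offset_invariant(self):
        sw = _linear_iv_sweeps()
        shifted = SweepSet(dt=DT, data=sw.data + 12.0, protocol=sw.protocol)
        assert measure_input_resistance(shifted) == pytest.approx(
            measure_input_resistance(sw))

    def test_ap_threshold_shifts_with_offset(self):
        v, _ = spike_waveform_sweep(dt=1e-5)
        f0 = ap_waveform_features(v, 1e-5)
        f1 = ap_waveform_features(v + 5.0, 1e-5)
        assert f1.threshold_mv == pytest.approx(f0.threshold_mv + 5.0, abs=1e-9)
        assert f1.amplitude_mv == pytest.approx(f0.amplitude_mv, abs=1e-9)


class TestParameterRecoveryGrid:
    @pytest.mark.parametrize("rm", [50.0, 100.0, 200.0])
    @pytest.mark.parametrize("cm", [100.0, 200.0])
    def test_rm_cm_recovered_within_5pct(self, rm, cm, subthreshold_protocol):
        params = NeuronParams(r_m=rm, c_m=cm, g_h=0.0)
        sw = simulate_current_clamp(params, subthreshold_protocol, dt=DT)
        rm_hat = measure_input_resistance(sw)
        proto20 = StepProtocol(0.2, 0.5, (-20.0,), (0.0, 0.2))
        tau_hat, _ = fit_membrane_time_constant(
            simulate_current_clamp(params, proto20, dt=DT))
        assert rm_hat == pytest.approx(rm, rel=0.05)
        assert capacitance(tau_hat, rm_hat) == pytest.approx(cm, rel=0.05)
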