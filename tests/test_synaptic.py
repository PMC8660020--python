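"""PSC analysis against analytic kernels, frequency-response oracles, and
generator ground truth."""

import math

import numpy as np
import pytest
from scipy.optimize import brentq

from natalmap import synaptic as syn
from natalmap.sweeps import SweepSet
from natalmap.synth import (
    PscSimParams,
    kernel_peak_time,
    psc_kernel,
    simulate_evoked_psc,
    simulate_psc_trace,
)

DT = 1e-4


class TestLowpassFilter:
    def test_dc_unchanged(self):
        x = np.full(2000, 7.0)
        assert np.allclose(syn.lowpass_filter(x, DT), x)

    def test_passband_and_stopband(self):
        """Frequency response: <1% attenuation at 100 Hz, >90% at 4 kHz."""
        t = np.arange(20000) * DT
        for freq, bound, cmp in ((100.0, 0.01, "lt"), (4000.0, 0.90, "gt")):
            x = np.sin(2 * np.pi * freq * t)
            y = syn.lowpass_filter(x, DT)
            core = slice(2000, -2000)  # ignore edge transients
            atten = 1.0 - np.abs(y[core]).max() / np.abs(x[core]).max()
            assert (atten < bound) if cmp == "lt" else (atten > bound)

    def test_cutoff_above_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            syn.lowpass_filter(np.zeros(100), DT, cutoff_hz=6000.0)


class TestEventDetection:
    def test_zero_noise_single_event_exact(self):
        params = PscSimParams(rate=0.0, amp_mean=50.0, amp_sd=0.0, noise_sd=0.0,
                              duration=2.0)
        sweeps, _ = simulate_psc_trace(params, seed=0)
        trace = sweeps.sweep(0).copy()
        t_event = 1.0
        peak_t = t_event + kernel_peak_time(0.5, 5.0) * 1e-3
        k = psc_kernel((np.arange(trace.size) * DT - t_event) * 1e3, 0.5, 5.0)
        trace += -50.0 * k
        tbl = syn.detect_psc_events(trace, DT, polarity="inward", threshold_pa=10.0)
        assert tbl.n_events == 1
        assert tbl.times[0] == pytest.approx(peak_t, abs=1.5 * DT)
        assert tbl.amplitudes[0] == pytest.approx(-50.0, rel=0.02)

    def test_noise_only_false_event_rate(self):
        """At 5x the noise sd the filtered detector stays near-silent."""
        params = PscSimParams(rate=0.0, noise_sd=3.0, duration=20.0)
        false_events = 0
        for seed in range(40):
            sweeps, _ = simulate_psc_trace(params, seed=seed)
            filt = syn.lowpass_filter(sweeps.sweep(0), DT)
            false_events += syn.detect_psc_events(
                filt, DT, polarity="inward", threshold_pa=15.0).n_events
        assert false_events / 40 <= 1.0

    def test_recall_and_precision_on_planted_events(self):
        recalls, precisions = [], []
        params = PscSimParams(rate=1.0, amp_mean=50.0, amp_sd=5.0, noise_sd=3.0,
                              duration=20.0)
        for seed in range(10):
            sweeps, truth = simulate_psc_trace(params, seed=seed)
            filt = syn.lowpass_filter(sweeps.sweep(0), DT)
            tbl = syn.detect_psc_events(filt, DT, polarity="inward", threshold_pa=15.0)
            tt = truth["peak_time_s"].to_numpy()
            if not tt.size or not tbl.n_events:
                continue
            recalls.append(np.mean([np.abs(tbl.times - t).min() < 2e-3 for t in tt]))
            precisions.append(np.mean([np.abs(tt - t).min() < 2e-3 for t in tbl.times]))
        assert np.mean(recalls) >= 0.9
        assert np.mean(precisions) >= 0.9


class TestEventStatistics:
    def test_twelve_events_in_two_minutes(self):
        tables = [syn.PscEventTable(times=np.arange(1, 3) * 1.0,
                                    amplitudes=np.full(2, -30.0), polarity="inward")
                  for _ in range(6)]
        freq, amp = syn.event_statistics(tables, 120.0)
        assert freq == pytest.approx(12 / 120)
        assert amp == pytest.approx(30.0)

    def test_zero_events_flagged(self):
        empty = syn.PscEventTable(times=np.array([]), amplitudes=np.array([]),
                                  polarity="inward")
        freq, amp = syn.event_statistics([empty], 120.0)
        assert freq == 0.0 and math.isnan(amp)

    def test_simulated_rate_within_3se(self):
        params = PscSimParams(rate=2.0, amp_mean=60.0, noise_sd=3.0,
                              duration=20.0, n_sweeps=6)
        freqs = []
        for seed in range(5):
            sweeps, _ = simulate_psc_trace(params, seed=seed)
            tables = [syn.detect_psc_events(syn.lowpass_filter(sweeps.sweep(s), DT),
                                            DT, "inward", threshold_pa=20.0)
                      for s in range(6)]
            freqs.append(syn.event_statistics(tables, 120.0)[0])
        se = math.sqrt(2.0 / 120.0 / len(freqs))
        assert abs(np.mean(freqs) - 2.0) < 3 * se


@pytest.fixture(scope="module")
def kinetics(clean_psc):
    params, sweeps, events = clean_psc
    tbl = syn.detect_psc_events(sweeps.sweep(0), DT, "inward", threshold_pa=10.0)
    return syn.mean_event_kinetics(sweeps.sweep(0), DT, tbl)


class TestMeanEventKinetics:
    def test_tau_decay_recovered(self, kinetics):
        assert kinetics.tau_decay_ms == pytest.approx(5.0, rel=0.02)

    def test_rise_time_matches_root_found_crossings(self, kinetics):
        """10-90% rise equals the analytic kernel's crossing-time difference."""
        tp = kernel_peak_time(0.5, 5.0)
        f = lambda t, lvl: psc_kernel(np.array([t]), 0.5, 5.0)[0] - lvl
        t10 = brentq(f, 1e-9, tp, args=(0.1,))
        t90 = brentq(f, 1e-9, tp, args=(0.9,))
        assert kinetics.rise_10_90_ms == pytest.approx(t90 - t10, abs=0.1)

    def test_decay_90_37_matches_analytic(self, kinetics):
        tp = kernel_peak_time(0.5, 5.0)
        f = lambda t, lvl: psc_kernel(np.array([t]), 0.5, 5.0)[0] - lvl
        t90 = brentq(f, tp, 60.0, args=(0.9,))
        t37 = brentq(f, tp, 60.0, args=(0.37,))
        assert kinetics.decay_90_37_ms == pytest.approx(t37 - t90, rel=0.05)

    def test_area_matches_symbolic_integral(self, kinetics):
        """Trapezoidal area equals the closed-form kernel integral over the
        window: amp * (tau_d (1-e^(-T/tau_d)) - tau_r (1-e^(-T/tau_r))) / peak."""
        tr, td, big_t = 0.5, 5.0, 40.0
        tp = kernel_peak_time(tr, td)
        peak = math.exp(-tp / td) - math.exp(-tp / tr)
        integral = 50.0 * (td * (1 - math.exp(-big_t / td))
                           - tr * (1 - math.exp(-big_t / tr))) / peak
        assert kinetics.area_pa_ms == pytest.approx(integral, rel=0.01)

    def test_amplitude_scaling_properties(self, clean_psc):
        """Area scales linearly and half-width stays constant under scaling."""
        _, sweeps, _ = clean_psc
        x = sweeps.sweep(0)
        tbl = syn.detect_psc_events(x, DT, "inward", threshold_pa=10.0)
        k1 = syn.mean_event_kinetics(x, DT, tbl)
        tbl3 = syn.detect_psc_events(3.0 * x, DT, "inward", threshold_pa=30.0)
        k3 = syn.mean_event_kinetics(3.0 * x, DT, tbl3)
        assert k3.area_pa_ms == pytest.approx(3.0 * k1.area_pa_ms, rel=0.01)
        assert k3.halfwidth_ms == pytest.approx(k1.halfwidth_ms, rel=0.01)

    def test_edge_events_dropped_and_counted(self):
        x = np.zeros(round(1.0 / DT))
        k = psc_kernel(np.arange(round(0.05 / DT)) * DT * 1e3, 0.5, 5.0)
        x[:k.size] += -50.0 * k  # event at t=0: inside half a window of the edge
        x[5000:5000 + k.size] += -50.0 * k
        tp = round(kernel_peak_time(0.5, 5.0) * 1e-3 / DT)
        tbl = syn.PscEventTable(times=np.array([tp, 5000 + tp]) * DT,
                                amplitudes=np.array([-50.0, -50.0]), polarity="inward")
        kin = syn.mean_event_kinetics(x, DT, tbl)
        assert kin.n_events_averaged == 1 and kin.n_edge_dropped == 1


class TestEvokedResponse:
    def test_planted_amplitude_recovered(self):
        sw = simulate_evoked_psc((0.1,), (-120.0,), noise_sd=1.0, seed=1, n_sweeps=10)
        res = syn.evoked_response(sw, 0.1, polarity="inward")
        assert res.responded
        assert res.amplitude_pa == pytest.approx(-120.0, rel=0.02)

    def test_flat_trace_flagged_no_response(self):
        sw = simulate_evoked_psc((0.1,), (0.0,), noise_sd=1.0, seed=2)
        res = syn.evoked_response(sw, 0.1, polarity="inward")
        assert not res.responded and res.amplitude_pa == 0.0

    def test_two_peak_decay_fit_follows_last_peak(self):
        """tau is fit after the second peak: recovered tau tracks the second
        kernel's decay even when the first is much slower."""
        sw = simulate_evoked_psc((0.1, 0.15), (-80.0, -100.0), tau_rise=1.0,
                                 tau_decay=12.0, noise_sd=0.0, n_sweeps=1, seed=0)
        res = syn.evoked_response(sw, 0.1, polarity="inward", response_window_s=0.3)
        assert res.tau_decay_ms == pytest.approx(12.0, rel=0.1)


class TestPairedPulseRatio:
    def _two_pulse(self, a1, a2, tau_decay=5.0, interval=0.05, noise=0.0, seed=0):
        return simulate_evoked_psc((0.1, 0.1 + interval), (a1, a2), tau_rise=0.5,
                                   tau_decay=tau_decay, noise_sd=noise,
                                   n_sweeps=5, seed=seed)

    def test_constructed_ratio(self):
        sw = self._two_pulse(-100.0, -150.0)
        assert syn.paired_pulse_ratio(sw, (0.1, 0.15)) == pytest.approx(1.5, rel=0.01)

    def test_identical_pulses_full_decay_give_unity(self):
        sw = self._two_pulse(-100.0, -100.0, tau_decay=3.0)
        assert syn.paired_pulse_ratio(sw, (0.1, 0.15)) == pytest.approx(1.0, rel=0.02)

    def test_scale_invariance(self):
        sw = self._two_pulse(-100.0, -130.0, noise=0.5, seed=3)
        ppr1 = syn.paired_pulse_ratio(sw, (0.1, 0.15))
        scaled = SweepSet(dt=sw.dt, data=sw.data * 4.0, protocol=sw.protocol,
                          units=sw.units, meta=sw.meta)
        assert syn.paired_pulse_ratio(scaled, (0.1, 0.15)) == pytest.approx(ppr1)

    def test_riding_on_decay_matches_dense_oracle(self):
        """Slow first decay (tau 30 ms): peak2 from the common baseline equals
        the same rule applied to the dense analytic superposition."""
        tr, td = 0.5, 30.0
        sw = self._two_pulse(-100.0, -100.0, tau_decay=td)
        measured = syn.paired_pulse_ratio(sw, (0.1, 0.15))

        dt_f = 1e-6
        t = np.arange(0, 0.4, dt_f)
        lat = 2e-3
        y = 100.0 * psc_kernel((t - 0.1 - lat) * 1e3, tr, td) \
            + 100.0 * psc_kernel((t - 0.15 - lat) * 1e3, tr, td)
        p1 = y[(t > 0.1) & (t <= 0.145)].max()
        p2 = y[(t > 0.15) & (t <= 0.195)].max()
        assert measured == pytest.approx(p2 / p1, rel=0.01)
        assert measured > 1.0  # summation inflates the un-subtracted peak 2

    def test_subtract_decay_restores_unity(self):
        sw = self._two_pulse(-100.0, -100.0, tau_decay=30.0)
        ppr = syn.paired_pulse_ratio(sw, (0.1, 0.15), subtract_decay=True)
        assert ppr == pytest.approx(1.0, rel=0.05)

    def test_absent_first_peak_flagged(self):
        sw = self._two_pulse(0.0, 0.0, noise=0.0, seed=5)
        assert math.isnan(syn.paired_pulse_ratio(sw, (0.1, 0.15)))


class TestEiBalanceAndQc:
    def test_ei_ratios(self):
        bal = syn.ei_balance(e_amp=20.0, e_freq=1.0, i_amp=40.0, i_freq=4.0)
        assert bal.amp_ratio == pytest.approx(0.5)
        assert bal.freq_ratio == pytest.approx(0.25)

    def test_zero_denominator_flagged(self):
        bal = syn.ei_balance(20.0, 1.0, 0.0, 0.0)
        assert math.isnan(bal.amp_ratio) and math.isnan(bal.freq_ratio)

    def test_simulated_frequency_ratio(self):
        params_e = PscSimParams(rate=2.0, amp_mean=40.0, noise_sd=2.0, duration=20.0,
                                n_sweeps=3)
        params_i = PscSimParams(rate=1.0, amp_mean=40.0, noise_sd=2.0, duration=20.0,
                                n_sweeps=3, polarity="outward")
        ratios = []
        for seed in range(5):
            fe = self._measured_freq(params_e, seed, "inward")
            fi = self._measured_freq(params_i, seed + 100, "outward")
            ratios.append(fe / fi)
        se = 2.0 / math.sqrt(60 * len(ratios))  # rough Poisson SE on the ratio
        assert abs(np.mean(ratios) - 2.0) < 3 * max(se, 0.2)

    @staticmethod
    def _measured_freq(params, seed, polarity):
        sweeps, _ = simulate_psc_trace(params, seed=seed)
        tables = [syn.detect_psc_events(syn.lowpass_filter(sweeps.sweep(s), DT),
                                        DT, polarity, threshold_pa=15.0)
                  for s in range(params.n_sweeps)]
        return syn.event_statistics(tables, params.n_sweeps * params.duration)[0]

    def _qc_sweeps(self, peaks_pa):
        n = round(0.1 / DT)
        data = np.zeros((len(peaks_pa), n))
        i0 = round(0.01 / DT)
        for s, p in enumerate(peaks_pa):
            data[s, i0:i0 + 10] = -p  # capacitive transient
        return SweepSet(dt=DT, data=data, units="pA")

    def test_rs_from_ohms_law(self):
        qc = syn.series_resistance_qc(self._qc_sweeps([250.0, 250.0]), 0.01)
        assert qc.rs_mean_mohm == pytest.approx(20.0)
        assert qc.passed

    def test_mean_above_30_fails(self):
        qc = syn.series_resistance_qc(self._qc_sweeps([143.0, 143.0]), 0.01)
        assert qc.rs_mean_mohm == pytest.approx(35.0, abs=0.1)
        assert not qc.passed

    def test_variation_above_20pct_fails(self):
        # 5 mV / 250 pA = 20 MΩ, 5 mV / ~192 pA = 26 MΩ -> variation 26%
        qc = syn.series_resistance_qc(self._qc_sweeps([250.0, 5000.0 / 26.0]), 0.01)
        assert qc.variation_pct == pytest.approx(26.0, abs=0.5)
        assert not qc.passed

    def test_polarity_contradicting_holding_rejected(self):
        sw = simulate_evoked_psc((0.1,), (-120.0,), seed=0)
        sw.meta["holding_mv"] = 0.0  # glutamate reversal -> outward expected
        with pytest.raises(ValueError, match="polarity"):
            syn.evoked_response(sw, 0.1, polarity="inward")
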