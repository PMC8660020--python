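"""Model-neuron current-clamp simulator.

A single-compartment leaky membrane with an optional hyperpolarization-
activated (Ih-like) conductance reproduces the sag/rebound phenomenology of
CA1 pyramidal cells:

    c_m dV/dt = -(V - v_rest)/r_m - g_h h (V - e_h) + I(t)
        dh/dt = (h_inf(V) - h) / tau_h,   h_inf(V) = 1 / (1 + exp((V - v_half_h)/k_h))

Units are the patch-clamp conventions: mV, pA, MΩ, pF, nS, ms (time-step
arguments are in seconds to match acquisition metadata).  Spiking, where
enabled, is hard-threshold integrate-and-fire: crossing ``v_thresh`` resets
the potential to ``v_reset`` for ``t_refract``; no action-potential waveform
is drawn.  For AP-feature analysis a separate parametric waveform generator
(:func:`spike_waveform_sweep`) builds spikes with a constructed threshold
inflection, which IF spikes do not have.

Integration is fixed-step exponential Euler, exact for the piecewise-frozen
conductances, at the 10 kHz grid typical of the recordings this emulates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np

from natalmap.sweeps import StepProtocol, SweepSet

__all__ = ["NeuronParams", "simulate_current_clamp", "spike_waveform_sweep"]


@dataclass(frozen=True)
class NeuronParams:
    """Ground-truth membrane parameters of the simulated cell.

    v_rest mV; r_m MΩ; c_m pF; g_h nS (>= 0); e_h mV; tau_h ms;
    v_half_h / k_h mV (falling-sigmoid activation); v_thresh / v_reset mV;
    t_refract ms.  Set ``v_thresh=None`` (or inf) to disable spiking.
    """

    v_rest: float = -65.0
    r_m: float = 100.0
    c_m: float = 200.0
    g_h: float = 0.0
    e_h: float = -30.0
    tau_h: float = 50.0
    v_half_h: float = -80.0
    k_h: float = 6.0
    v_thresh: float | None = None
    v_reset: float = -60.0
    t_refract: float = 2.0

    def __post_init__(self) -> None:
        vals = [self.v_rest, self.r_m, self.c_m, self.g_h, self.e_h,
                self.tau_h, self.v_half_h, self.k_h, self.v_reset, self.t_refract]
        if self.v_thresh is not None:
            vals.append(self.v_thresh)
        if not all(math.isfinite(v) for v in vals):
            raise ValueError("non-finite neuron parameter")
        if self.r_m <= 0 or self.c_m <= 0 or self.tau_h <= 0:
            raise ValueError("r_m, c_m and tau_h must be positive")
        if self.g_h < 0:
            raise ValueError("g_h must be >= 0")
        if self.v_thresh is not None and not self.v_reset < self.v_thresh:
            raise ValueError("v_reset must be below v_thresh")

    @property
    def tau_m(self) -> float:
        """Passive membrane time constant r_m * c_m, ms."""
        return self.r_m * self.c_m / 1000.0

    @property
    def g_leak(self) -> float:
        """Leak conductance 1/r_m, nS."""
        return 1000.0 / self.r_m

    def h_inf(self, v: float) -> float:
        return 1.0 / (1.0 + math.exp((v - self.v_half_h) / self.k_h))

    def resting_state(self) -> tuple[float, float]:
        """Zero-current fixed point (V, h), by damped fixed-point iteration."""
        v = self.v_rest
        for _ in range(500):
            h = self.h_inf(v)
            g_tot = self.g_leak + self.g_h * h
            v_new = (self.g_leak * self.v_rest + self.g_h * h * self.e_h) / g_tot
            if abs(v_new - v) < 1e-12:
                v = v_new
                break
            v = 0.5 * v + 0.5 * v_new
        return v, self.h_inf(v)


def simulate_current_clamp(
    params: NeuronParams,
    protocol: StepProtocol,
    dt: float = 1e-4,
    seed: int | None = None,
    noise_sd: float = 0.0,
    spike_paint_mv: float = 30.0,
) -> SweepSet:
    """Simulate one current-clamp sweep per protocol amplitude.

    Parameters
    ----------
    dt : float
        Sample interval in seconds; rejected if coarser than a tenth of
        either membrane or gating time constant.
    noise_sd : float
        Optional additive Gaussian voltage noise, mV (seeded).

    Returns
    -------
    SweepSet
        Voltage sweeps (mV) with ground truth in ``meta["ground_truth"]``:
        the parameters, initial state, and per-sweep spike times.
    """
    if dt <= 0 or not math.isfinite(dt):
        raise ValueError("dt must be positive and finite")
    dt_ms = dt * 1e3
    if dt_ms > params.tau_h / 10.0 or dt_ms > params.tau_m / 10.0:
        raise ValueError(
            f"dt={dt} s too coarse for tau_h={params.tau_h} ms / tau_m={params.tau_m} ms"
        )
    if not all(math.isfinite(a) for a in protocol.amplitudes):
        raise ValueError("protocol amplitudes must be finite")

    n = int(round((protocol.step_onset + protocol.step_duration) / dt)) + int(round(0.5 / dt))
    i_on = int(round(protocol.step_onset / dt))
    i_off = int(round((protocol.step_onset + protocol.step_duration) / dt))
    n_ref = int(round(params.t_refract / dt_ms))

    v0, h0 = params.resting_state()
    g_l = params.g_leak
    decay_h = math.exp(-dt_ms / params.tau_h)
    spiking = params.v_thresh is not None and math.isfinite(params.v_thresh)

    data = np.empty((len(protocol.amplitudes), n))
    spike_times: list[list[float]] = []
    for s, amp in enumerate(protocol.amplitudes):
        v, h = v0, h0
        refract = 0
        spikes: list[float] = []
        trace = data[s]
        for i in range(n):
            trace[i] = v
            i_inj = amp if i_on <= i < i_off else 0.0
            if refract > 0:
                refract -= 1
                v = params.v_reset
            else:
                g_tot = g_l + params.g_h * h
                v_inf = (g_l * params.v_rest + params.g_h * h * params.e_h + i_inj) / g_tot
                v = v_inf + (v - v_inf) * math.exp(-dt_ms * g_tot / params.c_m)
                if spiking and v >= params.v_thresh:
                    spikes.append((i + 1) * dt)
                    # paint a one-sample marker so threshold-crossing spike
                    # detectors register IF spikes (no waveform is modeled)
                    v = spike_paint_mv
                    refract = max(n_ref, 1)
            h_inf = params.h_inf(v)
            h = h_inf + (h - h_inf) * decay_h
        spike_times.append(spikes)

    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        data = data + rng.normal(0.0, noise_sd, size=data.shape)

    gt = {
        "params": asdict(params),
        "tau_m_ms": params.tau_m,
        "v0": v0,
        "h0": h0,
        "spike_times": spike_times,
        "analytic_rheobase_pa": None,
    }
    if spiking:
        # nS * mV = pA; exact for g_h = 0, steady-state approximation otherwise
        g_eff = g_l + params.g_h * h0
        gt["analytic_rheobase_pa"] = (params.v_thresh - v0) * g_eff

    return SweepSet(dt=dt, data=data, protocol=protocol, units="mV",
                    meta={"clamp": "current", "ground_truth": gt, "seed": seed})


def spike_waveform_sweep(
    dt: float = 1e-4,
    v_baseline: float = -65.0,
    v_thresh: float = -45.0,
    v_peak: float = 35.0,
    v_fahp_min: float = -53.0,
    ramp_ms: float = 20.0,
    rise_ms: float = 0.8,
    fall_ms: float = 1.2,
    recovery_tau_ms: float = 20.0,
    pre_ms: float = 20.0,
    post_ms: float = 60.0,
) -> tuple[np.ndarray, dict]:
    """Parametric action-potential waveform with a constructed threshold.

    The depolarizing approach to threshold is linear (zero curvature), the
    upstroke is a raised-sine from ``v_thresh`` to ``v_peak``; curvature is
    therefore maximal at the onset of the upstroke, i.e. the second-derivative
    peak sits at ``v_thresh`` by construction.  The downstroke is a raised-
    sine descent to ``v_fahp_min`` followed by exponential recovery.

    Returns the voltage trace (mV) and a ground-truth dict (threshold, peak
    voltage/time, fAHP depth).
    """
    if not v_baseline < v_thresh < v_peak:
        raise ValueError("need v_baseline < v_thresh < v_peak")
    if not v_fahp_min < v_thresh:
        raise ValueError("fAHP minimum must undershoot threshold")
    dt_ms = dt * 1e3
    t_th = pre_ms + ramp_ms
    t_peak = t_th + rise_ms
    t_min = t_peak + fall_ms
    total_ms = t_min + post_ms
    t = np.arange(int(round(total_ms / dt_ms))) * dt_ms

    v = np.full_like(t, v_baseline)
    ramp = (t >= pre_ms) & (t < t_th)
    v[ramp] = v_baseline + (v_thresh - v_baseline) * (t[ramp] - pre_ms) / ramp_ms
    up = (t >= t_th) & (t < t_peak)
    v[up] = v_thresh + (v_peak - v_thresh) * np.sin(
        0.5 * np.pi * (t[up] - t_th) / rise_ms) ** 2
    down = (t >= t_peak) & (t < t_min)
    v[down] = v_peak + (v_fahp_min - v_peak) * np.sin(
        0.5 * np.pi * (t[down] - t_peak) / fall_ms) ** 2
    # after the fAHP the membrane relaxes back toward the depolarized
    # (near-threshold) level sustained by the current injection, so the
    # post-spike minimum is exactly v_fahp_min
    rec = t >= t_min
    v[rec] = v_thresh + (v_fahp_min - v_thresh) * np.exp(
        -(t[rec] - t_min) / recovery_tau_ms)

    gt = {
        "threshold_mv": v_thresh,
        "peak_mv": v_peak,
        "peak_time_s": t_peak * 1e-3,
        "amplitude_mv": v_peak - v_thresh,
        "fahp_mv": v_thresh - v_fahp_min,
    }
    return v, gt
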