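"""Synthetic postsynaptic-current traces.

Events follow a homogeneous Poisson process; each adds a biexponential
kernel a * (exp(-t/tau_decay) - exp(-t/tau_rise)) scaled so its peak equals
the drawn amplitude; Gaussian noise is added on top.  Ground truth (event
times and signed peak amplitudes) is returned alongside the trace.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from natalmap.sweeps import StepProtocol, SweepSet

__all__ = [
    "PscSimParams",
    "kernel_peak_time",
    "psc_kernel",
    "simulate_psc_trace",
    "simulate_evoked_psc",
]

_MAX_EXPECTED_EVENTS = 1_000_000


@dataclass(frozen=True)
class PscSimParams:
    """Event-train parameters: rate Hz, amplitudes pA (magnitudes),
    kernel time constants ms, polarity, noise sd pA, sweep length s."""

    rate: float = 2.0
    amp_mean: float = 30.0
    amp_sd: float = 8.0
    tau_rise: float = 0.5
    tau_decay: float = 5.0
    polarity: str = "inward"
    noise_sd: float = 3.0
    duration: float = 20.0
    n_sweeps: int = 1

    def __post_init__(self) -> None:
        if not (self.tau_decay > self.tau_rise > 0):
            raise ValueError("need tau_decay > tau_rise > 0")
        if self.rate < 0:
            raise ValueError("rate must be >= 0")
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.polarity not in ("inward", "outward"):
            raise ValueError("polarity must be 'inward' or 'outward'")
        if self.noise_sd < 0 or self.amp_mean <= 0:
            raise ValueError("noise_sd >= 0 and amp_mean > 0 required")
        if self.rate * self.duration * self.n_sweeps > _MAX_EXPECTED_EVENTS:
            raise ValueError("expected event count exceeds overflow guard")

    @property
    def sign(self) -> float:
        return -1.0 if self.polarity == "inward" else 1.0


def kernel_peak_time(tau_rise: float, tau_decay: float) -> float:
    """Peak time of exp(-t/tau_decay) - exp(-t/tau_rise), ms (closed form)."""
    return math.log(tau_decay / tau_rise) * tau_rise * tau_decay / (tau_decay - tau_rise)


def psc_kernel(t_ms: np.ndarray, tau_rise: float, tau_decay: float) -> np.ndarray:
    """Unit-peak biexponential kernel sampled at t_ms (zero for t < 0)."""
    t = np.asarray(t_ms, dtype=float)
    tc = np.maximum(t, 0.0)  # clamp first: exp overflows for t << 0
    raw = np.where(t >= 0, np.exp(-tc / tau_decay) - np.exp(-tc / tau_rise), 0.0)
    tp = kernel_peak_time(tau_rise, tau_decay)
    peak = math.exp(-tp / tau_decay) - math.exp(-tp / tau_rise)
    return raw / peak


def _add_events(trace: np.ndarray, dt: float, times_s: np.ndarray,
                amps_signed: np.ndarray, tau_rise: float, tau_decay: float) -> None:
    """Add unit-peak-scaled kernels in place; kernel truncated at 10 tau_decay."""
    dt_ms = dt * 1e3
    klen = int(round(10.0 * tau_decay / dt_ms)) + 1
    kern = psc_kernel(np.arange(klen) * dt_ms, tau_rise, tau_decay)
    n = trace.size
    for t0, a in zip(times_s, amps_signed):
        i0 = int(round(t0 / dt))
        if i0 >= n:
            continue
        i1 = min(i0 + klen, n)
        trace[i0:i1] += a * kern[: i1 - i0]


def simulate_psc_trace(
    params: PscSimParams, seed: int | None = None, dt: float = 1e-4
) -> tuple[SweepSet, pd.DataFrame]:
    """Simulate spontaneous PSC sweeps plus the ground-truth event table.

    Returns
    -------
    (SweepSet, DataFrame)
        Current sweeps in pA and a table with columns ``sweep``, ``time_s``
        (event onset), ``peak_time_s``, ``amplitude_pa`` (signed peak).
    """
    rng = np.random.default_rng(seed)
    n = int(round(params.duration / dt))
    data = np.zeros((params.n_sweeps, n))
    rows = []
    tp_s = kernel_peak_time(params.tau_rise, params.tau_decay) * 1e-3
    for s in range(params.n_sweeps):
        n_ev = rng.poisson(params.rate * params.duration)
        times = np.sort(rng.uniform(0.0, params.duration, size=n_ev))
        amps = np.abs(rng.normal(params.amp_mean, params.amp_sd, size=n_ev))
        _add_events(data[s], dt, times, params.sign * amps,
                    params.tau_rise, params.tau_decay)
        for t0, a in zip(times, amps):
            rows.append((s, t0, t0 + tp_s, params.sign * a))
    if params.noise_sd > 0:
        data += rng.normal(0.0, params.noise_sd, size=data.shape)

    events = pd.DataFrame(rows, columns=["sweep", "time_s", "peak_time_s", "amplitude_pa"])
    sweeps = SweepSet(
        dt=dt, data=data, protocol=None, units="pA",
        meta={"clamp": "voltage", "polarity": params.polarity,
              "ground_truth": {"params": asdict(params)}, "seed": seed},
    )
    return sweeps, events


def simulate_evoked_psc(
    stim_times: tuple[float, ...],
    peak_amps: tuple[float, ...],
    tau_rise: float = 1.0,
    tau_decay: float = 10.0,
    polarity: str = "inward",
    latency_ms: float = 2.0,
    duration: float = 0.5,
    n_sweeps: int = 5,
    noise_sd: float = 2.0,
    seed: int | None = None,
    dt: float = 1e-4,
) -> SweepSet:
    """Evoked-response sweeps: one kernel per stimulus, fixed latency.

    ``peak_amps`` are signed per-stimulus peak contributions (pA); sweeps
    differ only in noise.  Stimulus times are stored in the protocol.
    """
    if len(stim_times) != len(peak_amps):
        raise ValueError("one amplitude per stimulus required")
    sign = -1.0 if polarity == "inward" else 1.0
    rng = np.random.default_rng(seed)
    n = int(round(duration / dt))
    clean = np.zeros(n)
    onset_times = np.asarray(stim_times) + latency_ms * 1e-3
    _add_events(clean, dt, onset_times, np.asarray(peak_amps, dtype=float),
                tau_rise, tau_decay)
    data = clean[None, :] + (
        rng.normal(0.0, noise_sd, size=(n_sweeps, n)) if noise_sd > 0 else 0.0
    )
    proto = StepProtocol(step_onset=float(min(stim_times)), step_duration=0.0,
                         amplitudes=(0.0,) * n_sweeps,
                         baseline_window=(0.0, float(min(stim_times))),
                         stim_times=tuple(stim_times))
    return SweepSet(dt=dt, data=np.atleast_2d(data), protocol=proto, units="pA",
                    meta={"clamp": "voltage", "polarity": polarity, "sign": sign,
                          "ground_truth": {"stim_times": list(stim_times),
                                           "peak_amps": list(peak_amps),
                                           "latency_ms": latency_ms},
                          "seed": seed})
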