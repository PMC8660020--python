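"""Current-clamp intrinsic properties.

Implements the standard slice-physiology measures for CA1 pyramidal cells:
input resistance from the I-V slope of steady-state responses to
subthreshold steps, membrane time constant from a biexponential fit to a
small hyperpolarizing pulse, capacitance Cm = tau_m / Rm, sag and rebound on
a -200 pA step, spike detection, F-I curve with rheobase, and
action-potential waveform features measured on the first spike (threshold at
the second-derivative peak, amplitude and fast AHP from threshold,
half-width between threshold and peak).

All measures are baseline-referenced and therefore invariant to a constant
voltage offset, except the AP threshold, which is an absolute potential.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from natalmap.sweeps import StepProtocol, SweepSet

__all__ = [
    "SpikeTrain",
    "ApFeatures",
    "IntrinsicProfile",
    "detect_spikes",
    "measure_input_resistance",
    "fit_membrane_time_constant",
    "capacitance",
    "measure_sag",
    "measure_rebound",
    "fi_curve_and_rheobase",
    "ap_waveform_features",
]


@dataclass(frozen=True)
class SpikeTrain:
    """Ordered spike times (s) and spike-peak sample indices for one sweep."""

    times: np.ndarray
    peak_indices: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        if t.size > 1 and not np.all(np.diff(t) > 0):
            raise ValueError("spike times must be strictly increasing")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "peak_indices", np.asarray(self.peak_indices, dtype=int))

    @property
    def n_spikes(self) -> int:
        return self.times.size


@dataclass(frozen=True)
class ApFeatures:
    threshold_mv: float
    amplitude_mv: float
    halfwidth_ms: float
    fahp_mv: float
    truncated: bool = False


@dataclass
class IntrinsicProfile:
    """Per-cell intrinsic measures. NaN marks an undefined (flagged) value."""

    rm_mohm: float = math.nan
    tau_m_ms: float = math.nan
    cm_pf: float = math.nan
    sag_mv: float = math.nan
    rebound_mv: float = math.nan
    rheobase_pa: float = math.nan
    fi_curve: dict = field(default_factory=dict)
    ap: ApFeatures | None = None


def _baseline(v: np.ndarray, sweeps: SweepSet, protocol: StepProtocol) -> float:
    t0, t1 = protocol.baseline_window
    if t1 <= t0:
        t0, t1 = 0.0, protocol.step_onset
    return float(v[sweeps.window(t0, t1)].mean())


def detect_spikes(
    v: np.ndarray, dt: float, threshold_mv: float = -20.0, refractory_ms: float = 1.0
) -> SpikeTrain:
    """Spikes as upward threshold crossings separated by >= refractory_ms.

    The spike peak is the local maximum between the crossing and the next
    downward crossing (or refractory end).  Runs on the unfiltered trace.
    """
    v = np.asarray(v, dtype=float)
    above = v >= threshold_mv
    crossings = np.flatnonzero(~above[:-1] & above[1:]) + 1
    n_ref = max(int(round(refractory_ms * 1e-3 / dt)), 1)
    times, peaks = [], []
    last = -n_ref - 1
    for c in crossings:
        if c - last < n_ref:
            continue
        last = c
        end = c
        while end < v.size and v[end] >= threshold_mv:
            end += 1
        peak = c + int(np.argmax(v[c:max(end, c + 1)]))
        times.append(peak * dt)
        peaks.append(peak)
    return SpikeTrain(times=np.array(times), peak_indices=np.array(peaks, dtype=int))


def measure_input_resistance(
    sweeps: SweepSet, steady_window_s: float = 0.1
) -> float:
    """Input resistance (MΩ): OLS slope of steady-state ΔV vs injected current.

    Steady state is the mean over the last ``steady_window_s`` of the step;
    sweeps containing spikes are excluded.
    """
    proto = sweeps.protocol
    if proto is None:
        raise ValueError("step protocol required")
    dv, current = [], []
    for i in range(sweeps.n_sweeps):
        v = sweeps.sweep(i)
        if detect_spikes(v, sweeps.dt).n_spikes > 0:
            continue
        ss = v[sweeps.window(proto.step_end - steady_window_s, proto.step_end)].mean()
        dv.append(ss - _baseline(v, sweeps, proto))
        current.append(proto.amplitudes[i])
    if len(dv) < 2:
        raise ValueError(f"need >= 2 spike-free subthreshold sweeps, got {len(dv)}")
    current = np.asarray(current)
    if np.ptp(current) == 0:
        raise ValueError("zero current spread across sweeps")
    slope_gohm = np.polyfit(current, np.asarray(dv), 1)[0]  # mV/pA = GΩ
    return float(slope_gohm * 1e3)


def _biexp(t, v0, a1, tau1, a2, tau2):
    return v0 + a1 * np.exp(-t / tau1) + a2 * np.exp(-t / tau2)


def fit_membrane_time_constant(
    sweeps: SweepSet, amplitude: float = -20.0, sweep_index: int | None = None
) -> tuple[float, dict]:
    """Membrane time constant (ms) from a biexponential fit to a small pulse.

    Fits V(t) = V0 + A1 exp(-t/tau1) + A2 exp(-t/tau2) over the step and
    reports the time constant of the larger-|amplitude| component as tau_m
    (convention recorded in the diagnostics).  Falls back to the
    monoexponential seed fit when the two components collapse or the
    optimizer fails.
    """
    proto = sweeps.protocol
    if proto is None:
        raise ValueError("step protocol required")
    if sweep_index is None:
        matches = [i for i, a in enumerate(proto.amplitudes) if abs(a - amplitude) < 1e-9]
        if not matches:
            raise ValueError(f"no sweep at amplitude {amplitude} pA")
        sweep_index = matches[0]
    v = sweeps.sweep(sweep_index)
    sl = sweeps.window(proto.step_onset, proto.step_end)
    seg = v[sl]
    t_ms = (np.arange(seg.size) * sweeps.dt) * 1e3

    # monoexponential seed: log-linear regression on |V - V_ss|
    v_ss = seg[int(seg.size * 0.8):].mean()
    resid = seg - v_ss
    a0 = resid[0]
    usable = np.abs(resid) > max(1e-4, 0.05 * abs(a0))
    if usable.sum() >= 3 and abs(a0) > 0:
        sign = 1.0 if a0 >= 0 else -1.0
        coef = np.polyfit(t_ms[usable], np.log(np.abs(resid[usable])), 1)
        tau_seed = float(np.clip(-1.0 / coef[0], 0.1, 500.0)) if coef[0] < 0 else 20.0
        a_seed = sign * float(np.exp(coef[1]))
    else:
        tau_seed, a_seed = 20.0, a0

    diagnostics: dict = {"converged": False, "convention": "larger-amplitude component"}
    p0 = [v_ss, a_seed / 4.0, max(tau_seed / 5.0, 0.15), a_seed, tau_seed]
    lo = [-np.inf, -np.inf, 0.1, -np.inf, 0.1]
    hi = [np.inf, np.inf, 500.0, np.inf, 500.0]
    try:
        popt, _ = curve_fit(_biexp, t_ms, seg, p0=p0, bounds=(lo, hi),
                            maxfev=20000, xtol=1e-8, ftol=1e-8)
        v0, a1, tau1, a2, tau2 = popt
        resid_norm = float(np.linalg.norm(_biexp(t_ms, *popt) - seg))
        comps = sorted([(abs(a1), tau1, a1), (abs(a2), tau2, a2)], reverse=True)
        tau_m = float(comps[0][1])
        diagnostics.update(
            converged=True, v0=float(v0), residual_norm=resid_norm,
            components=[{"amplitude_mv": float(c[2]), "tau_ms": float(c[1])} for c in comps],
            collapsed=abs(tau1 - tau2) < 0.05 * max(tau1, tau2),
        )
        return tau_m, diagnostics
    except RuntimeError as err:
        diagnostics.update(error=str(err), fallback="monoexponential seed")
        return float(tau_seed), diagnostics


def capacitance(tau_m_ms: float, rm_mohm: float) -> float:
    """Cm = tau_m / Rm, in pF (ms / MΩ = nF; x1000 -> pF)."""
    if tau_m_ms <= 0 or rm_mohm <= 0:
        raise ValueError("tau_m and Rm must be positive")
    return tau_m_ms / rm_mohm * 1e3


def _pick_sweep(sweeps: SweepSet, amplitude: float, sweep_index: int | None) -> int:
    if sweep_index is not None:
        return sweep_index
    proto = sweeps.protocol
    for i, a in enumerate(proto.amplitudes):
        if abs(a - amplitude) < 1e-9:
            return i
    raise ValueError(f"no sweep at amplitude {amplitude} pA")


def measure_sag(
    sweeps: SweepSet,
    amplitude: float = -200.0,
    sweep_index: int | None = None,
    peak_window_s: float = 0.2,
    ss_window_s: float = 0.045,
) -> float:
    """Sag (mV) on a hyperpolarizing step: ΔV_steady-state − ΔV_peak.

    ΔV_peak is the minimum within ``peak_window_s`` of step onset; the steady
    state is averaged over ``ss_window_s`` centered at the temporal midpoint
    of the step; both are baseline-referenced.  Positive values indicate sag.
    """
    proto = sweeps.protocol
    idx = _pick_sweep(sweeps, amplitude, sweep_index)
    if proto.amplitudes[idx] >= 0:
        raise ValueError("sag requires a hyperpolarizing (negative) step")
    v = sweeps.sweep(idx)
    base = _baseline(v, sweeps, proto)
    peak = v[sweeps.window(proto.step_onset, proto.step_onset + peak_window_s)].min()
    mid = proto.step_onset + proto.step_duration / 2.0
    if mid + ss_window_s / 2 > proto.step_end:
        raise ValueError("steady-state window exceeds the step")
    ss = v[sweeps.window(mid - ss_window_s / 2, mid + ss_window_s / 2)].mean()
    return float((ss - base) - (peak - base))


def measure_rebound(
    sweeps: SweepSet,
    amplitude: float = -200.0,
    sweep_index: int | None = None,
    window_s: float = 0.2,
) -> float:
    """Rebound (mV): post-step depolarization peak minus baseline.

    Returns NaN (undefined) when rebound spikes occur in the post-step
    window, mirroring the exclusion applied to recorded cells.
    """
    proto = sweeps.protocol
    idx = _pick_sweep(sweeps, amplitude, sweep_index)
    v = sweeps.sweep(idx)
    sl = sweeps.window(proto.step_end, min(proto.step_end + window_s, sweeps.duration))
    if detect_spikes(v[sl], sweeps.dt).n_spikes > 0:
        return math.nan
    base = _baseline(v, sweeps, proto)
    return float(v[sl].max() - base)


def fi_curve_and_rheobase(sweeps: SweepSet) -> tuple[dict[float, int], float]:
    """Spike count per injected amplitude and the rheobase (pA).

    Rheobase is the smallest amplitude eliciting >= 1 spike; NaN if no sweep
    spikes.
    """
    proto = sweeps.protocol
    if proto is None:
        raise ValueError("step protocol required")
    fi: dict[float, int] = {}
    for i, amp in enumerate(proto.amplitudes):
        fi[float(amp)] = detect_spikes(sweeps.sweep(i), sweeps.dt).n_spikes
    spiking = [a for a, n in fi.items() if n > 0]
    rheobase = min(spiking) if spiking else math.nan
    return fi, float(rheobase)


def ap_waveform_features(
    v: np.ndarray,
    dt: float,
    spikes: SpikeTrain | None = None,
    search_ms: float = 2.0,
    fahp_ms: float = 5.0,
    smooth: bool = False,
) -> ApFeatures:
    """AP features on the first spike of an unfiltered voltage sweep.

    threshold: V at the peak of the centered second finite difference within
    [peak − search_ms, peak] (earliest sample on ties); amplitude and fAHP
    from threshold; half-width at (threshold + peak)/2 between the rising and
    falling crossings.  A never-recrossed half level flags the spike as
    truncated (half-width NaN).
    """
    v = np.asarray(v, dtype=float)
    if spikes is None:
        spikes = detect_spikes(v, dt)
    if spikes.n_spikes == 0:
        raise ValueError("no spikes in sweep")
    peak = int(spikes.peak_indices[0])
    v_peak = v[peak]

    w = v.copy()
    if smooth:
        w[1:-1] = (v[:-2] + v[1:-1] + v[2:]) / 3.0
    d2 = np.empty_like(w)
    d2[1:-1] = w[2:] - 2.0 * w[1:-1] + w[:-2]
    d2[0] = d2[-1] = -np.inf
    i0 = max(peak - int(round(search_ms * 1e-3 / dt)), 1)
    i_th = i0 + int(np.argmax(d2[i0:peak + 1]))
    v_th = float(v[i_th])

    half = 0.5 * (v_th + v_peak)

    def _cross(i, j, level):  # linear interpolation between samples i, j
        return (i + (level - v[i]) / (v[j] - v[i])) * dt

    rise_t = None
    for i in range(peak, i0 - 1, -1):
        if v[i - 1] < half <= v[i]:
            rise_t = _cross(i - 1, i, half)
            break
    fall_t = None
    i_end = min(peak + int(round(fahp_ms * 1e-3 / dt)), v.size - 1)
    for i in range(peak, i_end):
        if v[i] >= half > v[i + 1]:
            fall_t = _cross(i, i + 1, half)
            break
    truncated = rise_t is None or fall_t is None
    halfwidth = math.nan if truncated else (fall_t - rise_t) * 1e3

    fahp = float(v_th - v[peak:i_end + 1].min())
    return ApFeatures(threshold_mv=v_th, amplitude_mv=float(v_peak - v_th),
                      halfwidth_ms=halfwidth, fahp_mv=fahp, truncated=truncated)
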