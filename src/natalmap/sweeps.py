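"""Core containers for patch-clamp sweep data.

A :class:`SweepSet` holds the repeated responses of one cell to a step
protocol: a common time base (fixed sample interval ``dt``), one array per
sweep, and the :class:`StepProtocol` describing the injected (or commanded)
steps.  Current-clamp sweeps are in mV, voltage-clamp sweeps in pA; the
``units`` field records which.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = ["StepProtocol", "SweepSet"]


@dataclass(frozen=True)
class StepProtocol:
    """Square-step stimulus protocol shared by all sweeps of a set.

    Parameters
    ----------
    step_onset : float
        Step onset time in seconds.
    step_duration : float
        Step duration in seconds.
    amplitudes : tuple of float
        Injected amplitude per sweep, pA (current clamp) or mV (VC command).
    baseline_window : (float, float)
        Window (t0, t1) in seconds, before the step, used as baseline.
    stim_times : tuple of float, optional
        Extracellular stimulation times (s), for evoked protocols.
    """

    step_onset: float
    step_duration: float
    amplitudes: tuple[float, ...]
    baseline_window: tuple[float, float] = (0.0, 0.0)
    stim_times: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        t0, t1 = self.baseline_window
        if not (0.0 <= t0 <= t1 <= self.step_onset + 1e-12):
            raise ValueError(
                f"baseline window {self.baseline_window} must satisfy "
                f"0 <= t0 <= t1 <= step_onset ({self.step_onset})"
            )
        object.__setattr__(self, "amplitudes", tuple(float(a) for a in self.amplitudes))
        object.__setattr__(self, "stim_times", tuple(float(t) for t in self.stim_times))

    @property
    def step_end(self) -> float:
        return self.step_onset + self.step_duration


@dataclass
class SweepSet:
    """Multi-sweep time series with protocol metadata.

    ``data`` has shape (n_sweeps, n_samples); row i is the response to
    ``protocol.amplitudes[i]`` where a step protocol applies.
    """

    dt: float
    data: np.ndarray
    protocol: StepProtocol | None = None
    units: str = "mV"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError(f"dt must be positive, got {self.dt}")
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.protocol is not None:
            if self.protocol.step_onset + self.protocol.step_duration > self.duration + 1e-9:
                raise ValueError("protocol step extends beyond trace duration")

    @property
    def n_sweeps(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples * self.dt

    @property
    def time(self) -> np.ndarray:
        return np.arange(self.n_samples) * self.dt

    def index(self, t: float) -> int:
        """Sample index of time ``t`` (rounded to the grid)."""
        return int(round(t / self.dt))

    def window(self, t0: float, t1: float) -> slice:
        """Slice covering [t0, t1); clipped to the trace."""
        i0 = max(self.index(t0), 0)
        i1 = min(self.index(t1), self.n_samples)
        if i1 <= i0:
            raise ValueError(f"empty window [{t0}, {t1}) at dt={self.dt}")
        return slice(i0, i1)

    def sweep(self, i: int) -> np.ndarray:
        return self.data[i]

    def select(self, indices: Sequence[int]) -> "SweepSet":
        """Subset of sweeps (protocol amplitudes subset accordingly)."""
        idx = list(indices)
        proto = self.protocol
        if proto is not None and len(proto.amplitudes) == self.n_sweeps:
            proto = StepProtocol(
                step_onset=proto.step_onset,
                step_duration=proto.step_duration,
                amplitudes=tuple(proto.amplitudes[i] for i in idx),
                baseline_window=proto.baseline_window,
                stim_times=proto.stim_times,
            )
        return SweepSet(dt=self.dt, data=self.data[idx], protocol=proto,
                        units=self.units, meta=dict(self.meta))
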