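"""Open-field exploration metrics: path distance and center-zone occupancy.

The arena is the 435 x 290 mm rectangular exploration chamber with a
290 x 193 mm center zone; time spent in the center is the (inverse)
thigmotaxis proxy used to compare exploration conditions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ArenaGeometry", "Trajectory", "path_distance", "center_occupancy"]


@dataclass(frozen=True)
class ArenaGeometry:
    """Rectangular arena (mm) with a centered rectangular center zone."""

    width: float = 435.0
    height: float = 290.0
    center_width: float = 290.0
    center_height: float = 193.0

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValueError("arena dimensions must be positive")
        if not (0 < self.center_width <= self.width and 0 < self.center_height <= self.height):
            raise ValueError("center zone must fit inside the arena")

    @property
    def center_bounds(self) -> tuple[float, float, float, float]:
        """(x0, x1, y0, y1) of the center zone."""
        mx = (self.width - self.center_width) / 2.0
        my = (self.height - self.center_height) / 2.0
        return (mx, self.width - mx, my, self.height - my)

    @property
    def center_area_fraction(self) -> float:
        return (self.center_width * self.center_height) / (self.width * self.height)

    def contains(self, x: np.ndarray, y: np.ndarray, eps: float = 1e-9) -> np.ndarray:
        return ((x >= -eps) & (x <= self.width + eps)
                & (y >= -eps) & (y <= self.height + eps))


@dataclass(frozen=True)
class Trajectory:
    """Tracked positions: times (s, strictly increasing) and x/y (mm)."""

    times: np.ndarray
    x: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=float)
        if not (t.size == x.size == y.size):
            raise ValueError("times, x, y must have equal length")
        if t.size > 1 and not np.all(np.diff(t) > 0):
            raise ValueError("times must be strictly increasing")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)

    @property
    def n(self) -> int:
        return self.times.size


def path_distance(traj: Trajectory) -> float:
    """Total path length (mm): sum of consecutive Euclidean displacements."""
    if traj.n < 2:
        raise ValueError("need at least two points")
    return float(np.hypot(np.diff(traj.x), np.diff(traj.y)).sum())


def center_occupancy(traj: Trajectory, arena: ArenaGeometry) -> float:
    """Percent of session time spent strictly inside the center zone.

    Each sample is weighted by its forward inter-sample interval; the last
    sample carries the median interval.  Out-of-bounds points are rejected.
    """
    if not np.all(arena.contains(traj.x, traj.y)):
        raise ValueError("trajectory leaves the arena")
    x0, x1, y0, y1 = arena.center_bounds
    inside = (traj.x > x0) & (traj.x < x1) & (traj.y > y0) & (traj.y < y1)
    if traj.n == 1:
        return 100.0 * float(inside[0])
    dwell = np.diff(traj.times)
    dwell = np.append(dwell, np.median(dwell))
    return float(100.0 * dwell[inside].sum() / dwell.sum())
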