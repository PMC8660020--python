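"""Reflected random-walk trajectories in a rectangular arena."""

from __future__ import annotations

import numpy as np

from natalmap.behavior import ArenaGeometry, Trajectory

__all__ = ["simulate_trajectory"]


def _reflect(pos: np.ndarray, size: float) -> np.ndarray:
    """Fold unbounded coordinates into [0, size] by specular reflection."""
    period = 2.0 * size
    folded = np.mod(pos, period)
    return size - np.abs(folded - size)


def simulate_trajectory(
    arena: ArenaGeometry,
    n_steps: int = 10_000,
    step_sd: float = 10.0,
    dt: float = 0.04,
    seed: int | None = None,
    start: tuple[float, float] | None = None,
) -> Trajectory:
    """Gaussian random walk (step sd in mm) reflected at the arena walls.

    All returned points are inside the arena for any seed.
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    if step_sd < 0 or dt <= 0:
        raise ValueError("step_sd >= 0 and dt > 0 required")
    rng = np.random.default_rng(seed)
    x0, y0 = start if start is not None else (arena.width / 2.0, arena.height / 2.0)
    steps = rng.normal(0.0, step_sd, size=(n_steps, 2)) if step_sd > 0 else np.zeros((n_steps, 2))
    raw = np.concatenate([[[x0, y0]], steps]).cumsum(axis=0)
    x = _reflect(raw[:, 0], arena.width)
    y = _reflect(raw[:, 1], arena.height)
    times = np.arange(n_steps + 1) * dt
    return Trajectory(times=times, x=x, y=y)
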