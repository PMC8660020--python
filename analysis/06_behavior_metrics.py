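#!/usr/bin/env python
"""Exploration metrics per simulated condition: total path distance and
center-zone occupancy (thigmotaxis proxy) in the 435 x 290 mm arena.

Writes results/analysis/behavior_metrics.csv.
"""

from pathlib import Path

import pandas as pd

from natalmap import io, study
from natalmap.behavior import center_occupancy, path_distance

IN = Path("results/analysis/inputs")
OUT = Path("results/analysis")


def main() -> None:
    rows = []
    for cond in study.CONDITIONS:
        traj = io.read_trajectory(IN / f"trajectory_{cond}.csv")
        rows.append({
            "condition": cond,
            "n_samples": traj.n,
            "duration_s": traj.times[-1],
            "path_distance_mm": path_distance(traj),
            "center_occupancy_pct": center_occupancy(traj, study.ARENA),
        })
    table = pd.DataFrame(rows)
    OUT.mkdir(parents=True, exist_ok=True)
    table.to_csv(OUT / "behavior_metrics.csv", index=False)
    print(table.to_string(index=False, float_format=lambda v: f"{v:.1f}"))
    print(f"\ncenter-zone area fraction of the arena: "
          f"{100 * study.ARENA.center_area_fraction:.1f}% "
          "(occupancy of a diffusive walker approaches this as step size grows)")


if __name__ == "__main__":
    main()
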