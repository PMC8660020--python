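"""File formats: sweep sets as CSV + JSON sidecar, label volumes as
multi-page TIFF + JSON voxel-size sidecar, trajectories and animal tables
as CSV.  All round-trip to machine precision (masks exactly)."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from natalmap.anatomy import LabelVolume3D
from natalmap.behavior import Trajectory
from natalmap.sweeps import StepProtocol, SweepSet

__all__ = [
    "write_sweepset", "read_sweepset",
    "write_label_volume", "read_label_volume",
    "write_trajectory", "read_trajectory",
    "write_animal_table", "read_animal_table",
]


class SchemaError(ValueError):
    """Raised when a file does not match the expected schema."""


def _sidecar(path: Path) -> Path:
    return path.with_suffix(".json")


def write_sweepset(sweeps: SweepSet, path: str | Path) -> Path:
    """CSV with time_s plus one column per sweep, plus a JSON sidecar holding
    dt, units, protocol and metadata."""
    path = Path(path)
    cols = {"time_s": sweeps.time}
    for i in range(sweeps.n_sweeps):
        cols[f"sweep_{i:03d}"] = sweeps.sweep(i)
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.9g")
    proto = sweeps.protocol
    sidecar = {
        "dt": sweeps.dt,
        "units": sweeps.units,
        "meta": _jsonable(sweeps.meta),
        "protocol": None if proto is None else {
            "step_onset": proto.step_onset,
            "step_duration": proto.step_duration,
            "amplitudes": list(proto.amplitudes),
            "baseline_window": list(proto.baseline_window),
            "stim_times": list(proto.stim_times),
        },
    }
    _sidecar(path).write_text(json.dumps(sidecar, indent=1))
    return path


def read_sweepset(path: str | Path) -> SweepSet:
    path = Path(path)
    side_path = _sidecar(path)
    if not side_path.exists():
        raise SchemaError(f"missing sidecar {side_path}")
    side = json.loads(side_path.read_text())
    df = pd.read_csv(path)
    if "time_s" not in df.columns:
        raise SchemaError(f"{path}: missing 'time_s' column")
    sweep_cols = [c for c in df.columns if c.startswith("sweep_")]
    if not sweep_cols:
        raise SchemaError(f"{path}: no sweep_* columns")
    if df[sweep_cols].isna().any().any():
        bad = int(df[sweep_cols].isna().any(axis=1).idxmax())
        raise SchemaError(f"{path}: missing values at row {bad}")
    data = df[sorted(sweep_cols)].to_numpy().T
    proto = None
    if side.get("protocol"):
        p = side["protocol"]
        proto = StepProtocol(step_onset=p["step_onset"], step_duration=p["step_duration"],
                             amplitudes=tuple(p["amplitudes"]),
                             baseline_window=tuple(p["baseline_window"]),
                             stim_times=tuple(p.get("stim_times", ())))
    return SweepSet(dt=side["dt"], data=data, protocol=proto,
                    units=side.get("units", "mV"), meta=side.get("meta", {}))


def write_label_volume(vol: LabelVolume3D, path: str | Path) -> Path:
    """8-bit 0/255 multi-page TIFF + JSON sidecar with the voxel size (µm)."""
    path = Path(path)
    tifffile.imwrite(path, (vol.data.astype(np.uint8) * 255))
    _sidecar(path).write_text(json.dumps({"voxel_size_um": list(vol.voxel_size)}))
    return path


def read_label_volume(path: str | Path) -> LabelVolume3D:
    path = Path(path)
    side_path = _sidecar(path)
    if not side_path.exists():
        raise SchemaError(f"missing voxel-size sidecar {side_path}: voxel size required")
    side = json.loads(side_path.read_text())
    data = tifffile.imread(path)
    if data.ndim == 2:
        data = data[None]
    return LabelVolume3D(data=data > 0, voxel_size=tuple(side["voxel_size_um"]))


def write_trajectory(traj: Trajectory, path: str | Path) -> Path:
    pd.DataFrame({"time_s": traj.times, "x_mm": traj.x, "y_mm": traj.y}).to_csv(
        path, index=False, float_format="%.9g")
    return Path(path)


def read_trajectory(path: str | Path) -> Trajectory:
    df = pd.read_csv(path)
    needed = {"time_s", "x_mm", "y_mm"}
    if not needed <= set(df.columns):
        raise SchemaError(f"{path}: needs columns {sorted(needed)}")
    return Trajectory(times=df["time_s"].to_numpy(), x=df["x_mm"].to_numpy(),
                      y=df["y_mm"].to_numpy())


def write_animal_table(df: pd.DataFrame, path: str | Path) -> Path:
    df.to_csv(path, index=False)
    return Path(path)


def read_animal_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    needed = {"animal_id", "birthdate", "factor2", "n_total", "n_pos"}
    missing = needed - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing columns {sorted(missing)}")
    return df


def _jsonable(obj):
    """Best-effort conversion of metadata to JSON-storable values."""
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    if isinstance(obj, (str, int, float, bool)) or obj is None:
        return obj
    return repr(obj)
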