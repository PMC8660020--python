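"""End-to-end orchestration: configuration, stage dispatch, manifests.

A run is described by a JSON config with per-stage sections; stages execute
in dependency order, every output file is checksummed, and the manifest
records the config hash and seeds so deterministic stages are
bit-reproducible.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

from natalmap import io, study
from natalmap.intrinsic import (
    capacitance,
    fi_curve_and_rheobase,
    fit_membrane_time_constant,
    measure_input_resistance,
    measure_rebound,
    measure_sag,
)
from natalmap.resampling import (
    BootstrapConfig,
    build_group_vector,
    frame_to_animals,
    pairwise_bootstrap_suite,
)
from natalmap.behavior import path_distance, center_occupancy
from natalmap.anatomy import colocalize_objects, mask_overlap_volume
from natalmap.sweeps import StepProtocol
from natalmap.synth import (
    CohortGroupSpec,
    CohortSimParams,
    NeuronParams,
    PscSimParams,
    VolumeSimParams,
    simulate_colabel_cohort,
    simulate_current_clamp,
    simulate_label_volume,
    simulate_psc_trace,
    simulate_trajectory,
)

__all__ = ["RunConfig", "RunManifest", "PipelineError", "run_pipeline"]

STAGES = ("simulate_neuron", "simulate_psc", "simulate_cohort", "simulate_volume",
          "simulate_trajectory", "intrinsic", "stats", "coloc", "behavior")


class PipelineError(RuntimeError):
    """Structured stage failure: names the stage and offending input."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    stages: list[str]
    out_dir: Path
    seed: int = 0
    params: dict = field(default_factory=dict)
    log_level: str = "INFO"

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        if not path.exists():
            raise PipelineError("config", f"config file not found: {path}")
        cfg = json.loads(path.read_text())
        unknown = set(cfg.get("stages", [])) - set(STAGES)
        if unknown:
            raise PipelineError("config", f"unknown stages {sorted(unknown)}")
        return cls(stages=list(cfg.get("stages", [])),
                   out_dir=Path(cfg.get("out_dir", "results")),
                   seed=int(cfg.get("seed", 0)),
                   params=cfg.get("params", {}),
                   log_level=cfg.get("log_level", "INFO"))


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    stages: list[str]
    outputs: dict[str, str]  # path -> sha256
    started: float
    finished: float

    def write(self, path: Path) -> None:
        path.write_text(json.dumps({
            "config_hash": self.config_hash, "seed": self.seed,
            "stages": self.stages, "outputs": self.outputs,
            "started": self.started, "finished": self.finished,
        }, indent=1))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _stage_simulate_neuron(cfg: RunConfig, out: Path) -> list[Path]:
    p = cfg.params.get("simulate_neuron", {})
    neuron = NeuronParams(**p.get("neuron", {}))
    proto = StepProtocol(
        step_onset=p.get("step_onset", 0.2),
        step_duration=p.get("step_duration", study.SUBTHRESHOLD_STEP_S),
        amplitudes=tuple(p.get("amplitudes", study.SUBTHRESHOLD_AMPLITUDES_PA)),
        baseline_window=(0.0, p.get("step_onset", 0.2)),
    )
    sweeps = simulate_current_clamp(neuron, proto, dt=study.SAMPLE_INTERVAL_S,
                                    seed=cfg.seed, noise_sd=p.get("noise_sd", 0.0))
    return [io.write_sweepset(sweeps, out / "neuron_sweeps.csv"),
            out / "neuron_sweeps.json"]


def _stage_simulate_psc(cfg: RunConfig, out: Path) -> list[Path]:
    p = cfg.params.get("simulate_psc", {})
    sweeps, events = simulate_psc_trace(PscSimParams(**p), seed=cfg.seed)
    events.to_csv(out / "psc_events_truth.csv", index=False)
    return [io.write_sweepset(sweeps, out / "psc_sweeps.csv"),
            out / "psc_sweeps.json", out / "psc_events_truth.csv"]


def _stage_simulate_cohort(cfg: RunConfig, out: Path) -> list[Path]:
    p = cfg.params.get("simulate_cohort", {})
    groups = p.get("groups")
    if groups is None:
        groups = [
            {"birthdate": b, "factor2": t, "p": 0.1 + 0.05 * i, "n_animals": 4}
            for i, (b, t) in enumerate(
                (b, t) for b in study.BIRTHDATES for t in study.TRACING_TARGETS)
        ]
    specs = tuple(CohortGroupSpec(**g) for g in groups)
    animals = simulate_colabel_cohort(CohortSimParams(groups=specs, seed=cfg.seed))
    from natalmap.resampling import animals_to_frame
    path = io.write_animal_table(animals_to_frame(animals), out / "cohort.csv")
    return [path]


def _stage_simulate_volume(cfg: RunConfig, out: Path) -> list[Path]:
    p = cfg.params.get("simulate_volume", {})
    params = VolumeSimParams(
        shape=tuple(p.get("shape", (120, 120, 40))),
        voxel_size=tuple(p.get("voxel_size", (0.2, 0.2, 0.41))),
        planted_overlaps=p.get("planted_overlaps", 3),
        extra_a=p.get("extra_a", 2), extra_b=p.get("extra_b", 2),
        radius_um=p.get("radius_um", 1.0),
    )
    vol_a, vol_b, gt = simulate_label_volume(params, seed=cfg.seed)
    paths = [io.write_label_volume(vol_a, out / "mask_a.tif"),
             io.write_label_volume(vol_b, out / "mask_b.tif")]
    (out / "volume_truth.json").write_text(json.dumps({
        "overlap_voxels": gt["overlap_voxels"],
        "n_overlap_objects": gt["n_overlap_objects"],
    }))
    return paths + [out / "mask_a.json", out / "mask_b.json", out / "volume_truth.json"]


def _stage_simulate_trajectory(cfg: RunConfig, out: Path) -> list[Path]:
    p = cfg.params.get("simulate_trajectory", {})
    traj = simulate_trajectory(study.ARENA, n_steps=p.get("n_steps", 10_000),
                               step_sd=p.get("step_sd", 10.0),
                               dt=p.get("dt", 0.04), seed=cfg.seed)
    return [io.write_trajectory(traj, out / "trajectory.csv")]


def _stage_intrinsic(cfg: RunConfig, out: Path) -> list[Path]:
    p = cfg.params.get("intrinsic", {})
    traces = Path(p.get("traces", out / "neuron_sweeps.csv"))
    if not traces.exists():
        raise PipelineError("intrinsic", f"input not found: {traces}")
    sweeps = io.read_sweepset(traces)
    result: dict = {"rm_mohm": measure_input_resistance(sweeps)}
    try:
        tau, diag = fit_membrane_time_constant(sweeps)
        result["tau_m_ms"] = tau
        result["cm_pf"] = capacitance(tau, result["rm_mohm"])
        result["tau_fit"] = diag
    except ValueError:
        pass
    for name, fn in (("sag_mv", measure_sag), ("rebound_mv", measure_rebound)):
        try:
            result[name] = fn(sweeps)
        except ValueError:
            pass
    try:
        fi, rheo = fi_curve_and_rheobase(sweeps)
        result["fi_curve"] = {str(k): v for k, v in fi.items()}
        result["rheobase_pa"] = rheo
    except ValueError:
        pass
    path = out / "intrinsic.json"
    path.write_text(json.dumps(io._jsonable(result), indent=1))
    return [path]


def _stage_stats(cfg: RunConfig, out: Path) -> list[Path]:
    p = cfg.params.get("stats", {})
    table = Path(p.get("table", out / "cohort.csv"))
    if not table.exists():
        raise PipelineError("stats", f"input not found: {table}")
    animals = frame_to_animals(io.read_animal_table(table))
    keys = sorted({(a.birthdate, a.factor2) for a in animals})
    groups = {k: build_group_vector(animals, k) for k in keys}
    boot = BootstrapConfig(n_iter=p.get("n_iter", study.BOOTSTRAP_ITERS),
                           ci_level=p.get("ci_level", study.CI_TRACING),
                           statistic=p.get("statistic", "mean"), seed=cfg.seed)
    table_df = pairwise_bootstrap_suite(groups, boot,
                                        correction=p.get("correction", "holm"))
    path = out / "pairwise_bootstrap.csv"
    table_df.to_csv(path, index=False)
    return [path]


def _stage_coloc(cfg: RunConfig, out: Path) -> list[Path]:
    p = cfg.params.get("coloc", {})
    pa = Path(p.get("mask_a", out / "mask_a.tif"))
    pb = Path(p.get("mask_b", out / "mask_b.tif"))
    for q in (pa, pb):
        if not q.exists():
            raise PipelineError("coloc", f"input not found: {q}")
    a, b = io.read_label_volume(pa), io.read_label_volume(pb)
    overlap = mask_overlap_volume(a, b)
    objs = colocalize_objects(a, b, connectivity=p.get("connectivity", 26),
                              min_size=p.get("min_size", 0))
    path = out / "coloc.json"
    path.write_text(json.dumps({
        "overlap_voxels": overlap.voxel_count,
        "overlap_um3": overlap.overlap_um3,
        "overlap_per_z_um3": overlap.overlap_per_z_um3,
        "n_objects": len(objs),
        "object_voxel_counts": [o.voxel_count for o in objs],
    }, indent=1))
    return [path]


def _stage_behavior(cfg: RunConfig, out: Path) -> list[Path]:
    p = cfg.params.get("behavior", {})
    traj_path = Path(p.get("traj", out / "trajectory.csv"))
    if not traj_path.exists():
        raise PipelineError("behavior", f"input not found: {traj_path}")
    traj = io.read_trajectory(traj_path)
    path = out / "behavior.json"
    path.write_text(json.dumps({
        "path_distance_mm": path_distance(traj),
        "center_occupancy_pct": center_occupancy(traj, study.ARENA),
    }, indent=1))
    return [path]


_STAGE_FNS = {
    "simulate_neuron": _stage_simulate_neuron,
    "simulate_psc": _stage_simulate_psc,
    "simulate_cohort": _stage_simulate_cohort,
    "simulate_volume": _stage_simulate_volume,
    "simulate_trajectory": _stage_simulate_trajectory,
    "intrinsic": _stage_intrinsic,
    "stats": _stage_stats,
    "coloc": _stage_coloc,
    "behavior": _stage_behavior,
}


def run_pipeline(cfg: RunConfig) -> RunManifest:
    """Execute the selected stages in declaration order, write the manifest."""
    started = time.time()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_hash = hashlib.sha256(json.dumps(
        {"stages": cfg.stages, "seed": cfg.seed, "params": cfg.params},
        sort_keys=True).encode()).hexdigest()
    outputs: dict[str, str] = {}
    for stage in cfg.stages:
        fn = _STAGE_FNS.get(stage)
        if fn is None:
            raise PipelineError(stage, "unknown stage")
        try:
            paths = fn(cfg, out)
        except PipelineError:
            raise
        except Exception as err:
            raise PipelineError(stage, str(err)) from err
        for p in paths:
            outputs[str(p)] = _sha256(Path(p))
    manifest = RunManifest(config_hash=cfg_hash, seed=cfg.seed, stages=cfg.stages,
                           outputs=outputs, started=started, finished=time.time())
    manifest.write(out / "manifest.json")
    return manifest
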