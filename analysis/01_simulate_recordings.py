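#!/usr/bin/env python
"""Generate the synthetic study inputs used by the downstream analyses.

Three model cells stand in for the three birthdate groups: they differ in
input resistance and sag conductance (the mid-gestation group gets the
highest Rm and g_h, mirroring the direction of the reported group effects).
Also writes spontaneous EPSC/IPSC sweeps, an evoked paired-pulse set, a
co-labeling cohort for both two-factor designs, 3D label volumes with
planted overlaps, and open-field trajectories.

Outputs go to results/analysis/inputs/.
"""

import json
from pathlib import Path

from natalmap import io, study
from natalmap.resampling import animals_to_frame
from natalmap.sweeps import StepProtocol
from natalmap.synth import (
    CohortGroupSpec,
    CohortSimParams,
    NeuronParams,
    PscSimParams,
    VolumeSimParams,
    simulate_colabel_cohort,
    simulate_current_clamp,
    simulate_evoked_psc,
    simulate_label_volume,
    simulate_psc_trace,
    simulate_trajectory,
)

SEED = 20
OUT = Path("results/analysis/inputs")

# ground-truth membrane parameters per group: the middle group is the most
# excitable (highest Rm) and has the largest h-conductance
CELL_PARAMS = {
    "E12.5": NeuronParams(r_m=90.0, c_m=180.0, g_h=1.0, v_thresh=-50.0),
    "E14.5": NeuronParams(r_m=140.0, c_m=180.0, g_h=2.5, v_thresh=-50.0),
    "E16.5": NeuronParams(r_m=100.0, c_m=180.0, g_h=1.5, v_thresh=-50.0),
}

PSC_PARAMS = {
    "EPSC": PscSimParams(rate=2.0, amp_mean=30.0, amp_sd=8.0, tau_rise=0.5,
                         tau_decay=5.0, polarity="inward", noise_sd=3.0,
                         duration=study.VC_SWEEP_S, n_sweeps=study.SPONTANEOUS_STAT_SWEEPS),
    "IPSC": PscSimParams(rate=4.0, amp_mean=45.0, amp_sd=10.0, tau_rise=1.0,
                         tau_decay=12.0, polarity="outward", noise_sd=3.0,
                         duration=study.VC_SWEEP_S, n_sweeps=study.SPONTANEOUS_STAT_SWEEPS),
}


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)

    sub = StepProtocol(0.2, study.SUBTHRESHOLD_STEP_S,
                       study.SUBTHRESHOLD_AMPLITUDES_PA, (0.0, 0.2))
    pulse = StepProtocol(0.2, 0.5, (study.TAU_PULSE_PA,), (0.0, 0.2))
    sag = StepProtocol(0.2, study.SAG_STEP_S, (study.SAG_STEP_PA,), (0.0, 0.2))
    fi = StepProtocol(0.2, study.FI_STEP_S, study.FI_AMPLITUDES_PA, (0.0, 0.2))

    truth = {}
    for group, params in CELL_PARAMS.items():
        # passive protocols (Rm, tau) on the g_h-free twin: the h-conductance
        # legitimately depresses the measured I-V slope below r_m, so the
        # recovery check targets the passive membrane
        passive = NeuronParams(v_rest=params.v_rest, r_m=params.r_m, c_m=params.c_m,
                               g_h=0.0)
        for name, proto, cell in (("sub", sub, passive), ("pulse", pulse, passive),
                                  ("sag", sag, params), ("fi", fi, params)):
            sw = simulate_current_clamp(cell, proto, dt=study.SAMPLE_INTERVAL_S,
                                        seed=SEED, noise_sd=0.1)
            io.write_sweepset(sw, OUT / f"cc_{group}_{name}.csv")
        truth[group] = {"r_m": params.r_m, "c_m": params.c_m, "tau_m": params.tau_m,
                        "g_h": params.g_h}
    (OUT / "cc_ground_truth.json").write_text(json.dumps(truth, indent=1))

    for name, params in PSC_PARAMS.items():
        holding = study.HOLDING_EPSC_MV if name == "EPSC" else study.HOLDING_IPSC_MV
        sweeps, events = simulate_psc_trace(params, seed=SEED)
        sweeps.meta["holding_mv"] = holding
        io.write_sweepset(sweeps, OUT / f"vc_{name}.csv")
        events.to_csv(OUT / f"vc_{name}_truth.csv", index=False)

    ppr = simulate_evoked_psc((0.1, 0.1 + study.PPR_INTERVAL_S), (-100.0, -130.0),
                              tau_rise=1.0, tau_decay=10.0, noise_sd=2.0,
                              n_sweeps=10, seed=SEED)
    io.write_sweepset(ppr, OUT / "vc_ppr.csv")

    # cohorts: tracing (3 x 5 targets) and exploration (3 x 3 conditions);
    # the E14.5 x LS cell carries a planted enrichment
    tracing = tuple(
        CohortGroupSpec(b, t, 0.45 if (b, t) == ("E14.5", "LS") else 0.15,
                        n_animals=4, cells_per_animal=(40, 120))
        for b in study.BIRTHDATES for t in study.TRACING_TARGETS)
    cfos = tuple(
        CohortGroupSpec(b, c, {"HC": 0.05, "FAM": 0.15, "NOV": 0.25}[c],
                        n_animals=study.CFOS_MICE[b][c], cells_per_animal=(60, 150))
        for b in study.BIRTHDATES for c in study.CONDITIONS)
    for name, groups in (("tracing", tracing), ("cfos", cfos)):
        animals = simulate_colabel_cohort(CohortSimParams(groups=groups, seed=SEED))
        io.write_animal_table(animals_to_frame(animals), OUT / f"cohort_{name}.csv")

    vol_a, vol_b, gt = simulate_label_volume(
        VolumeSimParams(shape=(200, 200, 60), voxel_size=(0.2, 0.2, 0.41),
                        planted_overlaps=5, extra_a=4, extra_b=4), seed=SEED)
    io.write_label_volume(vol_a, OUT / "mask_tdt.tif")
    io.write_label_volume(vol_b, OUT / "mask_cfos.tif")
    (OUT / "mask_truth.json").write_text(json.dumps(
        {"overlap_voxels": gt["overlap_voxels"],
         "n_overlap_objects": gt["n_overlap_objects"]}, indent=1))

    for i, cond in enumerate(study.CONDITIONS):
        traj = simulate_trajectory(study.ARENA, n_steps=30_000, step_sd=8.0 + 4.0 * i,
                                   dt=0.04, seed=SEED + i)
        io.write_trajectory(traj, OUT / f"trajectory_{cond}.csv")

    print(f"wrote synthetic inputs for {len(CELL_PARAMS)} cells, "
          f"{len(PSC_PARAMS)} PSC polarities, 2 cohorts, 2 masks, "
          f"{len(study.CONDITIONS)} trajectories -> {OUT}")


if __name__ == "__main__":
    main()
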