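"""Published study-design inputs used as fixture data.

These are the printed design numbers of the birthdate study this pipeline
reanalyzes: group sizes per experiment, the exploration cohort table, the
whole-CA1 abundance means, the acquisition and protocol settings, and the
bootstrap configuration per analysis.  They parameterize the synthetic-data
generators and the bookkeeping checks; none of them is a measured output of
this package.
"""

from __future__ import annotations

from natalmap.behavior import ArenaGeometry

BIRTHDATES = ("E12.5", "E14.5", "E16.5")

# retrograde-tracing target regions (second design factor, tracing arm)
TRACING_TARGETS = ("Amy", "LHA", "LS", "NAcc", "mPFC")

# exploration conditions (second design factor, cFos arm)
CONDITIONS = ("HC", "FAM", "NOV")

# cells per birthdate group in the two slice-physiology experiments
VOLTAGE_CLAMP_CELLS = {"E12.5": 12, "E14.5": 15, "E16.5": 13}
CURRENT_CLAMP_CELLS = {"E12.5": 10, "E14.5": 12, "E16.5": 10}
TOTAL_RECORDED_CELLS = 72

# neurobiotin-filled cells used for dendrite morphometry ("Sixty-three")
MORPHOLOGY_CELLS = {"E12.5": 30, "E14.5": 14, "E16.5": 19}
TOTAL_MORPHOLOGY_CELLS = 63

# exploration cohort: mice per birthdate x condition (printed total 25)
CFOS_MICE = {
    "E12.5": {"HC": 2, "FAM": 2, "NOV": 3},
    "E14.5": {"HC": 3, "FAM": 3, "NOV": 4},
    "E16.5": {"HC": 2, "FAM": 3, "NOV": 3},
}
TOTAL_CFOS_MICE = 25

# whole-CA1 fate-mapped cell counts per brain (mean), clarified-brain counts
ABUNDANCE_MEAN_CELLS = {"E12.5": 917, "E14.5": 6810, "E16.5": 3585}

# acquisition: 10 kHz digitization
SAMPLE_INTERVAL_S = 1e-4

# current-clamp step protocols
SUBTHRESHOLD_STEP_S = 0.5          # 500 ms subthreshold steps from -100 pA
SUBTHRESHOLD_AMPLITUDES_PA = tuple(float(a) for a in range(-100, 0, 20))
SAG_STEP_PA = -200.0               # 1 s step for sag/rebound
SAG_STEP_S = 1.0
FI_STEP_S = 1.0                    # depolarizing steps up to 500 pA, +40 pA
FI_AMPLITUDES_PA = tuple(float(a) for a in range(40, 501, 40))
TAU_PULSE_PA = -20.0               # small pulse for the biexponential tau fit

# voltage clamp: 9 sweeps of 20 s; spontaneous statistics over 2 min (6 sweeps)
VC_SWEEPS = 9
VC_SWEEP_S = 20.0
SPONTANEOUS_STAT_SWEEPS = 6
HOLDING_EPSC_MV = -86.0            # GABA reversal -> inward EPSC
HOLDING_IPSC_MV = 0.0              # glutamate reversal -> outward IPSC
LIQUID_JUNCTION_MV = -13.0         # applied to VC command potentials
RS_MAX_MOHM = 30.0
RS_MAX_VARIATION = 0.2
PPR_INTERVAL_S = 0.05

# bootstrap inference settings
BOOTSTRAP_ITERS = 10_000
CI_TRACING = 0.999
CI_CFOS = 0.95
TRACING_N_TESTS = 45
CFOS_N_TESTS = 18

# PV-bouton imaging voxel size (µm)
PV_VOXEL_UM = (0.06, 0.06, 0.41)

# exploration arena (mm) with its center zone
ARENA = ArenaGeometry(width=435.0, height=290.0,
                      center_width=290.0, center_height=193.0)
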