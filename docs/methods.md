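# Methods

This note documents the models, estimators and numerical choices behind
natalmap, what the synthetic-data generators do and do not emulate, and the
decisions taken where the underlying procedures were open to interpretation.

## Model neuron

The current-clamp simulator integrates a single-compartment membrane with an
optional hyperpolarization-activated conductance:

    C_m dV/dt = -(V - V_rest)/R_m - g_h h (V - E_h) + I(t)
        dh/dt = (h_inf(V) - h) / tau_h
      h_inf(V) = 1 / (1 + exp((V - v_half_h)/k_h))

in patch-clamp units (mV, pA, MΩ, pF, nS, ms). The gating variable is a
minimal first-order mechanism chosen to reproduce sag-and-rebound
phenomenology, not a biophysical HCN model; the defaults v_half_h = −80 mV,
k_h = 6 mV, tau_h = 50 ms are simulator conventions. Integration is
fixed-step exponential Euler at dt = 1e-4 s (the 10 kHz acquisition grid of
the recordings the simulator emulates); with conductances frozen over a step
the update is exact, and the passive (g_h = 0) trace matches the RC closed
form to ~1e-13 mV. The step size is rejected if it exceeds a tenth of either
time constant. Agreement with an implicit (Radau) reference solution is
tested to < 0.05 mV on the sag protocol.

Spiking is hard-threshold integrate-and-fire: threshold crossing resets V to
v_reset for a refractory period, and one sample is painted at +30 mV so that
crossing-based spike detectors register the event; IF spikes carry no
waveform, so action-potential features are tested on a separate parametric
waveform whose upstroke is a raised sine starting exactly at the designed
threshold — curvature is maximal at the onset, which places the
second-derivative peak at the constructed threshold by design. The
threshold-by-curvature measure carries an upward discretization bias of
roughly one sample of upstroke (~3 mV at 10 kHz for a 0.8 ms rise); waveform
validation therefore samples at 100 kHz, where the bias is < 0.05 mV. The
analytic rheobase (v_thresh − V_0) · g_eff is attached as ground truth; for
g_h > 0 it uses the resting activation and is an approximation.

## PSC model and kinetics

Events are a homogeneous Poisson process; each adds
a · (exp(−t/τ_d) − exp(−t/τ_r)), scaled by the closed-form peak at
t* = ln(τ_d/τ_r) · τ_r τ_d / (τ_d − τ_r) so the drawn amplitude is the peak
amplitude. Gaussian noise is added per sample. Real recordings differ in
ways the generator ignores: correlated (1/f and synaptic-background) noise,
amplitude–kinetics correlations, series-resistance filtering of fast events,
and non-Poisson timing. Passing detection/recovery tests therefore
demonstrates correctness of the estimators under ideal event shapes, not
detector performance parity on real data.

Event detection (plumbing, not a replication of the commercial detector
used for the original recordings): deviations from a running median
(200 ms window evaluated every 10 ms and interpolated) beyond a threshold,
default 4× the robust (MAD-based) sd of the deviation signal; the MAD is
taken on the deviation rather than on first differences because zero-phase
low-pass filtering leaves strongly correlated noise. Peaks are the extremum
within 10 ms of the crossing; events within 5 ms merge; detection re-arms
only after the deviation falls below half the threshold, which suppresses
double counts on decaying tails. At the default threshold a pure-noise sweep
yields ~0.15 false events/s; at 5× the raw noise sd (the setting used in the
validation tests) the false rate is ≈ 0.

Mean-event kinetics are measured on the peak-aligned average over a
[−5, +40] ms window (edge events dropped and counted), baseline = first 2 ms
of the window: 10–90% rise and 90–37% decay via linear interpolation of
level crossings, decay τ by least-squares monoexponential from the 90% point
of the descent to the first baseline re-crossing, half-width at 50% of peak,
area by trapezoidal integration. Evoked responses average up to 10 sweeps;
the response baseline is the mean between the stimulus and the onset of the
ascending phase, operationalized as the first run of 5 consecutive samples
deviating more than 3 pre-stimulus sds (configurable); with multi-peak
responses the decay fit starts after the last detected peak. The
paired-pulse ratio measures both peaks from the common pre-pulse-1 baseline
with no decay subtraction by default — the alternative policy (subtract the
extrapolated monoexponential decay of response 1 under pulse 2) is
implemented behind `subtract_decay=True`; with 50 ms intervals and τ ≈ 10 ms
the two agree, with slow decays the default reads higher, and both policies
are exercised in tests. Series resistance is ΔV divided by the peak
test-pulse transient; QC passes below a 30 MΩ mean and 20% max variation.
A −13 mV liquid-junction correction applies to voltage-clamp holding
potentials at the I/O layer (current clamp is uncorrected), and analyses
reject a polarity inconsistent with the holding potential (inward events at
the GABA reversal −86 mV, outward at 0 mV).

## Bootstrap inference on pooled binary vectors

Cells are treated as independent Bernoulli trials pooled across animals of
the same design cell — deliberately ignoring the nested cell-within-animal
structure, as the original procedure does; an animal-level sensitivity mode
is not the default. For a pair of group vectors, both are independently
resampled with replacement at their own sizes for n_iter = 10,000
iterations; the difference of the configured statistic (mean for co-labeling
fractions, median for skewed numeric measures) is accumulated; the CI is the
empirical percentile interval (linear interpolation between order
statistics; BCa deliberately not used, for fidelity to the stated
procedure); significance is 0 outside the CI. A two-sided bootstrap p —
2·min(P(Δ≤0), P(Δ≥0)), floored at 2/n_iter — is attached because the
family-wise corrections need p-values; the floor means adjusted p-values
below 2m/n_iter are not resolvable.

Implementation notes. Each group's resampling stream is keyed by the global
seed, the comparison key, and a digest of the group's sorted content, which
makes results bit-reproducible, invariant to permutation within groups,
exactly antisymmetric under swapping the two groups, and stable when
comparisons are added. For 0/1 vectors with the mean statistic the resampled
mean is Binomial(n, p̂)/n exactly, and the implementation draws it directly
(method="auto"); the generic index-resampling path (method="resample") is
retained and the two are cross-checked. Monte-Carlo calibration on Bernoulli
nulls (n = 100/group, 1,000 replicates) gives a false-positive rate of
~0.04–0.05 at the 95% CI and ≤ 0.01 at 99.9%; a planted p = 0.1 vs 0.6
effect at n = 200 is detected in 10/10 replicates at the 99.9% CI.

Pairwise comparisons in two-factor designs are restricted to pairs sharing
one factor level — the rule that reproduces both printed test counts
(45 for 3 × 5, 18 for 3 × 3) and is verified against exhaustive enumeration
for all designs up to 6 × 6. Holm–Bonferroni is implemented as the standard
step-down adjustment (cross-checked against statsmodels); the Šidák
per-comparison alpha 1 − (1 − α)^(1/m) gives 0.016952 for m = 3, printed
as 0.0169 (truncated). Correlations with cell position are tested by paired
bootstrap of the Pearson r; because published legends report intervals on
either r or the regression slope, both CIs are emitted.

## Imaging operators

The minimum-cross-entropy threshold minimizes
−Σ_c m_c μ_c ln μ_c over the two classes exhaustively across all distinct
histogram levels — the definitional form of the criterion — and returns the
midpoint between the boundary levels; scikit-image's iterative solver is an
independent cross-check (agreement is asserted on the induced partition,
since any threshold inside an empty intensity gap segments identically). The
robust-background threshold is trimmed mean + k·sd after discarding the 5%
lowest and highest intensities (k = 2), the documented defaults of the tool
it reimplements. Mask overlap is the voxelwise AND count times the physical
voxel volume (anisotropic voxels handled in physical units, no resampling),
normalized by the number of z-steps of the stack; normalizing by the soma's
own z-extent is available as an option since the published wording is
ambiguous. Object colocalization labels the mask product with 26-connectivity
by default (6 by flag); the min-size filter defaults to 0 here and to 10 in
pipeline configs, standing in for the manual confirmation step that is out
of scope. Rasterization places voxel centers at (i + 0.5)·d; a rasterized
sphere's volume is within 10% of 4/3 π r³ once r ≥ 5 voxel dims.

## Positions, morphology, behavior

Radial positions are signed distances from the SP/SR border (positive toward
stratum oriens) divided by the local SP thickness, unclamped so ectopic
cells read outside [0, 1]. Quantiles (median, IQR) use linear interpolation.
Dendrite length approximates the primary dendrite by 1–3 straight segments.
Path distance is the sum of consecutive displacements, unsmoothed (no
smoothing is applied by the tracking emulation either). Center occupancy
weights each sample by its forward interval, with the median interval for
the last sample — the tracking software's own rule is unknown, and for the
regular sampling used here any sane rule agrees. The arena is 435 × 290 mm
with a centered 290 × 193 mm zone (44.4% by area), and uniform positions
reproduce that fraction within Monte-Carlo error.

## Synthetic cohorts and volumes

Cohort generators draw per-animal totals (uniform in a configurable range,
default 40–120 cells) and co-label counts Binomial(n, p) with the group's
true p — the conditions used in the calibration and power checks (n = 100
and 200 cells per group) sit inside the realistic per-animal range. Volume
generators either rasterize caller-specified ellipsoids or plant k
overlapping A–B sphere pairs (B shifted by half a radius) plus disjoint
extras on a lattice with > 2-voxel separation, so the planted pair count is
the ground-truth object count by construction. All generators fan a single
seed into named child streams (BLAKE2-keyed SeedSequence), so adding a
generator never shifts another's draws.

## Problem sizes

Default validation sizes: 20 s sweeps at 10 kHz, 6-cell passive grids,
1,000-replicate bootstrap calibration at 10,000 iterations (using the exact
binomial path), 200³-voxel volumes, 1e5-sample occupancy checks. These are
the sizes the test suite and the acceptance script use.

## Known limitations

The Ih mechanism, IF spiking, and Gaussian noise are deliberately minimal;
amplifier filtering (2.9 kHz low-pass at acquisition) is not emulated.
Event detection is a simple threshold detector, not a template-matching
replication. ROUT outlier removal, ANOVA/Tukey comparisons, trainable
segmentation, and atlas registration are out of scope. Which biexponential
component is "the" membrane time constant is a convention (larger-amplitude
component, recorded in the fit diagnostics). The F–I step grid is
configurable because published protocol descriptions are internally
inconsistent about the number of current levels.
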