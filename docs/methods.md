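# Methods

## Waveform model

A sweep is 200 ms sampled at 10 kHz with the stimulus at 60 ms, leaving
a full 50 ms pre-stimulus noise window and 140 ms of post-stimulus
response. The evoked response is assembled from:

* a brief biphasic **stimulus artifact** (default 0.4 mV) confined to
  the 2 ms blanking interval;
* an optional Gaussian **fiber volley** (MF configurations: 0.12 mV,
  σ = 0.35 ms) just before the fEPSP onset, constant across
  potentiation and facilitation because it is axonal, not synaptic;
* the **fEPSP**: a negative-going difference of exponentials
  `−A·(e^(−t/τ_d) − e^(−t/τ_r))/g_max` with rise τ_r = 1 ms, decay
  τ_d = 8 ms and onset 2 ms after the stimulus (4 ms for MF), normalized
  so the trough depth equals the configured amplitude `A` (default
  1 mV). The kinetic constants are phenomenological: they reproduce the
  morphology of interface-chamber CA3 field potentials, but absolute
  amplitudes and noise levels are not constrained by any public data and
  are plainly configurable placeholders.

White Gaussian noise (σ = 0.02 mV) is added and the sum passes a
**causal** 4th-order Butterworth low-pass at 1 kHz emulating the analog
acquisition chain. Causality matters: a zero-phase filter would smear
the stimulus artifact backwards into the pre-stimulus window and inflate
the peak-to-peak noise estimate that the afterpotential threshold rests
on (we measured a 2.5× inflation before switching).

## Afterpotentials: depth, injection, detection

Afterpotentials ride on the decaying fEPSP, so "depth" is
operationalized as **topographic prominence** of the local minimum
within an 8 ms window, not absolute voltage. Detection scans the
interval from (trough + 3 ms refractory gap) to 120 ms post-stimulus
and keeps strict local minima whose prominence strictly exceeds
`threshold_multiplier × peak-to-peak noise` (default 2.0), where the
noise estimate is the mean max-minus-min of the 50 ms pre-stimulus
segment over the ten designated sweeps of the phase (−5…−0.5 min before
induction, 0.5…5 min after). The detector is deterministic and sees only
the trace and the noise estimate — a label-permutation test verifies
that group identity cannot leak into the count, which is the property
the original blinded manual counting protected.

The generator injects raised-cosine dips (width 3 ms) on a jittered
grid (centers ≥ 7 ms apart, latency 8–95 ms after the trough) and
**calibrates** each dip iteratively so that its realized prominence on
the filtered noise-free trace equals `depth_multiplier ×` the
peak-to-peak noise reference (aiming 3% high so the ground-truth
contract `prominence ≥ multiplier × reference` holds with margin). With
the default multiplier of 4 relative to the *realized* per-slice noise,
detector recall on synthetic cohorts is complete; the acceptance suite
additionally verifies 100% recall at 3× depth and zero false positives
at 1.5× depth under the 2× rule.

Per-slice incidence follows a two-level model: a slice expresses the
afterpotential process in a phase with the configured presence
probability (set from the reported per-subgroup incidence), and an
expressing slice draws per-sweep counts from a Poisson distribution
(N1: λ matched to the reported 5.9/9.8 mean counts; elsewhere λ = 1.2 -
2.0, the one-or-two-extra-peaks morphology described for control
tissue). An expressing slice is guaranteed at least one event in its
designated window. Counts are truncated at the 13 available latency
slots — a ~1% downward bias on the N1 means, well inside the reported
SEM. In control configurations the after-phase intensity scales with
the slice's drawn potentiation factor (exponent 1), which is what makes
the fold-change-of-peaks vs LTP correlation positive there; NMDAR-CSF
configurations are uncoupled, mirroring the dissociation the study
design probes.

## Plasticity metrics

* **LTP magnitude** uses slopes: mean over the last 5 min (the final 10
  sweeps at the 30 s cadence) as a percentage of the baseline mean. The
  baseline excludes the first 2 sweeps as settling; this exclusion is a
  design choice, not a reported rule.
* **PPR** uses amplitudes (deliberate asymmetry with the slope-based
  LTP): the second response is measured after subtracting a log-linear
  exponential extrapolation of the first response's decay fitted between
  (trough + 2 ms) and the second stimulus. Interstimulus interval is
  40 ms for both pathways (reported for MF; unreported for A/C, set
  equal).
* **1 Hz facilitation**: response amplitude ramps linearly to the
  slice's facilitation factor over the first five train pulses and holds
  there; the analysis averages pulses 6–30 as the steady state (the
  steady-state window is a design choice). The fiber volley is reported
  alongside and stays at 100%.
* **DCG-IV residual**: last-10-sweep plateau after drug onset over the
  pre-drug plateau, with a below-noise-floor flag.
* **I/O curves**: responses follow a Hill curve in intensity; the
  baseline convention places the configured amplitude at 45% of maximum,
  and the analysis returns the interpolated intensity producing 40–50%
  of the maximal response, rejecting flat curves.

Potentiation is applied as a constant per-slice scale factor from the
induction marker onward, drawn once per slice from a **log-normal**
distribution whose mean and SD come from each subgroup's reported
mean ± SEM and n (SD = SEM·√n). Log-normal rather than normal because
slice LTP distributions are positive and right-skewed. The same recipe
parameterizes PPR, facilitation and DCG-IV suppression. D-AP5 is a
config transformation, not pharmacokinetics: A/C potentiation collapses
to 1.0, NMDAR-CSF afterpotential processes empty, control incidence and
MF potentiation are untouched.

## Statistics

Fisher's exact test is two-sided by the probability-mass rule (sum of
hypergeometric probabilities ≤ that of the observed table, 1e-7 relative
tie tolerance); this convention — and Yates continuity correction as the
χ² default — reproduces the reported contingency p-values exactly, and
the alternative conventions do not. The Student-Newman-Keuls stepdown
runs on the studentized range at fixed α = 0.05, testing ranges from
widest to narrowest and never inside a retained non-significant range;
for k = 3 its widest step coincides with the Tukey HSD decision, which
the tests exploit as a cross-check. Rank tests use exact distributions
for small tie-free samples (Mann-Whitney n ≤ 10 per group, Wilcoxon
n ≤ 25) and tie-corrected normal approximations otherwise. Standard
tests are computed by scipy/statsmodels behind the package's interface;
the SNK procedure is implemented here.

Type-I calibration uses 1000 seeded replicates per test. Continuous
tests run at small n (8–20 per group). The discrete tests (Fisher,
Yates χ²) are conservative by construction at small n — exact
enumeration over a two-binomial null puts the Yates test's true level at
0.040 for n = 250 versus 0.045 at n = 1000 — so their calibration uses
n = 1000 per group, the regime those tests are asymptotically meant for;
the n was chosen from the enumeration, not from simulation outcomes.

## Problem sizes

Synthetic LTP experiments run 10 min baseline + 20 min post (3 extra
paired-pulse sweeps up front; 10 DCG-IV sweeps appended for MF), i.e.
63–73 sweeps of 2000 samples per slice. The packaged cohorts are the
reported ones: 62 control and 40 NMDAR-CSF A/C slices, 10 NMDAR-CSF MF
slices, 14 control MF facilitation recordings. The full acceptance
recomputation takes seconds to tens of seconds on one CPU.

## What the synthetic cohorts do and do not show

The generator reproduces the *statistical structure* the analysis
assumes — waveform shape, stationary Gaussian noise, per-slice effect
sizes, incidence rates — so passing tests establish that the pipeline
measures what was injected, at the reported sample sizes and
variabilities. They do not establish performance on real recordings:
real noise is neither white nor stationary (line hum, slow drift),
population spikes can masquerade as a first "afterpotential",
potentiation develops over minutes rather than stepping, and the
original afterpotential counts involved human judgment whose residual
criteria beyond the stated threshold rule are unknowable. Real-data-only
quantities (the control-subgroup Kruskal-Wallis H = 6.452, the
fold-change/LTP correlation r = 0.753, the I/O two-way ANOVA
P = 0.062) are therefore not reproduction targets; the correlation is
checked for sign only under the coupled generator. Where the reported
summaries disagree (pooled control LTP 168 ± 8%, n = 54 in one place
vs 167 ± 8%, n = 62 in another; the NMDAR contingency row n = 46 vs
subgroup counts summing to 49), the package uses the Results-level
pooling of all five control subgroups and stores the printed table
verbatim. The N4 CSF sample appears only in the MF experiments and is
folded into the NMDAR MF configuration. At the reported N1/N2/N3 effect
sizes the SNK posthoc separates N3 from N1/N2 in roughly half of
replicate cohorts (simulated power 0.48/0.60) — a single real dataset
landing significant is entirely consistent with that.

## Known limitations

Phenomenological throughout: no conductance-based or network model, no
antibody diffusion/titer/post-operative-day effects. Afterpotential
counts above 13 per sweep are truncated by window geometry. The HDF5
layout is a convenience mirror of the text layout; vendor acquisition
formats (ABF/NWB) are out of scope and would enter as readers producing
`SliceRecording` objects.
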