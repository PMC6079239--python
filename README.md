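# ca3ltp

Evoked field-potential analysis for CA3 slice plasticity experiments —
and a synthetic sweep generator that makes every stage of the analysis
testable against known ground truth.

## The problem

In hippocampal area CA3, two afferent pathways converge on the same
pyramidal cells: associational-commissural (A/C) fibers, whose long-term
potentiation (LTP) is NMDA-receptor-dependent, and mossy fibers (MF),
whose LTP is not. Slice studies of anti-NMDAR encephalitis exploit this
to separate antibody effects on NMDAR-dependent plasticity from
NMDAR-independent plasticity, and additionally read out hyperexcitability
as *epileptiform afterpotentials* — extra negative deflections trailing
the field EPSP (fEPSP).

Analyzing such experiments means turning thousands of per-sweep voltage
traces into per-slice outcomes and cohort statistics:

* **fEPSP slope** — the maximal negative slope of the first peak,
  measured by a 1 ms sliding linear regression between stimulus and
  trough (stimulus artifact blanked);
* **LTP magnitude** — mean slope of the last 5 min of the experiment as
  a percentage of the mean baseline slope,
  `LTP% = 100 · ⟨slope⟩_last 5 min / ⟨slope⟩_baseline`;
* **epileptiform afterpotentials** — local minima after the fEPSP trough
  whose depth (topographic prominence) exceeds **2 × the peak-to-peak
  noise** of the ten designated sweeps of the phase (−5…−0.5 min before,
  0.5…5 min after induction); the deterministic detector replaces the
  blinded manual count and by construction sees only the trace and the
  noise estimate, never group labels;
* **short-term plasticity** — paired-pulse ratio (amplitude₂/amplitude₁
  after subtracting the extrapolated decay of the first response), 1 Hz
  frequency facilitation at the MF input, DCG-IV residual, and
  input-output curves with the 40–50%-of-maximum baseline-intensity
  convention;
* **cohort statistics** — two-sided Fisher exact (probability-mass
  rule), Yates-corrected χ², Mann-Whitney U, Wilcoxon signed-rank,
  Kruskal-Wallis, one-way ANOVA with Student-Newman-Keuls posthoc,
  two-way ANOVA, and Pearson correlation with its t-test.

No public raw recordings exist for this kind of study, so the package
ships a generator (`ca3ltp.synth`) producing sweep series with the same
statistical structure — dual-exponential fEPSPs behind a causal 1 kHz
acquisition filter, Gaussian noise, per-slice log-normal potentiation
factors, calibrated afterpotential trains, paired-pulse and 1 Hz
facilitation, D-AP5 and DCG-IV drug conditions — with ground-truth
labels for every injected event. Packaged reference configurations
(`ca3ltp.reference`) carry the reported subgroup effect sizes of the
modeled anti-NMDAR-encephalitis study design (control subgroups naive,
ACSF, C1–C3; NMDAR-CSF subgroups N1–N3; MF cohorts).

## Worked example

```python
import numpy as np
import ca3ltp as c

rng = np.random.default_rng(42)
ref = c.get_config("C1")                       # packaged control-CSF subgroup
rec, truth = c.synth_slice(ref.config, rng, slice_id="C1-demo")
out = c.analyze_slice(rec)
print(f"true potentiation factor : {truth.potentiation_factor:.3f}")
print(f"measured LTP magnitude   : {out.ltp_magnitude:.1f} % of baseline")
print(f"paired-pulse ratio       : {out.ppr:.2f}")

from ca3ltp.stats import fisher_exact_two_sided, round_p
p = fisher_exact_two_sided([[12, 34], [0, 25]]).p_value
print(f"Fisher exact, NMDAR-CSF before mdBS (D-AP5 effect): p = {round_p(p)}")
```

prints

```
true potentiation factor : 1.798
measured LTP magnitude   : 180.0 % of baseline
paired-pulse ratio       : 1.29
Fisher exact, NMDAR-CSF before mdBS (D-AP5 effect): p = 0.006
```

The slice drew a potentiation factor of 1.798 from the C1 distribution;
the pipeline recovers 180.0% — slope extraction and the LTP definition
agree with the injected truth to a fraction of a percent. The PPR of
1.29 sits inside the 1.2–1.6 acceptance band used to confirm A/C fiber
responses. The Fisher p of 0.006 is the D-AP5 effect on afterpotential
prevalence in NMDAR-CSF tissue before induction (12/46 present without
the blocker vs 0/25 with it).

## Command line

```bash
ca3ltp synth     --config cohort.yaml --seed 3 --out-dir cohort/ --format csv
ca3ltp analyze   --in-dir cohort/ --out report/ --threshold-multiplier 2.0
ca3ltp report    --config cohort.yaml --seed 3 --out report/
ca3ltp reproduce --seed 1 --out report/        # all packaged A/C subgroups
```

Cohorts are written as plain-text traces (two columns: time s, voltage
mV) with a JSON sidecar per slice and a CSV manifest, or as a single
HDF5 container; both layouts round-trip losslessly and yield identical
reports.

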