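"""Per-slice plasticity outcomes.

LTP magnitude is the mean fEPSP *slope* of the last 5 min of the
experiment as a percentage of the mean baseline slope; the paired-pulse
ratio uses *amplitudes* (second over first, after subtracting the
extrapolated decay of the first response) — the asymmetry is deliberate
and mirrors how these quantities are defined in slice electrophysiology.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .core import Sweep, SliceRecording
from .traces import AnalysisConfig, FepspFeatures, measure_fepsp, _per_sweep_noise

__all__ = [
    "PlasticityOutcome", "DrugResidual", "FacilitationResult", "IOCurve",
    "ltp_magnitude", "paired_pulse_ratio", "frequency_facilitation",
    "drug_residual", "io_curve", "peak_fold_change",
]


@dataclass
class PlasticityOutcome:
    """Derived metrics of one slice (fields are None when not applicable)."""

    slice_id: str
    group: str
    pathway: str
    drug: str
    ltp_magnitude: Optional[float] = None       # % of baseline
    ppr: Optional[float] = None
    freq_facilitation: Optional[float] = None   # %
    drug_residual: Optional[float] = None       # %
    ap_count_before: Optional[float] = None     # mean per designated sweep
    ap_count_after: Optional[float] = None
    ap_present_before: Optional[bool] = None
    ap_present_after: Optional[bool] = None
    peak_fold_change: Optional[float] = None


@dataclass(frozen=True)
class DrugResidual:
    percent: float
    below_noise_floor: bool


@dataclass(frozen=True)
class FacilitationResult:
    percent: float               # steady-state 1 Hz response, % of baseline
    fiber_volley_percent: float  # fiber-volley amplitude, % of baseline


@dataclass(frozen=True)
class IOCurve:
    intensities: tuple
    responses: tuple             # mean amplitude per intensity, mV
    half_max_intensity: float    # intensity yielding ~45% of the maximum
    half_max_fraction: float


def _slopes(sweeps: Sequence[Sweep], features: Sequence[FepspFeatures]) -> np.ndarray:
    vals = [f.slope for f in features if f.detected]
    if len(vals) < len(features):
        warnings.warn(f"{len(features) - len(vals)} sweeps without detectable fEPSP "
                      "excluded from slope average")
    return np.asarray(vals)


def ltp_magnitude(recording: SliceRecording,
                  features: Sequence[FepspFeatures],
                  last_min: float = 5.0,
                  settle_sweeps: int = 2) -> float:
    """LTP as mean slope of the last 5 min, % of the mean baseline slope.

    ``features`` must be parallel to ``recording.sweeps``.  The baseline
    is the full pre-induction phase except the first ``settle_sweeps``
    sweeps; sweeps acquired under an end-of-experiment drug (DCG-IV) are
    excluded from the final window.
    """
    if len(features) != len(recording.sweeps):
        raise ValueError("features must be parallel to recording.sweeps")
    singles = [(sw, f) for sw, f in zip(recording.sweeps, features)
               if sw.labels.get("protocol") == "single"
               and sw.labels.get("drug", "none") != "DCG-IV"]
    base = sorted([p for p in singles if p[0].sweep_time < 0], key=lambda p: p[0].sweep_time)
    post = sorted([p for p in singles if p[0].sweep_time > 0], key=lambda p: p[0].sweep_time)
    base = base[settle_sweeps:]
    if len(base) < 8 or len(post) < 10:
        raise ValueError("timeline too short: need >=10 baseline and >=10 post sweeps")
    t_end = post[-1][0].sweep_time
    last = [p for p in post if p[0].sweep_time > t_end - last_min]
    b = _slopes(*zip(*base))
    a = _slopes(*zip(*last))
    if b.size == 0 or a.size == 0:
        raise ValueError("no detectable responses in baseline or final window")
    b_mean = float(np.mean(b))
    if b_mean == 0:
        raise ZeroDivisionError("baseline slope mean is zero")
    return 100.0 * float(np.mean(a)) / b_mean


def _exp_extrapolation(sweep: Sweep, feats: FepspFeatures, cfg: AnalysisConfig,
                       i_fit0: int, i_fit1: int, i_out0: int, i_out1: int) -> np.ndarray:
    """Extrapolate the decay of response 1 over [i_out0, i_out1).

    Log-linear fit of (baseline - V) over the fit segment; returns the
    extrapolated *deviation from baseline* (negative values).
    """
    y = sweep.samples
    t = np.arange(y.size) * sweep.dt * 1e3
    dev = y[i_fit0:i_fit1] - feats.baseline_mv
    mask = dev < -1e-12
    if mask.sum() < 5:
        return np.zeros(i_out1 - i_out0)
    tt = t[i_fit0:i_fit1][mask]
    ll = np.log(-dev[mask])
    slope, intercept = np.polyfit(tt, ll, 1)
    return -np.exp(intercept + slope * t[i_out0:i_out1])


def paired_pulse_ratio(sweep: Sweep, cfg: AnalysisConfig = AnalysisConfig()) -> float:
    """Amplitude ratio of the second to the first evoked response.

    The second amplitude is measured after subtracting the extrapolated
    exponential decay of the first response.  Raises if the sweep does
    not contain exactly two stimuli or the second response is not
    detectable above noise.
    """
    if len(sweep.stimulus_times) != 2:
        raise ValueError("paired-pulse ratio requires exactly two stimuli")
    stim1, stim2 = sorted(sweep.stimulus_times)
    f1 = measure_fepsp(sweep, cfg, stimulus_index=0)
    if not f1.detected:
        raise ValueError("first response not detected")

    i_fit0 = sweep.index_at(stim1 + (f1.trough_time_ms + 2.0) * 1e-3)
    i_fit1 = sweep.index_at(stim2 - 0.3e-3)
    i_out0 = sweep.index_at(stim2)
    i_out1 = sweep.index_at(min(stim2 + cfg.trough_search_ms * 1e-3, sweep.duration_s))
    extrap = _exp_extrapolation(sweep, f1, cfg, i_fit0, i_fit1, i_out0, i_out1)

    corrected = sweep.samples[i_out0:i_out1] - extrap
    i_blank = sweep.index_at(stim2 + cfg.blank_ms * 1e-3) - i_out0
    seg = corrected[i_blank:]
    amp2 = f1.baseline_mv - float(np.min(seg))
    if amp2 <= cfg.min_amplitude_multiplier * _per_sweep_noise(sweep, cfg):
        raise ValueError("second response not detected above noise")
    return amp2 / f1.amplitude


def frequency_facilitation(recording: SliceRecording,
                           cfg: AnalysisConfig = AnalysisConfig(),
                           steady_pulses: tuple[int, int] = (6, 30)) -> FacilitationResult:
    """Steady-state 1 Hz response as % of the low-frequency baseline.

    The steady state is the mean amplitude over train pulses
    ``steady_pulses[0]..steady_pulses[1]``.  The presynaptic fiber-volley
    amplitude is reported alongside (it should stay constant — the
    facilitation is synaptic, not axonal).
    """
    base = recording.sweeps_where(protocol="ff_baseline")
    train = [sw for sw in recording.sweeps_where(protocol="ff_train")
             if steady_pulses[0] <= sw.labels.get("pulse_index", 0) <= steady_pulses[1]]
    if not base:
        raise ValueError("no 0.033 Hz baseline sweeps in recording")
    if not train:
        raise ValueError("no 1 Hz steady-state train sweeps in recording")

    def amp(sweeps):
        feats = [measure_fepsp(sw, cfg) for sw in sweeps]
        vals = [f.amplitude for f in feats if f.detected]
        if not vals:
            raise ValueError("no detectable responses")
        return float(np.mean(vals))

    def fv(sweeps):
        vals = []
        for sw in sweeps:
            stim = min(sw.stimulus_times)
            i0 = sw.index_at(stim + cfg.fv_window_ms[0] * 1e-3)
            i1 = sw.index_at(stim + cfg.fv_window_ms[1] * 1e-3)
            i_b0 = sw.index_at(max(0.0, stim - cfg.baseline_ms * 1e-3))
            baseline = float(np.mean(sw.samples[i_b0:sw.index_at(stim)]))
            vals.append(baseline - float(np.min(sw.samples[i0:max(i1, i0 + 1)])))
        return float(np.mean(vals))

    base_amp = amp(base)
    fv_base = fv(base)
    fv_pct = 100.0 * fv(train) / fv_base if fv_base > 0 else float("nan")
    return FacilitationResult(percent=100.0 * amp(train) / base_amp,
                              fiber_volley_percent=fv_pct)


def drug_residual(recording: SliceRecording,
                  cfg: AnalysisConfig = AnalysisConfig(),
                  plateau_sweeps: int = 10,
                  drug_label: str = "DCG-IV") -> DrugResidual:
    """Residual response after end-of-experiment drug, % of the pre-drug plateau."""
    pre = [sw for sw in recording.sweeps_where(protocol="single")
           if sw.labels.get("drug", "none") != drug_label]
    post = [sw for sw in recording.sweeps if sw.labels.get("drug") == drug_label]
    if not post:
        raise ValueError(f"no {drug_label} sweeps in recording")
    if not pre:
        raise ValueError("no pre-drug sweeps in recording")
    pre = sorted(pre, key=lambda sw: sw.sweep_time)[-plateau_sweeps:]
    post = sorted(post, key=lambda sw: sw.sweep_time)[-plateau_sweeps:]

    def raw_amp(sw: Sweep) -> float:
        stim = min(sw.stimulus_times)
        i_b0 = sw.index_at(max(0.0, stim - cfg.baseline_ms * 1e-3))
        baseline = float(np.mean(sw.samples[i_b0:sw.index_at(stim)]))
        i0 = sw.index_at(stim + cfg.blank_ms * 1e-3)
        i1 = sw.index_at(stim + cfg.trough_search_ms * 1e-3)
        return baseline - float(np.min(sw.samples[i0:i1]))

    pre_amp = float(np.mean([raw_amp(sw) for sw in pre]))
    post_amp = float(np.mean([raw_amp(sw) for sw in post]))
    if pre_amp <= 0:
        raise ValueError("pre-drug plateau has no measurable response")
    noise = float(np.mean([_per_sweep_noise(sw, cfg) for sw in post]))
    return DrugResidual(percent=100.0 * post_amp / pre_amp,
                        below_noise_floor=post_amp < cfg.min_amplitude_multiplier * noise)


def io_curve(series: Sequence[tuple[float, Sequence[Sweep]]],
             cfg: AnalysisConfig = AnalysisConfig(),
             target_fraction: float = 0.45) -> IOCurve:
    """Input-output curve over graded stimulation intensities.

    Returns mean amplitudes ordered by intensity and the (interpolated)
    intensity producing ``target_fraction`` of the maximal response —
    the baseline-intensity convention of stimulating at 40-50% of the
    maximal fEPSP.  A flat curve is rejected.
    """
    if len(series) < 3:
        raise ValueError("an I/O curve needs at least 3 intensities")
    pts = []
    for inten, sweeps in series:
        feats = [measure_fepsp(sw, cfg) for sw in sweeps]
        amps = [f.amplitude for f in feats if f.detected]
        pts.append((float(inten), float(np.mean(amps)) if amps else 0.0))
    pts.sort(key=lambda p: p[0])
    intensities = tuple(p[0] for p in pts)
    responses = tuple(p[1] for p in pts)
    r_max = max(responses)
    if r_max <= 0 or (r_max - min(responses)) < 0.05 * r_max:
        raise ValueError("flat I/O curve: cannot select a half-maximal intensity")
    target = target_fraction * r_max
    x = None
    for (i0, r0), (i1, r1) in zip(pts[:-1], pts[1:]):
        if (r0 - target) * (r1 - target) <= 0 and r1 != r0:
            x = i0 + (target - r0) * (i1 - i0) / (r1 - r0)
            break
    if x is None:
        x = intensities[int(np.argmin(np.abs(np.array(responses) - target)))]
    return IOCurve(intensities, responses, float(x), target_fraction)


def peak_fold_change(before_ap_counts: Sequence[int],
                     after_ap_counts: Sequence[int]) -> float:
    """Fold change of the number of fEPSP peaks (afterpotentials + 1).

    Mean peak count over the designated post-induction sweeps divided by
    the mean over the designated baseline sweeps.  The before mean can
    never be zero: a detected fEPSP always counts as one peak.
    """
    before = np.asarray(list(before_ap_counts), dtype=float) + 1.0
    after = np.asarray(list(after_ap_counts), dtype=float) + 1.0
    if before.size == 0 or after.size == 0:
        raise ValueError("both phases need counted sweeps")
    return float(np.mean(after) / np.mean(before))
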