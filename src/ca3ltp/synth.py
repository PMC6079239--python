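"""Synthetic extracellular sweep generator.

Emulates the statistical structure of evoked CA3 field-potential
recordings so that every analysis stage can be exercised against known
ground truth:

* negative-going dual-exponential fEPSP with optional fiber volley and
  stimulus artifact, digitized through a 1 kHz low-pass acquisition
  filter with additive white Gaussian noise,
* paired-pulse sweeps whose second response realizes a configured ratio,
* per-slice long-term potentiation: post-induction responses scale by a
  slice-specific factor drawn log-normally from the configured
  mean/SD (positivity and the right skew of slice LTP distributions),
* epileptiform afterpotential trains injected as calibrated deflections
  whose *realized prominence* equals ``depth_multiplier`` x the
  peak-to-peak noise reference, so detector recall/false-positive
  behavior can be verified exactly,
* 1 Hz frequency-facilitation trains and DCG-IV suppression for
  mossy-fiber recordings.

Every generated object is exactly reproducible from its configuration
and seed; per-slice child seeds derive deterministically from the cohort
master seed so cohorts are reproducible under reordering.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from functools import lru_cache
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.signal import butter, lfilter

from .core import AcquisitionParams, Sweep, SliceRecording, PHASE_BEFORE, PHASE_AFTER
from .traces import AnalysisConfig, event_prominences

__all__ = [
    "WaveformParams", "CountDistribution", "AfterpotentialSpec",
    "LogNormalSpec", "SliceSimConfig", "CohortConfig", "CohortMember",
    "SweepTruth", "SliceGroundTruth", "CohortResult",
    "make_fepsp_waveform", "synth_sweep", "synth_slice", "synth_cohort",
    "synth_paired_pulse_sweeps", "synth_frequency_facilitation",
    "synth_io_series", "apply_d_ap5", "expected_noise_p2p",
    "fepsp_peak_time_ms", "acquisition_filter",
]

DEFAULT_ACQ = AcquisitionParams()


# ---------------------------------------------------------------------------
# parameter containers


@dataclass(frozen=True)
class WaveformParams:
    """Shape of a single evoked response.

    Amplitudes are positive scalars in mV (the fEPSP deflection itself is
    negative-going). Kinetic constants are phenomenological choices that
    reproduce the morphology of typical interface-chamber CA3 field
    potentials; absolute amplitudes and noise levels are placeholders —
    real recordings do not constrain them — and are fully configurable.
    """

    fepsp_amplitude: float = 1.0      # mV
    rise_tau: float = 1.0             # ms
    decay_tau: float = 8.0            # ms
    fepsp_onset_delay: float = 2.0    # ms after stimulus
    fiber_volley_amplitude: float = 0.0  # mV; 0 disables
    fiber_volley_sigma: float = 0.35  # ms (Gaussian width)
    artifact_amplitude: float = 0.4   # mV; 0 disables
    noise_sigma: float = 0.02         # mV (white, before the 1 kHz filter)

    def __post_init__(self) -> None:
        if not self.rise_tau < self.decay_tau:
            raise ValueError("rise_tau must be smaller than decay_tau")
        if self.fepsp_onset_delay <= 0:
            raise ValueError("fepsp_onset_delay must be positive")
        for name in ("fepsp_amplitude", "fiber_volley_amplitude",
                     "artifact_amplitude", "noise_sigma"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass(frozen=True)
class CountDistribution:
    """Discrete distribution over non-negative integer event counts."""

    kind: str = "fixed"   # "fixed" or "poisson"
    value: float = 0.0    # fixed count, or Poisson mean

    def __post_init__(self) -> None:
        if self.kind not in ("fixed", "poisson"):
            raise ValueError(f"unknown count distribution kind {self.kind!r}")
        if self.value < 0:
            raise ValueError("count distribution parameter must be >= 0")

    def sample(self, rng: np.random.Generator) -> int:
        if self.kind == "fixed":
            return int(round(self.value))
        return int(rng.poisson(self.value))

    @property
    def mean(self) -> float:
        return float(self.value)


ZERO_COUNTS = CountDistribution("fixed", 0)


@dataclass(frozen=True)
class AfterpotentialSpec:
    """Afterpotential process of one phase.

    ``presence_prob`` is the slice-level probability that the process is
    expressed at all in this phase; when expressed, per-sweep event
    counts follow ``count_distribution``.  Event depth is expressed as a
    multiple of the peak-to-peak noise reference; event latency is drawn
    within ``latency_range`` (ms after the fEPSP trough) on a jittered
    grid that keeps neighboring events separable.
    """

    count_distribution: CountDistribution = ZERO_COUNTS
    presence_prob: float = 1.0
    depth_multiplier: float = 4.0
    latency_range: tuple[float, float] = (8.0, 95.0)
    width: float = 3.0                # ms
    min_separation: float = 7.0       # ms between event centers
    jitter_ms: float = 2.0

    def __post_init__(self) -> None:
        if self.depth_multiplier <= 0:
            raise ValueError("depth_multiplier must be positive")
        if not 0 <= self.presence_prob <= 1:
            raise ValueError("presence_prob must be in [0, 1]")
        if self.latency_range[0] >= self.latency_range[1]:
            raise ValueError("latency_range must be increasing")

    @property
    def n_slots(self) -> int:
        span = self.latency_range[1] - self.latency_range[0] - self.width
        return max(1, int(span // self.min_separation) + 1)

    def is_null(self) -> bool:
        return self.presence_prob == 0 or (self.count_distribution.kind == "fixed"
                                           and self.count_distribution.value == 0)


@dataclass(frozen=True)
class LogNormalSpec:
    """Positive quantity with slice-to-slice variability (log-normal)."""

    mean: float
    sd: float = 0.0

    def __post_init__(self) -> None:
        if self.mean <= 0:
            raise ValueError("mean must be positive")
        if self.sd < 0:
            raise ValueError("sd must be non-negative")

    @classmethod
    def from_sem(cls, mean: float, sem: float, n: int) -> "LogNormalSpec":
        """Back-compute the slice-level SD from a printed mean +/- SEM, n."""
        return cls(mean, sem * math.sqrt(n))

    def sample(self, rng: np.random.Generator) -> float:
        if self.sd == 0:
            return self.mean
        sigma2 = math.log(1.0 + (self.sd / self.mean) ** 2)
        mu = math.log(self.mean) - 0.5 * sigma2
        return float(rng.lognormal(mu, math.sqrt(sigma2)))


@dataclass(frozen=True)
class SliceSimConfig:
    """Everything needed to simulate one slice experiment."""

    pathway: str = "A/C"             # "A/C" or "MF"
    group: str = "naive"
    drug: str = "none"               # bath condition: "none" or "D-AP5"
    ppr_target: LogNormalSpec = LogNormalSpec(1.4, 0.15)
    potentiation_factor: LogNormalSpec = LogNormalSpec(1.6, 0.3)
    freq_facilitation_target: Optional[LogNormalSpec] = None   # MF only
    dcg_iv_suppression: Optional[LogNormalSpec] = None         # MF only
    afterpotentials_before: AfterpotentialSpec = AfterpotentialSpec()
    afterpotentials_after: AfterpotentialSpec = AfterpotentialSpec()
    waveform: WaveformParams = WaveformParams()
    ap_ltp_coupling: float = 0.0     # exponent coupling afterpotentials to LTP
    pp_interval_ms: float = 40.0     # paired-pulse interstimulus interval

    def __post_init__(self) -> None:
        if self.pathway not in ("A/C", "MF"):
            raise ValueError(f"unknown pathway {self.pathway!r}")
        if self.drug not in ("none", "D-AP5"):
            raise ValueError(f"unknown bath drug {self.drug!r}")
        if self.pathway == "A/C":
            if self.freq_facilitation_target is not None or self.dcg_iv_suppression is not None:
                raise ValueError("frequency facilitation and DCG-IV are MF-only fields")
        if self.ppr_target.mean <= 0 or self.potentiation_factor.mean <= 0:
            raise ValueError("targets must be positive")


@dataclass(frozen=True)
class CohortMember:
    name: str
    config: SliceSimConfig
    n_slices: int

    def __post_init__(self) -> None:
        if self.n_slices < 1:
            raise ValueError("n_slices must be >= 1")


@dataclass(frozen=True)
class CohortConfig:
    members: tuple
    master_seed: int
    sweep_interval_s: float = 30.0
    baseline_duration_min: float = 10.0
    post_duration_min: float = 20.0

    def __post_init__(self) -> None:
        if self.sweep_interval_s <= 0:
            raise ValueError("sweep_interval must be positive")
        names = [m.name for m in self.members]
        if len(names) != len(set(names)):
            raise ValueError("duplicate cohort member identifiers")


# ---------------------------------------------------------------------------
# ground truth


@dataclass
class SweepTruth:
    sweep_index: int
    scale: float
    ap_times_ms: tuple = ()
    ap_depths_mv: tuple = ()
    ppr: Optional[float] = None


@dataclass
class SliceGroundTruth:
    slice_id: str
    potentiation_factor: float = 1.0
    ppr_values: tuple = ()
    facilitation: Optional[float] = None
    suppression: Optional[float] = None
    sweep_truths: list = field(default_factory=list)


@dataclass
class CohortResult:
    recordings: list
    truths: list
    manifest: pd.DataFrame
    config: CohortConfig


# ---------------------------------------------------------------------------
# waveform assembly


def fepsp_peak_time_ms(rise_tau: float, decay_tau: float) -> float:
    """Time of the dual-exponential peak after onset (closed form)."""
    return math.log(decay_tau / rise_tau) * rise_tau * decay_tau / (decay_tau - rise_tau)


def _dual_exp(t_ms: np.ndarray, rise: float, decay: float) -> np.ndarray:
    g = np.where(t_ms >= 0, np.exp(-np.maximum(t_ms, 0) / decay)
                 - np.exp(-np.maximum(t_ms, 0) / rise), 0.0)
    tp = fepsp_peak_time_ms(rise, decay)
    gmax = math.exp(-tp / decay) - math.exp(-tp / rise)
    return g / gmax


@lru_cache(maxsize=8)
def _filter_coeffs(filter_hz: float, sample_rate_hz: float):
    return butter(4, filter_hz, fs=sample_rate_hz)


def acquisition_filter(samples: np.ndarray, acq: AcquisitionParams) -> np.ndarray:
    """Causal 1 kHz low-pass emulating the analog acquisition chain.

    Causality matters: a zero-phase filter would smear the stimulus
    artifact backwards into the pre-stimulus noise window and corrupt
    the peak-to-peak noise estimate the detection threshold rests on.
    """
    if acq.filter_hz is None:
        return np.asarray(samples, dtype=float)
    b, a = _filter_coeffs(acq.filter_hz, acq.sample_rate_hz)
    return lfilter(b, a, samples)


def _raised_cosine_dip(t_ms: np.ndarray, center_ms: float, depth: float,
                       width_ms: float) -> np.ndarray:
    u = (t_ms - center_ms) / width_ms
    out = np.zeros_like(t_ms)
    m = np.abs(u) <= 0.5
    out[m] = -0.5 * depth * (1.0 + np.cos(2 * np.pi * u[m]))
    return out


def _response(t_ms: np.ndarray, params: WaveformParams, stim_ms: float,
              amp: float) -> np.ndarray:
    """One stimulus artifact + fiber volley + fEPSP (noise-free)."""
    y = np.zeros_like(t_ms)
    if params.artifact_amplitude > 0:
        # brief biphasic artifact, fully inside the blanking interval
        y += params.artifact_amplitude * (
            np.exp(-0.5 * ((t_ms - stim_ms - 0.15) / 0.08) ** 2)
            - 0.7 * np.exp(-0.5 * ((t_ms - stim_ms - 0.45) / 0.12) ** 2))
    if params.fiber_volley_amplitude > 0:
        fv_center = stim_ms + max(0.3, params.fepsp_onset_delay - 1.2)
        y -= params.fiber_volley_amplitude * np.exp(
            -0.5 * ((t_ms - fv_center) / params.fiber_volley_sigma) ** 2)
    onset = stim_ms + params.fepsp_onset_delay
    y -= amp * _dual_exp(t_ms - onset, params.rise_tau, params.decay_tau)
    return y


def make_fepsp_waveform(params: WaveformParams, potentiation_scale: float = 1.0,
                        afterpotential_events: Sequence[tuple[float, float]] = (),
                        acq: AcquisitionParams = DEFAULT_ACQ,
                        amp_scales: Optional[Sequence[float]] = None,
                        stim_times_ms: Optional[Sequence[float]] = None,
                        filtered: bool = False) -> np.ndarray:
    """Noise-free voltage trace of one sweep.

    ``afterpotential_events`` is a sequence of (time ms post first
    stimulus, depth mV) raised-cosine deflections.  ``amp_scales`` gives
    the per-stimulus response scaling for multi-stimulus (paired-pulse)
    sweeps; by default a single stimulus scaled by
    ``potentiation_scale``. The trace is exactly reproducible from its
    inputs.
    """
    if potentiation_scale <= 0:
        raise ValueError("potentiation_scale must be positive")
    t_ms = acq.time_ms()
    stims = list(stim_times_ms) if stim_times_ms is not None else [acq.stim_ms]
    scales = list(amp_scales) if amp_scales is not None else [potentiation_scale]
    if len(scales) != len(stims):
        raise ValueError("one amplitude scale per stimulus required")
    y = np.zeros_like(t_ms)
    for stim, sc in zip(stims, scales):
        if sc <= 0:
            raise ValueError("response scales must be positive")
        y += _response(t_ms, params, stim, sc * params.fepsp_amplitude)
    for ev_t, depth in afterpotential_events:
        y += _raised_cosine_dip(t_ms, stims[0] + ev_t, depth, 3.0)
    return acquisition_filter(y, acq) if filtered else y


@lru_cache(maxsize=32)
def _unit_noise_p2p(acq: AcquisitionParams, window_ms: float) -> float:
    """E[max-min] over a window of unit-variance filtered noise (fixed MC)."""
    rng = np.random.default_rng(987654321)
    n_win = int(round(window_ms * 1e-3 * acq.sample_rate_hz))
    vals = []
    for _ in range(200):
        x = acquisition_filter(rng.standard_normal(acq.n_samples), acq)
        seg = x[:n_win]
        vals.append(seg.max() - seg.min())
    return float(np.mean(vals))


def expected_noise_p2p(noise_sigma: float, acq: AcquisitionParams = DEFAULT_ACQ,
                       window_ms: float = 50.0) -> float:
    """Expected peak-to-peak excursion of the filtered noise in a window."""
    if noise_sigma == 0:
        return 0.0
    return noise_sigma * _unit_noise_p2p(acq, window_ms)


# ---------------------------------------------------------------------------
# afterpotential injection with prominence calibration


def _place_events(spec: AfterpotentialSpec, count: int, trough_ms: float,
                  rng: np.random.Generator) -> list[float]:
    """Event times (ms post-stimulus) on a jittered grid after the trough."""
    count = min(count, spec.n_slots)
    if count == 0:
        return []
    slots = rng.choice(spec.n_slots, size=count, replace=False)
    jitter = rng.uniform(0.0, spec.jitter_ms, size=count)
    lat0 = spec.latency_range[0]
    times = trough_ms + lat0 + slots * spec.min_separation + jitter
    return sorted(float(t) for t in times)


def _calibrated_events(base_wave: np.ndarray, times_ms: Sequence[float],
                       target_depths: Sequence[float], stim_ms: float,
                       acq: AcquisitionParams, width_ms: float = 3.0,
                       cfg: AnalysisConfig = AnalysisConfig()) -> list[tuple[float, float]]:
    """Inject dips so their realized (filtered) prominence hits the target.

    Returns (time ms post-stimulus, injected depth) pairs; the injected
    depth is iteratively rescaled so the topographic prominence measured
    on the filtered, noise-free trace equals the target depth.
    """
    if not times_ms:
        return []
    t_ms_axis = np.arange(base_wave.size) / acq.sample_rate_hz * 1e3
    depths = np.asarray(target_depths, dtype=float).copy()
    wlen = max(3, int(round(cfg.prominence_wlen_ms * 1e-3 * acq.sample_rate_hz)) | 1)
    half_w = (width_ms / 2 + 0.1) * 1e-3 * acq.sample_rate_hz  # half dip footprint, samples
    for _ in range(3):
        y = base_wave.copy()
        for t, d in zip(times_ms, depths):
            y += _raised_cosine_dip(t_ms_axis, stim_ms + t, d, width_ms)
        yf = acquisition_filter(y, acq)
        idx = []
        for t in times_ms:
            c = int(round((stim_ms + t) * 1e-3 * acq.sample_rate_hz))
            lo, hi = int(c - half_w), int(c + half_w) + 1
            idx.append(lo + int(np.argmin(yf[lo:hi])))
        with np.errstate(all="ignore"):
            import warnings as _w
            with _w.catch_warnings():
                _w.simplefilter("ignore")
                prom = event_prominences(yf, idx, wlen)
        # aim 3% above the nominal depth so the realized prominence never
        # undershoots the ground-truth depth contract
        aim = 1.03 * np.asarray(target_depths)
        ratio = np.where(prom > 0, aim / np.maximum(prom, 1e-12), 1.0)
        depths *= np.clip(ratio, 0.25, 4.0)
    return list(zip([float(t) for t in times_ms], [float(d) for d in depths]))


# ---------------------------------------------------------------------------
# sweep / slice / cohort synthesis


def _build_sweep(config: SliceSimConfig, acq: AcquisitionParams, sweep_time: float,
                 scale: float, events: Sequence[tuple[float, float]],
                 noise: np.ndarray, labels: dict,
                 ppr: Optional[float] = None, event_width_ms: float = 3.0) -> Sweep:
    params = config.waveform
    if ppr is None:
        stims_ms = [acq.stim_ms]
        scales = [scale]
    else:
        stims_ms = [acq.stim_ms, acq.stim_ms + config.pp_interval_ms]
        scales = [scale, scale * ppr]
    t_ms = acq.time_ms()
    y = np.zeros_like(t_ms)
    for stim, sc in zip(stims_ms, scales):
        y += _response(t_ms, params, stim, sc * params.fepsp_amplitude)
    if events:
        cal = _calibrated_events(y, [t for t, _ in events], [d for _, d in events],
                                 acq.stim_ms, acq, width_ms=event_width_ms)
        for t, d in cal:
            y += _raised_cosine_dip(t_ms, acq.stim_ms + t, d, event_width_ms)
    yf = acquisition_filter(y, acq) + noise
    return Sweep(samples=yf, dt=acq.dt,
                 stimulus_times=tuple(s * 1e-3 for s in stims_ms),
                 sweep_time=sweep_time, labels=labels)


def _filtered_noise(params: WaveformParams, acq: AcquisitionParams,
                    rng: np.random.Generator) -> np.ndarray:
    if params.noise_sigma == 0:
        return np.zeros(acq.n_samples)
    return acquisition_filter(rng.normal(0.0, params.noise_sigma, acq.n_samples), acq)


def synth_sweep(config: SliceSimConfig, phase: str, rng: np.random.Generator,
                acq: AcquisitionParams = DEFAULT_ACQ, scale: float = 1.0,
                noise_ref: Optional[float] = None,
                paired_pulse: bool = False) -> tuple[Sweep, SweepTruth]:
    """One standalone sweep of the given phase ('before' or 'after').

    ``noise_ref`` is the peak-to-peak noise reference the afterpotential
    depths are expressed against; by default the expected post-filter
    value for the configured noise sigma.  Slice-level presence is not
    sampled here — the drawn count reflects an afterpotential-expressing
    slice (see :func:`synth_slice` for presence handling).
    """
    if phase not in ("before", "after"):
        raise ValueError("phase must be 'before' or 'after'")
    spec = (config.afterpotentials_before if phase == "before"
            else config.afterpotentials_after)
    params = config.waveform
    ref = expected_noise_p2p(params.noise_sigma, acq) if noise_ref is None else noise_ref

    ppr = config.ppr_target.sample(rng) if paired_pulse else None
    count = 0 if spec.is_null() else spec.count_distribution.sample(rng)
    trough_ms = params.fepsp_onset_delay + fepsp_peak_time_ms(params.rise_tau,
                                                              params.decay_tau)
    times = _place_events(spec, count, trough_ms, rng) if ref > 0 else []
    events = [(t, spec.depth_multiplier * ref) for t in times]
    noise = _filtered_noise(params, acq, rng)
    labels = {"phase": phase, "protocol": "paired_pulse" if paired_pulse else "single",
              "drug": config.drug, "group": config.group}
    sw = _build_sweep(config, acq, -1.0 if phase == "before" else 1.0,
                      scale, events, noise, labels, ppr=ppr,
                      event_width_ms=spec.width)
    truth = SweepTruth(sweep_index=0, scale=scale,
                       ap_times_ms=tuple(t for t, _ in events),
                       ap_depths_mv=tuple(d for _, d in events), ppr=ppr)
    return sw, truth


def synth_paired_pulse_sweeps(config: SliceSimConfig, n: int,
                              rng: np.random.Generator,
                              acq: AcquisitionParams = DEFAULT_ACQ) -> list[tuple[Sweep, SweepTruth]]:
    """``n`` independent paired-pulse sweeps at baseline intensity."""
    return [synth_sweep(config, "before", rng, acq, paired_pulse=True)
            for _ in range(n)]


def _conditional_presence(p_before: float, p_after: float,
                          rng: np.random.Generator) -> tuple[bool, bool]:
    """Slice-level presence flags, monotone (after implies at least before's rate)."""
    before = rng.random() < p_before
    if p_after <= p_before:
        after = before if p_before == 0 else (rng.random() < p_after / max(p_before, 1e-12)
                                              if before else False)
        # keep the marginal ~p_after while preferring before-expressing slices
        return before, after
    p_extra = (p_after - p_before) / (1.0 - p_before) if p_before < 1 else 0.0
    after = before or (rng.random() < p_extra)
    return before, after


def synth_slice(config: SliceSimConfig, rng: np.random.Generator,
                acq: AcquisitionParams = DEFAULT_ACQ,
                sweep_interval_s: float = 30.0,
                baseline_duration_min: float = 10.0,
                post_duration_min: float = 20.0,
                slice_id: str = "slice",
                n_paired_pulse: int = 3,
                noise_ref: Optional[float] = None) -> tuple[SliceRecording, SliceGroundTruth]:
    """One full LTP experiment timeline for a slice.

    Baseline sweeps run up to the induction event at t = 0, post sweeps
    follow every ``sweep_interval_s``; post-induction fEPSP responses
    scale by a slice-specific potentiation factor drawn once from the
    config.  A few paired-pulse sweeps precede the baseline.  When the
    config carries a DCG-IV suppression (MF pathway), ten drug sweeps
    are appended at the end.
    """
    interval_min = sweep_interval_s / 60.0
    if baseline_duration_min < 5.0 or post_duration_min < 5.0:
        raise ValueError("timeline too short for the -5..-0.5 min and last-5-min windows")
    t_baseline = np.arange(-baseline_duration_min, -1e-9, interval_min)
    t_post = np.arange(interval_min, post_duration_min + 1e-9, interval_min)
    if t_baseline.size < 10 or t_post.size < 10:
        raise ValueError("need at least 10 baseline and 10 post sweeps")

    params = config.waveform
    factor = config.potentiation_factor.sample(rng)
    suppression = (config.dcg_iv_suppression.sample(rng)
                   if config.dcg_iv_suppression is not None else None)

    spec_b, spec_a = config.afterpotentials_before, config.afterpotentials_after
    p_b = 0.0 if spec_b.is_null() else spec_b.presence_prob
    p_a = 0.0 if spec_a.is_null() else spec_a.presence_prob
    lam_scale = 1.0
    if config.ap_ltp_coupling > 0:
        m = (factor / config.potentiation_factor.mean) ** config.ap_ltp_coupling
        m = float(np.clip(m, 0.2, 3.0))
        p_a = min(0.98, p_a * m)
        lam_scale = m
    present_b, present_a = _conditional_presence(p_b, p_a, rng)

    pprs = [config.ppr_target.sample(rng) for _ in range(n_paired_pulse)]

    # counts drawn up front (fixed order) so the rest of the stream is stable
    def draw_counts(times: np.ndarray, spec: AfterpotentialSpec, present: bool,
                    scale_lam: float) -> list[int]:
        if not present or spec.is_null():
            return [0] * times.size
        dist = spec.count_distribution
        if dist.kind == "poisson" and scale_lam != 1.0:
            dist = CountDistribution("poisson", dist.value * scale_lam)
        return [dist.sample(rng) for _ in times]

    counts_b = draw_counts(t_baseline, spec_b, present_b, 1.0)
    counts_a = draw_counts(t_post, spec_a, present_a, lam_scale)

    # guarantee that a present phase shows >=1 event in its designated window
    def fix_window(times: np.ndarray, counts: list[int], window, present: bool) -> None:
        idx = [i for i, t in enumerate(times) if window[0] - 1e-9 <= t <= window[1] + 1e-9]
        if present and idx and all(counts[i] == 0 for i in idx):
            counts[idx[0]] = 1
    fix_window(t_baseline, counts_b, PHASE_BEFORE, present_b)
    fix_window(t_post, counts_a, PHASE_AFTER, present_a)

    trough_ms = params.fepsp_onset_delay + fepsp_peak_time_ms(params.rise_tau,
                                                              params.decay_tau)
    ev_times_b = [_place_events(spec_b, c, trough_ms, rng) for c in counts_b]
    ev_times_a = [_place_events(spec_a, c, trough_ms, rng) for c in counts_a]

    n_drug = 10 if suppression is not None else 0
    n_total = n_paired_pulse + t_baseline.size + t_post.size + n_drug
    noises = [_filtered_noise(params, acq, rng) for _ in range(n_total)]

    # realized noise reference from the designated before-window sweeps
    if noise_ref is not None:
        ref_b = ref_a = noise_ref
    elif params.noise_sigma == 0:
        ref_b = ref_a = 0.0
    else:
        n_win = int(round(50e-3 * acq.sample_rate_hz))
        i_stim = int(round(acq.stim_time_s * acq.sample_rate_hz))
        off = n_paired_pulse

        def realized(times: np.ndarray, window, base_off: int) -> float:
            vals = [noises[base_off + i][max(0, i_stim - n_win):i_stim]
                    for i, t in enumerate(times)
                    if window[0] - 1e-9 <= t <= window[1] + 1e-9]
            return float(np.mean([v.max() - v.min() for v in vals]))
        ref_b = realized(t_baseline, PHASE_BEFORE, off)
        ref_a = realized(t_post, PHASE_AFTER, off + t_baseline.size)

    rec = SliceRecording(slice_id=slice_id, pathway=config.pathway,
                         group=config.group, drug=config.drug,
                         induction="mdBS" if config.pathway == "A/C" else "tetanus",
                         metadata={"sweep_interval_s": sweep_interval_s})
    truth = SliceGroundTruth(slice_id=slice_id, potentiation_factor=factor,
                             ppr_values=tuple(pprs), suppression=suppression)

    k = 0
    pp_t0 = -baseline_duration_min - n_paired_pulse * interval_min
    for j, ppr in enumerate(pprs):
        labels = {"protocol": "paired_pulse", "drug": config.drug, "group": config.group}
        sw = _build_sweep(config, acq, pp_t0 + j * interval_min, 1.0, [],
                          noises[k], labels, ppr=ppr)
        rec.sweeps.append(sw)
        truth.sweep_truths.append(SweepTruth(k, 1.0, ppr=ppr))
        k += 1

    def add_single(t: float, scale: float, times_ms: list[float], ref: float,
                   drug_label: str) -> None:
        nonlocal k
        spec = spec_b if t < 0 else spec_a
        events = ([(tt, spec.depth_multiplier * ref) for tt in times_ms]
                  if ref > 0 else [])
        labels = {"protocol": "single", "drug": drug_label, "group": config.group,
                  "phase": "before" if t < 0 else "after"}
        sw = _build_sweep(config, acq, t, scale, events, noises[k], labels,
                          event_width_ms=spec.width)
        rec.sweeps.append(sw)
        truth.sweep_truths.append(SweepTruth(k, scale,
                                             ap_times_ms=tuple(tt for tt, _ in events),
                                             ap_depths_mv=tuple(d for _, d in events)))
        k += 1

    for t, times_ms in zip(t_baseline, ev_times_b):
        add_single(float(t), 1.0, times_ms, ref_b, config.drug)
    for t, times_ms in zip(t_post, ev_times_a):
        add_single(float(t), factor, times_ms, ref_a, config.drug)
    for j in range(n_drug):
        t = float(t_post[-1] + (j + 1) * interval_min)
        labels = {"protocol": "single", "drug": "DCG-IV", "group": config.group,
                  "phase": "drug"}
        sw = _build_sweep(config, acq, t, factor * suppression, [], noises[k], labels)
        rec.sweeps.append(sw)
        truth.sweep_truths.append(SweepTruth(k, factor * suppression))
        k += 1
    return rec, truth


def synth_frequency_facilitation(config: SliceSimConfig, rng: np.random.Generator,
                                 acq: AcquisitionParams = DEFAULT_ACQ,
                                 n_baseline: int = 10, n_pulses: int = 30,
                                 slice_id: str = "slice") -> tuple[SliceRecording, SliceGroundTruth]:
    """A 1 Hz frequency-facilitation experiment (MF pathway).

    Baseline responses at 0.033 Hz are followed by an ``n_pulses``-pulse
    1 Hz train whose response amplitude ramps to the slice's facilitation
    factor within five pulses and stays there; the fiber volley stays
    constant throughout.
    """
    if config.freq_facilitation_target is None:
        raise ValueError("config has no frequency-facilitation target (MF only)")
    fac = config.freq_facilitation_target.sample(rng)
    params = config.waveform
    rec = SliceRecording(slice_id=slice_id, pathway=config.pathway,
                         group=config.group, drug=config.drug, induction=None)
    truth = SliceGroundTruth(slice_id=slice_id, facilitation=fac)
    k = 0
    for j in range(n_baseline):
        labels = {"protocol": "ff_baseline", "drug": config.drug, "group": config.group}
        sw = _build_sweep(config, acq, -(n_baseline - j) * 0.5, 1.0, [],
                          _filtered_noise(params, acq, rng), labels)
        rec.sweeps.append(sw)
        truth.sweep_truths.append(SweepTruth(k, 1.0)); k += 1
    for p in range(1, n_pulses + 1):
        scale = 1.0 + (fac - 1.0) * min(1.0, (p - 1) / 5.0)
        labels = {"protocol": "ff_train", "drug": config.drug,
                  "group": config.group, "pulse_index": p}
        sw = _build_sweep(config, acq, p / 60.0, scale, [],
                          _filtered_noise(params, acq, rng), labels)
        rec.sweeps.append(sw)
        truth.sweep_truths.append(SweepTruth(k, scale)); k += 1
    return rec, truth


def synth_io_series(config: SliceSimConfig, intensities: Sequence[float],
                    rng: np.random.Generator, acq: AcquisitionParams = DEFAULT_ACQ,
                    n_per_intensity: int = 3,
                    i_half: float = 1.0, hill: float = 2.0) -> list[tuple[float, list[Sweep]]]:
    """Sweeps at graded stimulation intensities.

    The response follows a saturating Hill curve; the configured waveform
    amplitude corresponds to ~45% of the maximum (the baseline-intensity
    convention of adjusting to 40-50% of the maximal fEPSP).
    """
    params = config.waveform
    r_max = 1.0 / 0.45
    out = []
    for inten in intensities:
        frac = r_max * inten ** hill / (inten ** hill + i_half ** hill)
        sweeps = []
        for _ in range(n_per_intensity):
            labels = {"protocol": "io", "drug": config.drug, "group": config.group,
                      "intensity": float(inten)}
            sweeps.append(_build_sweep(config, acq, 0.0, max(frac, 1e-6), [],
                                       _filtered_noise(params, acq, rng), labels))
        out.append((float(inten), sweeps))
    return out


def synth_cohort(cohort: CohortConfig, acq: AcquisitionParams = DEFAULT_ACQ) -> CohortResult:
    """Generate every member slice of a cohort.

    Per-slice child seeds are derived deterministically from
    ``(master_seed, global slice index)`` so regeneration with the same
    master seed is identical and independent of member order changes
    that keep indices fixed.
    """
    recordings, truths, rows = [], [], []
    idx = 0
    for member in cohort.members:
        for j in range(member.n_slices):
            sid = f"{member.name}-{j:03d}"
            rng = np.random.default_rng(np.random.SeedSequence((cohort.master_seed, idx)))
            rec, truth = synth_slice(member.config, rng, acq,
                                     sweep_interval_s=cohort.sweep_interval_s,
                                     baseline_duration_min=cohort.baseline_duration_min,
                                     post_duration_min=cohort.post_duration_min,
                                     slice_id=sid)
            recordings.append(rec)
            truths.append(truth)
            rows.append({"slice_id": sid, "member": member.name,
                         "group": member.config.group, "pathway": member.config.pathway,
                         "drug": member.config.drug, "n_sweeps": len(rec.sweeps),
                         "master_seed": cohort.master_seed, "slice_index": idx})
            idx += 1
    manifest = pd.DataFrame(rows)
    if manifest["slice_id"].duplicated().any():
        raise ValueError("duplicate slice identifiers in cohort")
    return CohortResult(recordings, truths, manifest, cohort)


def apply_d_ap5(config: SliceSimConfig) -> SliceSimConfig:
    """Derive the D-AP5 bath condition from a drug-free config.

    NMDAR-dependent potentiation (the A/C pathway) collapses to ~1.0;
    afterpotential processes of NMDAR-CSF groups are emptied, control
    incidence is left unchanged; MF potentiation (NMDAR-independent) is
    untouched.  This is a contrast-level transformation, not
    pharmacokinetics.
    """
    kwargs: dict = {"drug": "D-AP5"}
    if config.pathway == "A/C":
        kwargs["potentiation_factor"] = LogNormalSpec(
            1.0, min(0.25, config.potentiation_factor.sd / max(config.potentiation_factor.mean, 1e-9)))
    if config.group.startswith("N"):
        kwargs["afterpotentials_before"] = replace(config.afterpotentials_before,
                                                   presence_prob=0.0,
                                                   count_distribution=ZERO_COUNTS)
        kwargs["afterpotentials_after"] = replace(config.afterpotentials_after,
                                                  presence_prob=0.0,
                                                  count_distribution=ZERO_COUNTS)
    return replace(config, **kwargs)
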