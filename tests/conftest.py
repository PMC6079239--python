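"""Shared fixtures and independent brute-force oracles."""

from __future__ import annotations

import math

import numpy as np
import pytest

from ca3ltp.core import AcquisitionParams, PHASE_BEFORE, PHASE_AFTER
from ca3ltp.traces import AnalysisConfig, measure_fepsp
from ca3ltp.pipeline import analyze_slice
from ca3ltp.reference import cohort_plan, CONTROL_SUBGROUPS, NMDAR_SUBGROUPS
from ca3ltp.synth import synth_cohort

#: acquisition without the 1 kHz filter, for closed-form waveform checks
NO_FILTER = AcquisitionParams(filter_hz=None)


# ---------------------------------------------------------------------------
# brute-force oracles (independent re-implementations by direct definition)


def _prominence_by_definition(x: np.ndarray, i: int, wlen: int) -> float:
    """Topographic prominence of maximum ``i`` of ``x`` within a window."""
    half = (wlen | 1) // 2
    lo, hi = max(0, i - half), min(len(x) - 1, i + half)
    left_min = x[i]
    j = i
    while j > lo and x[j - 1] <= x[i]:
        j -= 1
        left_min = min(left_min, x[j])
    right_min = x[i]
    j = i
    while j < hi and x[j + 1] <= x[i]:
        j += 1
        right_min = min(right_min, x[j])
    return float(x[i] - max(left_min, right_min))


def brute_force_afterpotentials(sweep, noise, cfg: AnalysisConfig = AnalysisConfig()):
    """Exhaustive scan: every strict local minimum, then the depth test."""
    feats = measure_fepsp(sweep, cfg)
    stims = sorted(sweep.stimulus_times)
    stim = stims[0]
    i_stim = sweep.index_at(stim)
    t0 = stim + (feats.trough_time_ms + cfg.refractory_ms) * 1e-3
    t1 = stim + cfg.response_window_ms * 1e-3
    if len(stims) > 1:
        t1 = min(t1, stims[1])
    i0, i1 = sweep.index_at(t0), sweep.index_at(t1)
    x = -sweep.samples[i0:i1]
    dt_ms = sweep.dt * 1e3
    wlen = max(3, int(round(cfg.prominence_wlen_ms / dt_ms)) | 1)
    thr = cfg.threshold_multiplier * noise.peak_to_peak
    events = []
    for i in range(1, len(x) - 1):
        if x[i] > x[i - 1] and x[i] > x[i + 1]:
            p = _prominence_by_definition(x, i, wlen)
            if p > thr:
                events.append(((i0 + i - i_stim) * dt_ms, p))
    return events


def fisher_two_sided_enumeration(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by full enumeration over fixed-margin tables."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    denom = math.comb(n, c1)

    def prob(x: int) -> float:
        return math.comb(r1, x) * math.comb(r2, c1 - x) / denom

    p_obs = prob(a)
    lo, hi = max(0, c1 - r2), min(r1, c1)
    return sum(prob(x) for x in range(lo, hi + 1) if prob(x) <= p_obs * (1 + 1e-7))


@pytest.fixture
def ap_oracle():
    return brute_force_afterpotentials


@pytest.fixture
def fisher_oracle():
    return fisher_two_sided_enumeration


# ---------------------------------------------------------------------------
# shared synthetic cohorts (expensive; generated once per session)


@pytest.fixture(scope="session")
def control_cohort():
    """The five-subgroup control cohort at its published sizes (62 slices)."""
    return synth_cohort(cohort_plan(CONTROL_SUBGROUPS, master_seed=101))


@pytest.fixture(scope="session")
def control_outcomes(control_cohort):
    return [analyze_slice(rec) for rec in control_cohort.recordings]


@pytest.fixture(scope="session")
def nmdar_cohort():
    """The three-subgroup NMDAR-CSF cohort (40 slices)."""
    return synth_cohort(cohort_plan(NMDAR_SUBGROUPS, master_seed=102))


@pytest.fixture(scope="session")
def nmdar_outcomes(nmdar_cohort):
    return [analyze_slice(rec) for rec in nmdar_cohort.recordings]
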