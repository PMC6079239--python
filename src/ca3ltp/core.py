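"""Core containers for sweep-based extracellular slice recordings.

A *sweep* is one digitized voltage trace evoked by one (or two, for
paired-pulse protocols) extracellular stimulus. A *slice recording* is the
ordered sweep timeline of a single hippocampal slice experiment, with the
plasticity-induction event (mdBS or tetanus) at time zero.

Conventions used throughout the package:

* voltages are in mV, sample spacing ``dt`` in seconds,
* ``sweep_time`` is the acquisition time of a sweep in minutes relative to
  the induction event (negative = baseline),
* stimulus times are in seconds from the start of the sweep.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

#: Designated analysis phases (minutes relative to induction): the ten
#: sweeps from -5 to -0.5 min before induction and the ten sweeps from
#: 0.5 to 5 min after it.
PHASE_BEFORE: tuple[float, float] = (-5.0, -0.5)
PHASE_AFTER: tuple[float, float] = (0.5, 5.0)


@dataclass(frozen=True)
class AcquisitionParams:
    """Digitization settings of the emulated acquisition chain.

    The analog chain low-pass filters at ``filter_hz`` (set ``None`` to
    disable) before digitization at ``sample_rate_hz``.  The stimulus is
    placed at ``stim_ms`` so that a full 50 ms pre-stimulus noise window
    and a 120 ms post-stimulus response window both fit in the sweep.
    """

    sample_rate_hz: float = 10_000.0
    sweep_ms: float = 200.0
    stim_ms: float = 60.0
    filter_hz: Optional[float] = 1000.0

    def __post_init__(self) -> None:
        if self.sample_rate_hz <= 0 or self.sweep_ms <= 0:
            raise ValueError("sample rate and sweep length must be positive")
        if not 0 < self.stim_ms < self.sweep_ms:
            raise ValueError("stimulus must fall inside the sweep")
        if self.filter_hz is not None and not 0 < self.filter_hz < self.sample_rate_hz / 2:
            raise ValueError("filter corner must be below Nyquist")

    @property
    def dt(self) -> float:
        """Sample interval in seconds."""
        return 1.0 / self.sample_rate_hz

    @property
    def n_samples(self) -> int:
        return int(round(self.sweep_ms * 1e-3 * self.sample_rate_hz))

    @property
    def stim_time_s(self) -> float:
        return self.stim_ms * 1e-3

    def time_ms(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sample_rate_hz * 1e3


@dataclass
class Sweep:
    """One evoked trace: uniformly sampled voltage plus stimulus timing."""

    samples: np.ndarray          # mV
    dt: float                    # s
    stimulus_times: tuple[float, ...]  # s from sweep start
    sweep_time: float            # min relative to induction
    labels: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size < 2:
            raise ValueError("samples must be a 1-D array with >=2 points")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        self.stimulus_times = tuple(float(t) for t in self.stimulus_times)
        if not self.stimulus_times:
            raise ValueError("a sweep needs at least one stimulus")
        dur = self.samples.size * self.dt
        if any(not 0 <= t < dur for t in self.stimulus_times):
            raise ValueError("stimulus times must fall within the record")

    @property
    def duration_s(self) -> float:
        return self.samples.size * self.dt

    def time_s(self) -> np.ndarray:
        return np.arange(self.samples.size) * self.dt

    def index_at(self, t_s: float) -> int:
        """Sample index of time ``t_s`` (clipped to the record)."""
        return int(np.clip(round(t_s / self.dt), 0, self.samples.size - 1))


@dataclass
class SliceRecording:
    """Ordered sweep timeline of one slice with phase/protocol markers."""

    slice_id: str
    pathway: str                 # "A/C" or "MF"
    group: str                   # subgroup label, e.g. "C1", "N3", "naive"
    drug: str = "none"           # bath condition: "none" or "D-AP5"
    induction: Optional[str] = None   # "mdBS", "tetanus" or None
    sweeps: list = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.pathway not in ("A/C", "MF"):
            raise ValueError(f"unknown pathway {self.pathway!r}")

    def sweeps_where(self, *, protocol: Optional[str] = None,
                     drug: Optional[str] = None,
                     window: Optional[tuple[float, float]] = None) -> list:
        """Sweeps filtered by protocol label, drug label and time window."""
        out = []
        for sw in self.sweeps:
            if protocol is not None and sw.labels.get("protocol") != protocol:
                continue
            if drug is not None and sw.labels.get("drug", "none") != drug:
                continue
            if window is not None and not (window[0] <= sw.sweep_time <= window[1]):
                continue
            out.append(sw)
        return out

    def phase_sweeps(self, phase: str) -> list:
        """The designated single-pulse sweeps of ``phase`` ('before'/'after')."""
        window = PHASE_BEFORE if phase == "before" else PHASE_AFTER
        if phase not in ("before", "after"):
            raise ValueError("phase must be 'before' or 'after'")
        return self.sweeps_where(protocol="single", window=window)
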