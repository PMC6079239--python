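"""Config-driven orchestration: sweeps in, cohort report out.

``run_pipeline`` takes recordings (generated synthetically from a cohort
config or loaded from disk), extracts per-sweep features, derives
per-slice plasticity outcomes, assembles the cohort metrics table, runs
the statistical battery, and emits a structured report (JSON + CSV +
human-readable summary).  Everything is deterministic given the seed and
inputs, and the report carries a provenance hash of the configuration.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .core import SliceRecording, PHASE_BEFORE, PHASE_AFTER
from .traces import (AnalysisConfig, estimate_noise, measure_fepsp,
                     detect_afterpotentials)
from .plasticity import (PlasticityOutcome, ltp_magnitude, paired_pulse_ratio,
                         frequency_facilitation, drug_residual, peak_fold_change)
from .stats import (ContingencyTable, build_contingency, fisher_exact_two_sided,
                    kruskal_wallis, mann_whitney_u, anova_with_posthoc,
                    pearson_correlation_test, round_p)
from .synth import CohortConfig, synth_cohort
from .io import read_cohort, read_cohort_hdf5
from .reference import supergroup

log = logging.getLogger("ca3ltp")

__all__ = ["PipelineConfig", "CohortReport", "analyze_slice", "run_pipeline",
           "PipelineError", "InputError"]


class PipelineError(RuntimeError):
    """Base class for pipeline failures."""


class InputError(PipelineError):
    """Missing or malformed input data."""


@dataclass(frozen=True)
class PipelineConfig:
    """What to analyze and how.

    Exactly one input source: a synthetic ``cohort`` config, or an
    ``input_path`` (text-layout directory or HDF5 container).  Phase
    windows default to the -5..-0.5 and 0.5..5 min conventions.
    """

    cohort: Optional[CohortConfig] = None
    input_path: Optional[str] = None
    input_format: str = "text"             # "text" or "hdf5"
    analysis: AnalysisConfig = AnalysisConfig()
    phase_before: tuple[float, float] = PHASE_BEFORE
    phase_after: tuple[float, float] = PHASE_AFTER
    out_dir: Optional[str] = None
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if (self.cohort is None) == (self.input_path is None):
            raise ValueError("exactly one of cohort / input_path must be given")
        if self.phase_before[1] > self.phase_after[0]:
            raise ValueError("phase windows must not overlap")

    def provenance_hash(self) -> str:
        def enc(o):
            if dataclasses.is_dataclass(o) and not isinstance(o, type):
                return {k: enc(v) for k, v in dataclasses.asdict(o).items()}
            if isinstance(o, (list, tuple)):
                return [enc(v) for v in o]
            if isinstance(o, dict):
                return {k: enc(v) for k, v in o.items()}
            return o
        blob = json.dumps(enc(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class CohortReport:
    metrics: pd.DataFrame
    comparisons: dict
    contingency: dict
    provenance: dict
    outcomes: list = field(default_factory=list)

    def to_json_dict(self) -> dict:
        return {
            "provenance": self.provenance,
            "metrics": json.loads(self.metrics.to_json(orient="records")),
            "comparisons": self.comparisons,
            "contingency": self.contingency,
        }


def _designated(recording: SliceRecording, window) -> list:
    return recording.sweeps_where(protocol="single", window=window)


def analyze_slice(recording: SliceRecording,
                  cfg: AnalysisConfig = AnalysisConfig(),
                  phase_before=PHASE_BEFORE, phase_after=PHASE_AFTER) -> PlasticityOutcome:
    """Extract every applicable per-slice metric from one recording."""
    out = PlasticityOutcome(slice_id=recording.slice_id, group=recording.group,
                            pathway=recording.pathway, drug=recording.drug)

    singles = recording.sweeps_where(protocol="single")
    singles = [sw for sw in singles if sw.labels.get("drug") != "DCG-IV"]
    if singles and any(sw.sweep_time < 0 for sw in singles) \
            and any(sw.sweep_time > 0 for sw in singles):
        feats = []
        for sw in recording.sweeps:
            if sw.labels.get("protocol") == "single" and sw.labels.get("drug") != "DCG-IV":
                feats.append(measure_fepsp(sw, cfg))
            else:
                feats.append(None)
        try:
            out.ltp_magnitude = ltp_magnitude(
                recording,
                [f if f is not None else measure_fepsp_placeholder() for f in feats])
        except ValueError as e:
            log.warning("%s: no LTP magnitude (%s)", recording.slice_id, e)

        for phase, window in (("before", phase_before), ("after", phase_after)):
            des = _designated(recording, window)
            if not des:
                continue
            noise = estimate_noise(des, noise_window_ms=cfg.noise_window_ms)
            counts = []
            for sw in des:
                f = measure_fepsp(sw, cfg)
                if not f.detected:
                    counts.append(0)
                    continue
                counts.append(len(detect_afterpotentials(sw, noise, cfg, f)))
            if phase == "before":
                out.ap_count_before = float(np.mean(counts))
                out.ap_present_before = any(c > 0 for c in counts)
                before_counts = counts
            else:
                out.ap_count_after = float(np.mean(counts))
                out.ap_present_after = any(c > 0 for c in counts)
                after_counts = counts
        if out.ap_count_before is not None and out.ap_count_after is not None:
            out.peak_fold_change = peak_fold_change(before_counts, after_counts)

    pp = recording.sweeps_where(protocol="paired_pulse")
    if pp:
        ratios = []
        for sw in pp:
            try:
                ratios.append(paired_pulse_ratio(sw, cfg))
            except ValueError as e:
                log.warning("%s: paired-pulse sweep skipped (%s)", recording.slice_id, e)
        if ratios:
            out.ppr = float(np.mean(ratios))

    if recording.sweeps_where(protocol="ff_baseline"):
        try:
            out.freq_facilitation = frequency_facilitation(recording, cfg).percent
        except ValueError as e:
            log.warning("%s: no facilitation (%s)", recording.slice_id, e)

    if any(sw.labels.get("drug") == "DCG-IV" for sw in recording.sweeps):
        try:
            out.drug_residual = drug_residual(recording, cfg).percent
        except ValueError as e:
            log.warning("%s: no drug residual (%s)", recording.slice_id, e)
    return out


def measure_fepsp_placeholder():
    from .traces import FepspFeatures
    return FepspFeatures(detected=False)


def _load(config: PipelineConfig):
    if config.cohort is not None:
        return synth_cohort(config.cohort).recordings
    path = Path(config.input_path)
    if config.input_format == "hdf5":
        if not path.exists():
            raise InputError(f"input container {path} does not exist")
        return read_cohort_hdf5(path)
    if not path.exists():
        raise InputError(f"input directory {path} does not exist")
    try:
        return read_cohort(path)
    except FileNotFoundError as e:
        raise InputError(str(e)) from None


def _test_result_dict(tr) -> dict:
    return {"statistic": tr.statistic, "p_value": tr.p_value,
            "p_rounded": round_p(tr.p_value), "method": tr.method,
            "n": list(tr.n)}


def _group_comparisons(df: pd.DataFrame, outcomes) -> tuple[dict, dict]:
    comparisons: dict = {}
    contingency: dict = {}
    ac = df[(df.pathway == "A/C") & df.ltp_magnitude.notna()]
    if not ac.empty:
        sg = ac.group.map(supergroup)
        ctrl = ac[(sg != "NMDAR-CSF") & (ac.drug == "none")].ltp_magnitude
        nmdar = ac[(sg == "NMDAR-CSF") & (ac.drug == "none")].ltp_magnitude
        if len(ctrl) >= 3 and len(nmdar) >= 3:
            comparisons["ltp_control_vs_nmdar"] = _test_result_dict(
                mann_whitney_u(ctrl, nmdar))
            comparisons["ltp_control_vs_nmdar"]["means"] = [
                float(ctrl.mean()), float(nmdar.mean())]
        ctrl_groups = [g.ltp_magnitude.values for _, g in
                       ac[(sg != "NMDAR-CSF") & (ac.drug == "none")].groupby("group")
                       if len(g) >= 3]
        if len(ctrl_groups) >= 3:
            comparisons["ltp_control_subgroups"] = _test_result_dict(
                kruskal_wallis(*ctrl_groups))
        nm = ac[(sg == "NMDAR-CSF") & (ac.drug == "none")]
        nm_groups = {k: g.ltp_magnitude.values for k, g in nm.groupby("group")
                     if len(g) >= 3}
        if len(nm_groups) >= 3:
            anova, pairs = anova_with_posthoc(nm_groups)
            comparisons["ltp_nmdar_subgroups"] = _test_result_dict(anova)
            comparisons["ltp_nmdar_subgroups"]["posthoc"] = [
                {"groups": list(p.groups), "q": None if np.isnan(p.q) else p.q,
                 "critical": p.critical, "span": p.span,
                 "significant": p.significant} for p in pairs]

        # fold-change / LTP correlation per supergroup
        for name, mask in (("control", sg != "NMDAR-CSF"), ("nmdar", sg == "NMDAR-CSF")):
            sub = ac[mask & (ac.drug == "none") & ac.peak_fold_change.notna()]
            if len(sub) >= 5 and sub.peak_fold_change.std() > 0:
                comparisons[f"foldchange_ltp_correlation_{name}"] = _test_result_dict(
                    pearson_correlation_test(sub.peak_fold_change, sub.ltp_magnitude))

        # Table-2-shaped contingency: supergroup x phase, without vs with D-AP5
        ac_outcomes = [o for o in outcomes if o.pathway == "A/C"]
        for sgname in ("ACSF", "control-CSF", "NMDAR-CSF"):
            rows = [o for o in ac_outcomes if supergroup(o.group) == sgname]
            if not rows or len({o.drug for o in rows}) < 2:
                continue
            for phase in ("before", "after"):
                usable = [o for o in rows
                          if getattr(o, f"ap_present_{phase}") is not None]
                if not usable:
                    continue
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    table = build_contingency(
                        usable, lambda o: "without D-AP5" if o.drug == "none"
                        else "with D-AP5", phase,
                        row_labels=("without D-AP5", "with D-AP5"))
                fisher = fisher_exact_two_sided(table)
                contingency[f"{sgname}|{phase}"] = {
                    "table": table.to_array().tolist(),
                    "row_labels": list(table.row_labels),
                    "fisher_p": fisher.p_value,
                    "fisher_p_rounded": round_p(fisher.p_value),
                }
    mf = df[(df.pathway == "MF") & df.ltp_magnitude.notna()]
    if not mf.empty and mf.group.nunique() >= 2:
        gs = [g.ltp_magnitude.values for _, g in mf.groupby("group") if len(g) >= 3]
        if len(gs) == 2:
            comparisons["mf_ltp_control_vs_nmdar"] = _test_result_dict(
                mann_whitney_u(gs[0], gs[1]))
    return comparisons, contingency


def run_pipeline(config: PipelineConfig) -> CohortReport:
    """Run the full analysis and (optionally) write the report files."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    recordings = _load(config)
    if not recordings:
        raise InputError("no recordings to analyze")
    log.info("analyzing %d slice recordings", len(recordings))

    outcomes = [analyze_slice(rec, config.analysis,
                              config.phase_before, config.phase_after)
                for rec in recordings]
    metrics = pd.DataFrame([dataclasses.asdict(o) for o in outcomes])
    comparisons, contingency = _group_comparisons(metrics, outcomes)

    provenance = {"config_hash": config.provenance_hash(),
                  "seed": config.cohort.master_seed if config.cohort else None,
                  "version": __version__,
                  "n_slices": len(recordings),
                  "timestamp": datetime.now(timezone.utc).isoformat()}
    report = CohortReport(metrics=metrics, comparisons=comparisons,
                          contingency=contingency, provenance=provenance,
                          outcomes=outcomes)

    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        metrics.to_csv(out / "metrics.csv", index=False)
        (out / "report.json").write_text(
            json.dumps(report.to_json_dict(), indent=1, sort_keys=True))
        (out / "summary.txt").write_text(render_summary(report))
    return report


def render_summary(report: CohortReport) -> str:
    """Human-readable digest of a cohort report."""
    lines = [f"ca3ltp cohort report (v{report.provenance['version']}, "
             f"config {report.provenance['config_hash']})",
             f"slices analyzed: {report.provenance['n_slices']}", ""]
    df = report.metrics
    if "ltp_magnitude" in df and df.ltp_magnitude.notna().any():
        lines.append("LTP magnitude (% of baseline) by group:")
        for (g, drug), sub in df[df.ltp_magnitude.notna()].groupby(["group", "drug"]):
            sem = sub.ltp_magnitude.sem() if len(sub) > 1 else float("nan")
            lines.append(f"  {g:12s} {drug:8s} {sub.ltp_magnitude.mean():6.1f} "
                         f"+/- {sem:5.1f} % (n={len(sub)})")
        lines.append("")
    for name, c in report.comparisons.items():
        lines.append(f"{name}: {c['method']}, p = {c['p_rounded']}")
    if report.contingency:
        lines.append("")
        lines.append("Afterpotential contingency (present/absent, without vs with D-AP5):")
        for key, c in report.contingency.items():
            t = c["table"]
            lines.append(f"  {key:24s} {t[0]} vs {t[1]}  Fisher p = {c['fisher_p_rounded']}")
    return "\n".join(lines) + "\n"
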