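"""Reading and writing cohorts of sweep recordings.

Two interchangeable layouts:

* **text**: one two-column delimited file per sweep (``time_s
  voltage_mV``), a JSON sidecar per slice holding all metadata, and a
  cohort-level ``manifest.csv``;
* **hdf5**: a single container mirroring the same hierarchy
  (one group per slice, one dataset per sweep, metadata as attributes).

Round-trips preserve voltages to full float64 precision and every
metadata field.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .core import Sweep, SliceRecording

__all__ = ["write_cohort", "read_cohort", "write_cohort_hdf5", "read_cohort_hdf5"]

_FLOAT_FMT = "%.17g"   # lossless for float64


def _sweep_meta(sw: Sweep) -> dict:
    return {"dt": sw.dt, "stimulus_times": list(sw.stimulus_times),
            "sweep_time": sw.sweep_time, "labels": sw.labels,
            "n_samples": int(sw.samples.size)}


def write_cohort(recordings: Sequence[SliceRecording], out_dir,
                 manifest: pd.DataFrame | None = None) -> Path:
    """Write the text layout; returns the cohort directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in recordings:
        sdir = out / rec.slice_id
        sdir.mkdir(parents=True, exist_ok=True)
        meta = {"slice_id": rec.slice_id, "pathway": rec.pathway,
                "group": rec.group, "drug": rec.drug, "induction": rec.induction,
                "metadata": rec.metadata, "sweeps": []}
        for i, sw in enumerate(rec.sweeps):
            fname = f"sweep_{i:04d}.txt"
            t = sw.time_s()
            np.savetxt(sdir / fname, np.column_stack([t, sw.samples]),
                       fmt=_FLOAT_FMT, delimiter="\t",
                       header="time_s\tvoltage_mV")
            m = _sweep_meta(sw)
            m["file"] = fname
            meta["sweeps"].append(m)
        (sdir / "slice.json").write_text(json.dumps(meta, indent=1, sort_keys=True))
        rows.append({"slice_id": rec.slice_id, "group": rec.group,
                     "pathway": rec.pathway, "drug": rec.drug,
                     "n_sweeps": len(rec.sweeps), "path": rec.slice_id})
    (manifest if manifest is not None else pd.DataFrame(rows)).to_csv(
        out / "manifest.csv", index=False)
    return out


def _check_uniform(t: np.ndarray, dt: float, path: str) -> None:
    if t.size >= 2:
        diffs = np.diff(t)
        if not np.allclose(diffs, dt, rtol=1e-6, atol=dt * 1e-6):
            raise ValueError(f"{path}: non-uniform time base")


def read_cohort(in_dir) -> list[SliceRecording]:
    """Read the text layout back into SliceRecordings."""
    root = Path(in_dir)
    sidecars = sorted(root.glob("*/slice.json"))
    if not sidecars:
        raise FileNotFoundError(f"no slice.json sidecars under {root}")
    recordings = []
    for sc in sidecars:
        meta = json.loads(sc.read_text())
        rec = SliceRecording(slice_id=meta["slice_id"], pathway=meta["pathway"],
                             group=meta["group"], drug=meta["drug"],
                             induction=meta["induction"],
                             metadata=meta.get("metadata", {}))
        for i, m in enumerate(meta["sweeps"]):
            arr = np.loadtxt(sc.parent / m["file"], delimiter="\t")
            if arr.ndim != 2 or arr.shape[1] != 2:
                raise ValueError(f"{m['file']}: expected two columns")
            t, v = arr[:, 0], arr[:, 1]
            if v.size != m["n_samples"]:
                raise ValueError(f"{sc.parent.name} sweep {i} ({m['file']}): "
                                 f"sample count {v.size} != metadata {m['n_samples']}")
            _check_uniform(t, m["dt"], str(sc.parent / m["file"]))
            rec.sweeps.append(Sweep(samples=v, dt=m["dt"],
                                    stimulus_times=tuple(m["stimulus_times"]),
                                    sweep_time=m["sweep_time"],
                                    labels=m["labels"]))
        recordings.append(rec)
    return recordings


def write_cohort_hdf5(recordings: Sequence[SliceRecording], path) -> Path:
    import h5py
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with h5py.File(path, "w") as f:
        for rec in recordings:
            g = f.create_group(rec.slice_id)
            g.attrs["pathway"] = rec.pathway
            g.attrs["group"] = rec.group
            g.attrs["drug"] = rec.drug
            g.attrs["induction"] = rec.induction if rec.induction else ""
            g.attrs["metadata"] = json.dumps(rec.metadata, sort_keys=True)
            for i, sw in enumerate(rec.sweeps):
                d = g.create_dataset(f"sweep_{i:04d}", data=sw.samples)
                d.attrs["dt"] = sw.dt
                d.attrs["stimulus_times"] = list(sw.stimulus_times)
                d.attrs["sweep_time"] = sw.sweep_time
                d.attrs["labels"] = json.dumps(sw.labels, sort_keys=True)
    return path


def read_cohort_hdf5(path) -> list[SliceRecording]:
    import h5py
    recordings = []
    with h5py.File(path, "r") as f:
        for sid in sorted(f.keys()):
            g = f[sid]
            rec = SliceRecording(slice_id=sid, pathway=g.attrs["pathway"],
                                 group=g.attrs["group"], drug=g.attrs["drug"],
                                 induction=g.attrs["induction"] or None,
                                 metadata=json.loads(g.attrs["metadata"]))
            for name in sorted(g.keys()):
                d = g[name]
                rec.sweeps.append(Sweep(samples=d[...],
                                        dt=float(d.attrs["dt"]),
                                        stimulus_times=tuple(d.attrs["stimulus_times"]),
                                        sweep_time=float(d.attrs["sweep_time"]),
                                        labels=json.loads(d.attrs["labels"])))
            recordings.append(rec)
    return recordings
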