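"""On-disk formats: per-cell trace files, behavior tables, features tables.

Trace format (plain text, bit-exact round trip):

* ``<cell_id>.json`` -- metadata: cell/animal ids, sampling rate, step timing,
  the ordered current amplitudes, and (for simulated cells) the ground truth.
* ``<cell_id>.csv`` -- the voltage matrix, one column per sweep (header names
  the injection, e.g. ``I_-300pA``), one row per sample, in mV.

An HDF5 container mirroring the same layout is available via
:func:`write_recording_h5` / :func:`read_recording_h5` for large cohorts.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .neuron import Recording, StepProtocol

__all__ = [
    "write_recording",
    "read_recording",
    "write_recording_h5",
    "read_recording_h5",
    "write_cohort",
    "read_cohort_recordings",
]

_FLOAT_FMT = "%.4f"  # 0.1 uV resolution, ample below the 0.5 mV noise floor


def _meta_dict(rec: Recording) -> dict:
    p = rec.protocol
    return {
        "cell_id": rec.cell_id,
        "animal_id": rec.animal_id,
        "sampling_rate_hz": p.sampling_rate_hz,
        "baseline_ms": p.baseline_ms,
        "step_ms": p.step_ms,
        "post_ms": p.post_ms,
        "currents_pA": list(p.current_amplitudes_pA),
        "ground_truth": rec.ground_truth,
    }


def _protocol_from_meta(meta: dict) -> StepProtocol:
    return StepProtocol(
        current_amplitudes_pA=tuple(meta["currents_pA"]),
        baseline_ms=meta["baseline_ms"],
        step_ms=meta["step_ms"],
        post_ms=meta["post_ms"],
        sampling_rate_hz=meta["sampling_rate_hz"],
    )


def write_recording(rec: Recording, out_dir) -> Path:
    """Write one cell as ``<cell_id>.json`` + ``<cell_id>.csv``; returns the JSON path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    meta_path = out_dir / f"{rec.cell_id}.json"
    meta_path.write_text(json.dumps(_meta_dict(rec), indent=1, sort_keys=True))
    header = ",".join(f"I_{int(a)}pA" for a in rec.protocol.current_amplitudes_pA)
    np.savetxt(
        out_dir / f"{rec.cell_id}.csv", rec.sweeps.T,
        fmt=_FLOAT_FMT, delimiter=",", header=header, comments="",
    )
    return meta_path


def read_recording(meta_path) -> Recording:
    """Read a cell written by :func:`write_recording` from its JSON metadata path."""
    meta_path = Path(meta_path)
    meta = json.loads(meta_path.read_text())
    csv_path = meta_path.with_suffix(".csv")
    mat = np.loadtxt(csv_path, delimiter=",", skiprows=1, ndmin=2)
    return Recording(
        sweeps=mat.T,
        protocol=_protocol_from_meta(meta),
        cell_id=meta["cell_id"],
        animal_id=meta["animal_id"],
        ground_truth=meta.get("ground_truth"),
    )


def write_recording_h5(rec: Recording, path) -> Path:
    """Write one cell to an HDF5 file mirroring the JSON+CSV layout."""
    import h5py

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with h5py.File(path, "w") as f:
        f.create_dataset("sweeps_mV", data=rec.sweeps)
        f.attrs["meta"] = json.dumps(_meta_dict(rec), sort_keys=True)
    return path


def read_recording_h5(path) -> Recording:
    import h5py

    with h5py.File(path, "r") as f:
        sweeps = f["sweeps_mV"][...]
        meta = json.loads(f.attrs["meta"])
    return Recording(
        sweeps=sweeps,
        protocol=_protocol_from_meta(meta),
        cell_id=meta["cell_id"],
        animal_id=meta["animal_id"],
        ground_truth=meta.get("ground_truth"),
    )


def write_cohort(cohort, out_dir, traces: bool = True, trace_format: str = "csv") -> Path:
    """Write a simulated cohort: behavior.csv, ground_truth.json, traces/.

    ``trace_format`` is ``"csv"`` (JSON+CSV pairs) or ``"h5"``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cohort.behavior.to_csv(out_dir / "behavior.csv", index=False)
    (out_dir / "ground_truth.json").write_text(
        json.dumps(cohort.ground_truth, indent=1, sort_keys=True)
    )
    if traces:
        trace_dir = out_dir / "traces"
        for recs in cohort.recordings.values():
            for rec in recs:
                if trace_format == "csv":
                    write_recording(rec, trace_dir)
                elif trace_format == "h5":
                    write_recording_h5(rec, trace_dir / f"{rec.cell_id}.h5")
                else:
                    raise ValueError(f"unknown trace_format {trace_format!r}")
    return out_dir


def read_cohort_recordings(trace_dir) -> list[Recording]:
    """Load every recording under a trace directory (JSON+CSV and/or HDF5)."""
    trace_dir = Path(trace_dir)
    recs = [read_recording(p) for p in sorted(trace_dir.glob("*.json"))]
    recs += [read_recording_h5(p) for p in sorted(trace_dir.glob("*.h5"))]
    if not recs:
        raise FileNotFoundError(f"no trace files found under {trace_dir}")
    return recs
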