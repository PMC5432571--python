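"""Trace and results I/O: CSV traces, JSON manifests, tidy CSV tables."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .synth import CurrentTrace

__all__ = ["write_trace", "read_trace", "write_json", "read_json"]

TRACE_COLUMNS = ["time_s", "current_pA", "voltage_mV"]


def write_trace(trace: CurrentTrace, path) -> Path:
    """Write a sweep as CSV (time_s, current_pA, voltage_mV [+ metadata
    columns]); the metadata dict rides along in a sidecar .json file."""
    path = Path(path)
    df = pd.DataFrame({c: getattr(trace, c) for c in TRACE_COLUMNS})
    df.to_csv(path, index=False, float_format="%.17g")  # exact float round-trip
    meta = {k: v for k, v in trace.meta.items()}
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(meta, indent=1, sort_keys=True, default=str))
    return path


def read_trace(path) -> CurrentTrace:
    """Read a sweep CSV; extra columns are preserved in meta['extra_columns']."""
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in TRACE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    t = df["time_s"].to_numpy()
    bad = np.where(np.diff(t) <= 0)[0]
    if len(bad):
        raise ValueError(f"{path}: non-monotone time at data row {int(bad[0]) + 2}")
    meta = {}
    sidecar = path.with_suffix(path.suffix + ".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        if "voltage_segments" in meta:
            meta["voltage_segments"] = [tuple(s) for s in meta["voltage_segments"]]
        if "solution_windows" in meta:
            meta["solution_windows"] = [tuple(w) for w in meta["solution_windows"]]
    extra = [c for c in df.columns if c not in TRACE_COLUMNS]
    if extra:
        meta["extra_columns"] = {c: df[c].tolist() for c in extra}
    return CurrentTrace(time_s=t, current_pA=df["current_pA"].to_numpy(),
                        voltage_mV=df["voltage_mV"].to_numpy(), meta=meta)


def write_json(obj, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(obj, indent=1, sort_keys=True, default=str))
    return path


def read_json(path):
    return json.loads(Path(path).read_text())
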