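"""Trace file I/O: CSV samples with a JSON metadata sidecar.

A single sweep is stored as ``<name>.csv`` with columns ``time_s,
current_pA`` plus ``<name>.json`` carrying the recording metadata
(voltage, sampling rate, filter, configuration, seed and, for synthetic
traces, the ground-truth gating model).  Multi-sweep recordings use one
columnar file with a ``sweep`` index column and a sidecar listing
per-sweep metadata.  write -> read is an exact round trip for samples and
field-complete for metadata.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InvalidInputError
from .gating import GatingModel, Trace

__all__ = ["write_trace", "read_trace", "write_sweeps", "read_sweeps"]

_REQUIRED_META = ("voltage_mV", "sampling_rate_hz", "configuration")


def _meta_dict(trace: Trace) -> dict:
    meta = {
        "voltage_mV": trace.voltage_mV,
        "sampling_rate_hz": trace.sampling_rate_hz,
        "filter_hz": trace.filter_hz,
        "configuration": trace.configuration,
        "seed": trace.seed,
        "sweep_index": trace.sweep_index,
        "segments_s": trace.segments_s,
        "segment_voltages_mV": trace.segment_voltages_mV,
    }
    if trace.truth is not None:
        meta["truth"] = asdict(trace.truth)
    return meta


def _trace_from_meta(samples: np.ndarray, meta: dict) -> Trace:
    missing = [k for k in _REQUIRED_META if k not in meta]
    if missing:
        raise InvalidInputError(
            "trace sidecar is missing required fields: " + ", ".join(missing)
        )
    truth = meta.get("truth")
    return Trace(
        samples_pA=samples,
        sampling_rate_hz=float(meta["sampling_rate_hz"]),
        voltage_mV=float(meta["voltage_mV"]),
        filter_hz=meta.get("filter_hz"),
        configuration=meta["configuration"],
        seed=meta.get("seed"),
        sweep_index=meta.get("sweep_index"),
        segments_s=meta.get("segments_s"),
        segment_voltages_mV=meta.get("segment_voltages_mV"),
        truth=GatingModel(**truth) if truth else None,
    )


def _sidecar(path: Path) -> Path:
    return path.with_suffix(".json")


def write_trace(path, trace: Trace) -> None:
    """Write one sweep as CSV + JSON sidecar."""
    path = Path(path)
    df = pd.DataFrame({"time_s": trace.time_s, "current_pA": trace.samples_pA})
    df.to_csv(path, index=False, float_format="%.17g")
    _sidecar(path).write_text(json.dumps(_meta_dict(trace), indent=2, sort_keys=True))


def read_trace(path) -> Trace:
    """Read one sweep written by :func:`write_trace`."""
    path = Path(path)
    side = _sidecar(path)
    if not side.exists():
        raise InvalidInputError(
            f"missing sidecar {side.name}; required fields: "
            + ", ".join(_REQUIRED_META)
        )
    df = pd.read_csv(path, float_precision="round_trip")
    if "current_pA" not in df.columns:
        raise InvalidInputError(
            f"{path.name}: malformed header, expected columns time_s,current_pA"
        )
    meta = json.loads(side.read_text())
    return _trace_from_meta(df["current_pA"].to_numpy(), meta)


def write_sweeps(path, traces: list[Trace]) -> None:
    """Write a multi-sweep recording as one columnar CSV + sidecar list."""
    path = Path(path)
    frames = []
    for k, tr in enumerate(traces):
        frames.append(pd.DataFrame({
            "time_s": tr.time_s,
            "sweep": np.full(tr.n_samples, k, dtype=int),
            "current_pA": tr.samples_pA,
        }))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False,
                                                float_format="%.17g")
    meta = {"sweeps": [_meta_dict(tr) for tr in traces]}
    _sidecar(path).write_text(json.dumps(meta, indent=2, sort_keys=True))


def read_sweeps(path) -> list[Trace]:
    """Read a multi-sweep columnar file into per-sweep traces."""
    path = Path(path)
    side = _sidecar(path)
    if not side.exists():
        raise InvalidInputError(f"missing sidecar {side.name}")
    df = pd.read_csv(path, float_precision="round_trip")
    for col in ("sweep", "current_pA"):
        if col not in df.columns:
            raise InvalidInputError(
                f"{path.name}: malformed header, expected columns "
                "time_s,sweep,current_pA"
            )
    metas = json.loads(side.read_text())["sweeps"]
    traces = []
    for k, meta in enumerate(metas):
        samples = df.loc[df["sweep"] == k, "current_pA"].to_numpy()
        traces.append(_trace_from_meta(samples, meta))
    return traces
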