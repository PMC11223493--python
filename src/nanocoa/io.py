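"""Trace and table I/O.

Traces round-trip losslessly through two dialects:

* HDF5 container: dataset ``current_pA`` with attributes ``sampling_rate``
  and ``voltage``; unknown metadata is preserved in a JSON attribute.
* Plain CSV fallback: ``# key: value`` header comments followed by
  ``time_s,current_pA`` rows at full float precision.

Event tables, annotations and predictions are tab-separated files read
and written through pandas.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .sigproc import TranslocationEvent
from .trace import CurrentTrace

EVENT_COLUMNS = ["trace_id", "event_id", "start", "end", "duration_s", "deltaI_pA", "rel_blockade"]


class TraceFormatError(ValueError):
    """Malformed trace file (missing or unreadable required field)."""


def write_trace(path: str | Path, trace: CurrentTrace) -> None:
    """Write a trace; dialect chosen by extension (.h5/.hdf5 vs .csv)."""
    path = Path(path)
    if path.suffix in {".h5", ".hdf5"}:
        _write_trace_h5(path, trace)
    elif path.suffix == ".csv":
        _write_trace_csv(path, trace)
    else:
        raise ValueError(f"unsupported trace extension {path.suffix!r} (use .h5 or .csv)")


def read_trace(path: str | Path) -> CurrentTrace:
    """Read a trace written by :func:`write_trace`."""
    path = Path(path)
    if path.suffix in {".h5", ".hdf5"}:
        return _read_trace_h5(path)
    if path.suffix == ".csv":
        return _read_trace_csv(path)
    raise ValueError(f"unsupported trace extension {path.suffix!r} (use .h5 or .csv)")


def _write_trace_h5(path: Path, trace: CurrentTrace) -> None:
    with h5py.File(path, "w") as f:
        # track_times=False keeps byte-identical files across reruns
        ds = f.create_dataset("current_pA", data=trace.samples, track_times=False)
        ds.attrs["sampling_rate"] = trace.sampling_rate
        if trace.voltage is not None:
            ds.attrs["voltage"] = trace.voltage
        if trace.trace_id is not None:
            ds.attrs["trace_id"] = trace.trace_id
        ds.attrs["metadata_json"] = json.dumps(trace.metadata, sort_keys=True)


def _read_trace_h5(path: Path) -> CurrentTrace:
    with h5py.File(path, "r") as f:
        if "current_pA" not in f:
            raise TraceFormatError(f"{path}: missing dataset 'current_pA'")
        ds = f["current_pA"]
        if "sampling_rate" not in ds.attrs:
            raise TraceFormatError(f"{path}: missing required attribute 'sampling_rate'")
        return CurrentTrace(
            samples=ds[...],
            sampling_rate=float(ds.attrs["sampling_rate"]),
            voltage=float(ds.attrs["voltage"]) if "voltage" in ds.attrs else None,
            metadata=json.loads(ds.attrs.get("metadata_json", "{}")),
            trace_id=str(ds.attrs["trace_id"]) if "trace_id" in ds.attrs else None,
        )


def _write_trace_csv(path: Path, trace: CurrentTrace) -> None:
    with open(path, "w") as f:
        f.write(f"# sampling_rate: {trace.sampling_rate!r}\n")
        if trace.voltage is not None:
            f.write(f"# voltage: {trace.voltage!r}\n")
        if trace.trace_id is not None:
            f.write(f"# trace_id: {trace.trace_id}\n")
        f.write(f"# metadata: {json.dumps(trace.metadata, sort_keys=True)}\n")
        f.write("time_s,current_pA\n")
        t = trace.time()
        for ti, ci in zip(t, trace.samples):
            f.write(f"{float(ti)!r},{float(ci)!r}\n")


def _read_trace_csv(path: Path) -> CurrentTrace:
    header: dict[str, str] = {}
    with open(path) as f:
        pos = f.tell()
        line = f.readline()
        while line.startswith("#"):
            try:
                key, value = line[1:].split(":", 1)
            except ValueError as exc:
                raise TraceFormatError(f"{path}: malformed header line {line.strip()!r}") from exc
            header[key.strip()] = value.strip()
            pos = f.tell()
            line = f.readline()
        f.seek(pos)
        table = pd.read_csv(f)
    if "sampling_rate" not in header:
        raise TraceFormatError(f"{path}: missing required header field 'sampling_rate'")
    if "current_pA" not in table.columns:
        raise TraceFormatError(f"{path}: missing column 'current_pA'")
    return CurrentTrace(
        samples=table["current_pA"].to_numpy(),
        sampling_rate=float(header["sampling_rate"]),
        voltage=float(header["voltage"]) if "voltage" in header else None,
        metadata=json.loads(header.get("metadata", "{}")),
        trace_id=header.get("trace_id"),
    )


# ---------------------------------------------------------------------------
# tables


def events_to_frame(events: list[TranslocationEvent]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "trace_id": [e.trace_id for e in events],
            "event_id": np.arange(len(events)),
            "start": [e.start for e in events],
            "end": [e.end for e in events],
            "duration_s": [e.duration for e in events],
            "deltaI_pA": [e.delta_i for e in events],
            "rel_blockade": [e.rel_blockade for e in events],
        },
        columns=EVENT_COLUMNS,
    )


def write_events(path: str | Path, events: list[TranslocationEvent]) -> None:
    events_to_frame(events).to_csv(path, sep="\t", index=False)


def read_events(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def frame_to_events(frame: pd.DataFrame, sampling_rate: float | None = None) -> list[TranslocationEvent]:
    return [
        TranslocationEvent(
            start=int(r.start),
            end=int(r.end),
            duration=float(r.duration_s),
            delta_i=float(r.deltaI_pA),
            rel_blockade=float(r.rel_blockade),
            trace_id=None if pd.isna(r.trace_id) else str(r.trace_id),
        )
        for r in frame.itertuples()
    ]
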