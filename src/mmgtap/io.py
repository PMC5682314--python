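"""Readers and writers for the package's two text formats.

* Signal file: delimited text (comma or tab, autodetected), header
  ``time_s,ch1,ch2,...`` with a uniformly spaced time column in seconds.
* Event table: CSV with header ``start_sample,end_sample,label``; the label
  column may be empty for unlabelled (detected) events.

Writers are exact inverses of the readers on their own output: samples are
serialised with 17 significant digits (round-trip-exact for float64) and
event tables round-trip byte-identically.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from .core import Event, EventTable, GestureLabel, Recording

__all__ = [
    "read_recording",
    "write_recording",
    "read_event_table",
    "write_event_table",
]

PathLike = Union[str, Path]

#: Relative tolerance on sampling-interval uniformity.
_DT_RTOL = 1e-6


def _sniff_sep(path: Path) -> str:
    header = path.open("r").readline()
    return "\t" if "\t" in header else ","


def read_recording(
    path: PathLike,
    baseline_interval: Optional[tuple[int, int]] = None,
    subject_id: Optional[str] = None,
) -> Recording:
    """Parse a delimited signal file into a :class:`Recording`.

    The file must have a ``time_s`` column with constant spacing and at least
    one ``ch*`` column; NaN samples and non-uniform timestamps are rejected
    with the offending row named.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sniff_sep(path), float_precision="round_trip")
    if "time_s" not in df.columns:
        raise ValueError(f"{path}: missing required column 'time_s'")
    channels = [c for c in df.columns if c.startswith("ch")]
    if not channels:
        raise ValueError(f"{path}: no channel columns (expected ch1, ch2, ...)")
    channels.sort(key=lambda c: int(c[2:]))

    t = df["time_s"].to_numpy(dtype=np.float64)
    if t.size < 2:
        raise ValueError(f"{path}: need at least 2 samples")
    dt = np.diff(t)
    ref = np.median(dt)
    if ref <= 0:
        bad = int(np.argmax(dt <= 0)) + 1
        raise ValueError(f"{path}: non-increasing time at row {bad}")
    off = np.abs(dt - ref) > _DT_RTOL * ref
    if off.any():
        bad = int(np.argmax(off)) + 1
        raise ValueError(
            f"{path}: non-uniform sampling interval at row {bad} "
            f"(dt={dt[bad - 1]:g}, expected {ref:g})"
        )
    samples = df[channels].to_numpy(dtype=np.float64).T
    if np.isnan(samples).any():
        bad = int(np.argmax(np.isnan(samples).any(axis=0)))
        raise ValueError(f"{path}: NaN sample at row {bad}")
    return Recording(
        samples=samples,
        sampling_rate=1.0 / ref,
        subject_id=subject_id or path.stem,
        baseline_interval=baseline_interval,
    )


def write_recording(rec: Recording, path: PathLike) -> None:
    """Write a recording as CSV, round-trip exact for float64 samples."""
    path = Path(path)
    header = "time_s," + ",".join(f"ch{i + 1}" for i in range(rec.n_channels))
    data = np.column_stack([rec.times(), rec.samples.T])
    np.savetxt(path, data, fmt="%.17g", delimiter=",", header=header, comments="")


def read_event_table(path: PathLike) -> EventTable:
    """Parse an event CSV (``start_sample,end_sample,label``)."""
    path = Path(path)
    df = pd.read_csv(path, dtype={"label": "string"})
    for col in ("start_sample", "end_sample"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column '{col}'")
    events = []
    for i, row in df.iterrows():
        start, end = int(row["start_sample"]), int(row["end_sample"])
        if start >= end:
            raise ValueError(
                f"{path}: row {i}: start_sample {start} must be < end_sample {end}"
            )
        label = None
        if "label" in df.columns and pd.notna(row["label"]) and str(row["label"]):
            label = GestureLabel.from_name(str(row["label"]))
        events.append(Event(start, end, label=label))
    return EventTable(events)


def write_event_table(table: EventTable, path: PathLike) -> None:
    """Write an event table as CSV; exact inverse of :func:`read_event_table`."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("start_sample,end_sample,label\n")
        for ev in table:
            label = ev.label.name if ev.label is not None else ""
            fh.write(f"{ev.start},{ev.end},{label}\n")
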