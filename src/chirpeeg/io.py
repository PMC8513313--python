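"""Reading and writing recordings.

The on-disk container is a single HDF5 bundle::

    /samples   float64, channels x time, microvolts
    /fs        scalar, Hz
    /labels    channel labels (UTF-8)
    /regions   region per channel, aligned with /labels
    /events/   onset_sample, kind, ramp_s, chirp_s, f_start_hz, f_end_hz,
               direction, depth

Events can additionally be round-tripped through a delimited sidecar
(columns onset_sample, onset_seconds, kind, ramp_s, chirp_s, f_start_hz,
f_end_hz) for use outside HDF5-aware tools.
"""

from __future__ import annotations

import logging
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .synthgen import ChirpStimulus, EventTable, Recording

log = logging.getLogger(__name__)

_EVENT_COLUMNS = ("onset_sample", "kind", "ramp_s", "chirp_s",
                  "f_start_hz", "f_end_hz", "direction", "depth")


def events_to_frame(events: EventTable, fs: float) -> pd.DataFrame:
    """Tidy event table matching the CSV sidecar schema."""
    return pd.DataFrame({
        "onset_sample": events.onsets,
        "onset_seconds": events.onsets / fs,
        "kind": events.kinds,
        "ramp_s": [s.ramp_duration for s in events.stimuli],
        "chirp_s": [s.chirp_duration for s in events.stimuli],
        "f_start_hz": [s.f_start for s in events.stimuli],
        "f_end_hz": [s.f_end for s in events.stimuli],
        "direction": [s.direction for s in events.stimuli],
        "depth": [s.modulation_depth for s in events.stimuli],
    })


def events_from_frame(df: pd.DataFrame) -> EventTable:
    stimuli = [
        ChirpStimulus(
            ramp_duration=row.ramp_s,
            chirp_duration=row.chirp_s,
            f_start=row.f_start_hz,
            f_end=row.f_end_hz,
            direction=getattr(row, "direction", "up"),
            modulation_depth=getattr(row, "depth", 1.0),
        )
        for row in df.itertuples()
    ]
    return EventTable(
        onsets=df["onset_sample"].to_numpy(dtype=np.int64),
        kinds=[str(k) for k in df["kind"]],
        stimuli=stimuli,
    )


def write_events_csv(events: EventTable, fs: float, path: str | Path) -> None:
    events_to_frame(events, fs).to_csv(path, index=False)


def read_events_csv(path: str | Path) -> EventTable:
    return events_from_frame(pd.read_csv(path))


def write_recording(rec: Recording, path: str | Path) -> None:
    """Write a recording as a single HDF5 bundle (see module docstring)."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("samples", data=rec.samples)
        f.create_dataset("fs", data=float(rec.fs))
        str_dt = h5py.string_dtype(encoding="utf-8")
        f.create_dataset("labels", data=np.array(rec.channel_labels, dtype=object),
                         dtype=str_dt)
        regions = [rec.region_assignment[c] for c in rec.channel_labels]
        f.create_dataset("regions", data=np.array(regions, dtype=object),
                         dtype=str_dt)
        ev = f.create_group("events")
        frame = events_to_frame(rec.events, rec.fs)
        for col in _EVENT_COLUMNS:
            data = frame[col].to_numpy()
            if data.dtype == object:
                ev.create_dataset(col, data=data, dtype=str_dt)
            else:
                ev.create_dataset(col, data=data)


def read_recording(path: str | Path) -> Recording:
    """Read an HDF5 bundle; a missing /events group yields an empty table."""
    path = Path(path)
    try:
        f = h5py.File(path, "r")
    except OSError as exc:
        raise IOError(f"cannot open recording bundle {path}: {exc}") from exc
    with f:
        for name in ("samples", "fs", "labels", "regions"):
            if name not in f:
                raise IOError(f"recording bundle {path} is missing /{name}")
        samples = f["samples"][()]
        fs = float(f["fs"][()])
        labels = [s.decode() if isinstance(s, bytes) else str(s)
                  for s in f["labels"][()]]
        regions = [s.decode() if isinstance(s, bytes) else str(s)
                   for s in f["regions"][()]]
        if len(regions) != len(labels):
            raise IOError(f"recording bundle {path}: /regions misaligned with /labels")
        if "events" in f:
            ev = f["events"]
            cols = {}
            for col in _EVENT_COLUMNS:
                if col not in ev:
                    raise IOError(f"recording bundle {path}: /events missing {col}")
                data = ev[col][()]
                if data.dtype.kind in ("S", "O"):
                    data = [s.decode() if isinstance(s, bytes) else str(s)
                            for s in data]
                cols[col] = data
            frame = pd.DataFrame(cols)
            frame["onset_seconds"] = frame["onset_sample"] / fs
            events = events_from_frame(frame)
        else:
            log.warning("no /events group in %s; using an empty event table", path)
            events = EventTable()
    return Recording(
        fs=fs,
        samples=samples,
        channel_labels=labels,
        region_assignment=dict(zip(labels, regions)),
        events=events,
    )
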