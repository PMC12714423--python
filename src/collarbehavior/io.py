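"""CSV readers/writers for the package's interchange formats, plus run
manifests.

All interchange is plain CSV (matching collar-export practice): activity
records, GPS fixes, observation bouts and labeled segments.  Column names
can be remapped so vendor exports are ingested without editing.  Timestamps
are parsed as ISO-8601 and assumed UTC unless an offset is present.  Every
CLI run emits a JSON manifest (command, config, seeds, input/output
checksums, package version) sufficient to re-run it bit-identically.
"""

from __future__ import annotations

import hashlib
import json
from datetime import datetime, timezone

import numpy as np
import pandas as pd

from . import __version__
from .encode import ActivityRecord
from .label import GPSTrack, ObservationBout, map_raw_behavior

ACTIVITY_COLUMNS = ("animal_id", "interval_start", "act_x", "act_y", "act_z")


def _apply_column_map(frame: pd.DataFrame, column_map, required) -> pd.DataFrame:
    if column_map:
        frame = frame.rename(columns={v: k for k, v in column_map.items()})
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise ValueError(
            f"missing required column(s) {missing}; available headers: "
            f"{list(frame.columns)}"
        )
    return frame


def _parse_times(series: pd.Series, name: str) -> pd.Series:
    times = pd.to_datetime(series, utc=True, format="ISO8601").dt.tz_localize(None)
    if times.isna().any():
        bad = series[times.isna()].index[:5].tolist()
        raise ValueError(f"unparseable {name} timestamps at rows {bad}")
    return times


def read_activity_csv(path, column_map: dict | None = None) -> pd.DataFrame:
    """Read 5-min activity records.

    ``column_map`` maps canonical names (animal_id, interval_start, act_x,
    act_y, act_z) to the file's headers.  A file with only the three
    activity columns is accepted (single unnamed animal, no timestamps).
    Out-of-range or non-integer activity values are rejected with row
    numbers.  Extra columns are preserved.
    """
    frame = pd.read_csv(path)
    if column_map:
        frame = frame.rename(columns={v: k for k, v in column_map.items()})
    missing = [c for c in ("act_x", "act_y", "act_z") if c not in frame.columns]
    if missing:
        raise ValueError(
            f"missing activity column(s) {missing}; available headers: "
            f"{list(frame.columns)}"
        )
    acts = frame[["act_x", "act_y", "act_z"]].to_numpy()
    bad = np.flatnonzero(
        np.any(
            (acts < 0) | (acts > 255) | (acts != np.round(acts)) | ~np.isfinite(acts),
            axis=1,
        )
    )
    if bad.size:
        raise ValueError(
            "activity values must be integers in [0, 255]; offending rows "
            f"(0-based): {bad[:20].tolist()}"
        )
    if "animal_id" not in frame.columns:
        frame.insert(0, "animal_id", "unknown")
    if "interval_start" in frame.columns:
        frame["interval_start"] = _parse_times(frame["interval_start"], "interval_start")
        frame = frame.sort_values(["animal_id", "interval_start"], kind="stable")
    return frame.reset_index(drop=True)


def activity_frame_to_records(frame: pd.DataFrame) -> list[ActivityRecord]:
    return [
        ActivityRecord(
            animal_id=str(r.animal_id),
            interval_start=pd.Timestamp(r.interval_start),
            act_x=int(r.act_x),
            act_y=int(r.act_y),
            act_z=int(r.act_z),
        )
        for r in frame.itertuples()
    ]


def write_activity_csv(frame_or_records, path) -> None:
    if isinstance(frame_or_records, pd.DataFrame):
        frame = frame_or_records
    else:
        from .encode import records_to_frame

        frame = records_to_frame(frame_or_records)
    frame.to_csv(path, index=False)


def read_gps_csv(path, column_map: dict | None = None) -> list[GPSTrack]:
    """Read GPS fixes (animal_id, timestamp, x, y in projected meters).

    Longitude/latitude input must be projected upstream; a file whose
    coordinate columns are named lon/lat is rejected with a demand for a
    declared projection, since planar distances on raw degrees are
    meaningless.
    """
    frame = pd.read_csv(path)
    lowered = {c.lower() for c in frame.columns}
    if {"lon", "lat"} & lowered or {"longitude", "latitude"} & lowered:
        if not column_map:
            raise ValueError(
                "input looks like lon/lat; project coordinates to meters and "
                "declare the planar columns via column_map"
            )
    frame = _apply_column_map(frame, column_map, ("animal_id", "timestamp", "x", "y"))
    frame["timestamp"] = _parse_times(frame["timestamp"], "gps")
    tracks = []
    for animal, g in frame.groupby("animal_id", sort=True):
        g = g.sort_values("timestamp", kind="stable")
        dup = g["timestamp"].duplicated()
        if dup.any():
            t = g.loc[dup, "timestamp"].iloc[0]
            raise ValueError(f"duplicated timestamp for animal {animal} at {t}")
        tracks.append(
            GPSTrack(
                animal_id=str(animal),
                times=pd.DatetimeIndex(g["timestamp"]),
                xy=g[["x", "y"]].to_numpy(dtype=float),
            )
        )
    return tracks


def write_gps_csv(tracks: list[GPSTrack], path) -> None:
    frames = [
        pd.DataFrame(
            {
                "animal_id": t.animal_id,
                "timestamp": t.times,
                "x": t.xy[:, 0],
                "y": t.xy[:, 1],
            }
        )
        for t in tracks
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_observation_csv(
    path, column_map: dict | None = None, category_table: dict | None = None
) -> list[ObservationBout]:
    """Read observation bouts (animal_id, start, end, behavior free text);
    raw behavior labels are mapped to broad states via the category table."""
    frame = pd.read_csv(path)
    frame = _apply_column_map(frame, column_map, ("animal_id", "start", "end", "behavior"))
    frame["start"] = _parse_times(frame["start"], "bout start")
    frame["end"] = _parse_times(frame["end"], "bout end")
    bouts = [
        ObservationBout(
            animal_id=str(r.animal_id),
            start=pd.Timestamp(r.start),
            end=pd.Timestamp(r.end),
            behavior=map_raw_behavior(r.behavior, category_table),
        )
        for r in frame.itertuples()
    ]
    return sorted(bouts, key=lambda b: (b.animal_id, b.start))


def write_observation_csv(bouts: list[ObservationBout], path) -> None:
    pd.DataFrame(
        {
            "animal_id": [b.animal_id for b in bouts],
            "start": [b.start for b in bouts],
            "end": [b.end for b in bouts],
            "behavior": [b.behavior.value for b in bouts],
        }
    ).to_csv(path, index=False)


def file_checksum(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(
    path, command: str, config: dict | None = None, seed: int | None = None,
    inputs: list | None = None, outputs: list | None = None
) -> dict:
    """Write a JSON run manifest sufficient to re-run the command."""
    manifest = {
        "command": command,
        "config": config or {},
        "seed": seed,
        "package_version": __version__,
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "inputs": {str(p): file_checksum(p) for p in (inputs or [])},
        "outputs": {str(p): file_checksum(p) for p in (outputs or [])},
    }
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
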