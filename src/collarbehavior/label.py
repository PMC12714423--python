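"""Build labeled 5-min training segments from observations and GPS speeds.

Training data for the behavior classifier are 5-min activity records joined
to a behavior label.  Two label sources are supported:

* direct observation bouts, reduced per record to the modal behavior and its
  time-coverage fraction ("purity"), with a purity filter — full purity for
  the strict rule, >= 0.6 for the relaxed "single behavior for >= 3 of 5 min"
  rule used where sample sizes are small;
* GPS step speeds, where steps at or above a speed threshold (default
  2.5 km/h, e.g. >= 420 m within a 10-min fix interval) mark the activity
  records they fully contain as traveling.

Records whose modal behavior is "other" are never emitted: those behaviors
are brief and excluded from model development.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .encode import INTERVAL_SECONDS, ActivityRecord
from .states import DEFAULT_CATEGORY_TABLE, BehaviorState, as_state

logger = logging.getLogger(__name__)

DEFAULT_SPEED_THRESHOLD_KMH = 2.5


@dataclass(frozen=True)
class ObservationBout:
    """One continuously observed behavior bout for one animal."""

    animal_id: str
    start: pd.Timestamp
    end: pd.Timestamp
    behavior: BehaviorState

    def __post_init__(self) -> None:
        if not self.end > self.start:
            raise ValueError(
                f"bout end must follow start (animal {self.animal_id}: "
                f"{self.start} .. {self.end})"
            )


@dataclass(frozen=True)
class LabeledSegment:
    """An ActivityRecord joined to a behavior label.

    ``purity`` is the fraction of the 5-min interval covered by the modal
    behavior; ``source`` records whether the label came from direct
    observation or was inferred from GPS step speed.
    """

    record: ActivityRecord
    behavior: BehaviorState
    purity: float
    source: str = "observed"

    def __post_init__(self) -> None:
        if not (0.0 < self.purity <= 1.0):
            raise ValueError(f"purity must be in (0, 1], got {self.purity}")
        if self.source not in ("observed", "gps_inferred"):
            raise ValueError(f"unknown label source {self.source!r}")


@dataclass
class GPSTrack:
    """GPS fixes for one animal on a projected plane (meters)."""

    animal_id: str
    times: pd.DatetimeIndex
    xy: np.ndarray  # (n, 2) meters

    def __post_init__(self) -> None:
        self.times = pd.DatetimeIndex(self.times)
        self.xy = np.asarray(self.xy, dtype=float)
        if self.xy.ndim != 2 or self.xy.shape[1] != 2:
            raise ValueError("xy must be an (n, 2) array of planar coordinates")
        if len(self.times) != self.xy.shape[0]:
            raise ValueError("times and xy must have equal length")
        diffs = np.diff(self.times.asi8)
        if np.any(diffs <= 0):
            i = int(np.argmax(diffs <= 0))
            raise ValueError(
                f"GPS timestamps must be strictly increasing (animal "
                f"{self.animal_id}, fix {i + 1} at {self.times[i + 1]})"
            )


def segments_to_frame(segments) -> pd.DataFrame:
    """Tabulate LabeledSegments as the labeled-segment CSV schema."""
    return pd.DataFrame(
        {
            "animal_id": [s.record.animal_id for s in segments],
            "interval_start": [s.record.interval_start for s in segments],
            "act_x": [s.record.act_x for s in segments],
            "act_y": [s.record.act_y for s in segments],
            "act_z": [s.record.act_z for s in segments],
            "behavior": [s.behavior.value for s in segments],
            "purity": [s.purity for s in segments],
            "source": [s.source for s in segments],
        }
    )


def map_raw_behavior(raw_label: str, category_table=None) -> BehaviorState:
    """Map a raw observation label ("ruminating", ...) to a broad state.

    Unknown labels map to ``other`` with a warning rather than failing, since
    field logs routinely contain rare one-off behaviors.
    """
    table = DEFAULT_CATEGORY_TABLE if category_table is None else category_table
    key = str(raw_label).strip().lower()
    if key in table:
        return as_state(table[key])
    try:
        return as_state(key)  # already a broad state name
    except ValueError:
        warnings.warn(
            f"unrecognized behavior label {raw_label!r}; mapping to 'other'",
            stacklevel=2,
        )
        return BehaviorState.OTHER


def _check_non_overlapping(bouts: list[ObservationBout]) -> None:
    by_animal: dict[str, list[ObservationBout]] = {}
    for b in bouts:
        by_animal.setdefault(b.animal_id, []).append(b)
    for animal, bs in by_animal.items():
        bs = sorted(bs, key=lambda b: b.start)
        for prev, nxt in zip(bs, bs[1:]):
            if nxt.start < prev.end:
                raise ValueError(
                    f"overlapping observation bouts for animal {animal}: "
                    f"({prev.start}..{prev.end}, {prev.behavior}) overlaps "
                    f"({nxt.start}..{nxt.end}, {nxt.behavior})"
                )


def segment_labels(
    bouts: list[ObservationBout],
    records: list[ActivityRecord],
    min_purity: float = 1.0,
) -> list[LabeledSegment]:
    """Label activity records with the modal observed behavior.

    Each record overlapped by observations receives the behavior covering the
    most observed time within its 5-min interval, together with the fraction
    of the interval that behavior covers.  A record is kept iff the modal
    behavior is not ``other`` and the purity reaches ``min_purity``
    (1.0 = strict single-behavior rule; 0.6 = the >=3-of-5-min rule).
    Records with no observation coverage are dropped.
    """
    if not (0.5 < min_purity <= 1.0):
        raise ValueError(f"min_purity must be in (0.5, 1], got {min_purity}")
    _check_non_overlapping(bouts)
    interval = pd.Timedelta(seconds=INTERVAL_SECONDS)
    out: list[LabeledSegment] = []
    for rec in records:
        r0 = rec.interval_start
        r1 = r0 + interval
        coverage: dict[BehaviorState, float] = {}
        for b in bouts:
            if b.animal_id != rec.animal_id:
                continue
            lo = max(b.start, r0)
            hi = min(b.end, r1)
            if hi > lo:
                coverage[b.behavior] = (
                    coverage.get(b.behavior, 0.0) + (hi - lo).total_seconds()
                )
        if not coverage:
            continue
        # deterministic modal choice: most seconds, ties by state name
        modal = max(coverage, key=lambda s: (coverage[s], s.value))
        purity = coverage[modal] / INTERVAL_SECONDS
        if modal is BehaviorState.OTHER or purity < min_purity:
            continue
        out.append(LabeledSegment(record=rec, behavior=modal, purity=purity))
    return out


def step_speeds_kmh(track: GPSTrack) -> np.ndarray:
    """Planar step speed (km/h) between sequential fixes; length n_fixes - 1."""
    dist_m = np.linalg.norm(np.diff(track.xy, axis=0), axis=1)
    dt_h = np.diff(track.times.asi8) / 1e9 / 3600.0
    return dist_m / 1000.0 / dt_h


def label_travel_from_gps(
    track: GPSTrack,
    records: list[ActivityRecord],
    speed_threshold: float = DEFAULT_SPEED_THRESHOLD_KMH,
) -> list[LabeledSegment]:
    """Label activity records as traveling from fast GPS steps.

    A step whose speed is at or above ``speed_threshold`` km/h (inclusive)
    marks every 5-min record fully contained between its two fixes as
    traveling with purity 1.0 and source ``gps_inferred``.  Partially
    overlapped records are left unlabeled (strict containment, conservative
    against label noise).
    """
    if speed_threshold <= 0:
        raise ValueError("speed_threshold must be positive")
    speeds = step_speeds_kmh(track)
    fast = np.flatnonzero(speeds >= speed_threshold)
    interval = pd.Timedelta(seconds=INTERVAL_SECONDS)
    out: list[LabeledSegment] = []
    for rec in records:
        if rec.animal_id != track.animal_id:
            continue
        r0, r1 = rec.interval_start, rec.interval_start + interval
        for i in fast:
            if track.times[i] <= r0 and r1 <= track.times[i + 1]:
                out.append(
                    LabeledSegment(
                        record=rec,
                        behavior=BehaviorState.TRAVELING,
                        purity=1.0,
                        source="gps_inferred",
                    )
                )
                break
    return out


def cross_species_support(segments: list[LabeledSegment], model) -> float:
    """Fraction of segments whose asserted label a trained model reproduces.

    The plausibility check for GPS-inferred labels: predict each segment's
    activity triplet with a model trained on another species and return the
    fraction of predictions agreeing with the asserted label.
    """
    if not segments:
        raise ValueError("no segments to check")
    X = np.array([s.record.triplet() for s in segments])
    preds = model.predict(X)
    asserted = np.array([s.behavior.value for s in segments])
    return float(np.mean(preds == asserted))
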