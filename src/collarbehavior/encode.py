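"""Activity-value encoding: raw triaxial acceleration to 8-bit activity data.

Vectronic Vertex collars in "Activity Mode 1" store, per axis, one 8-bit
activity value (0–255) per 5-min interval.  On-collar the value is the mean
absolute first difference of a down-sampled acceleration series, expressed in
units of 0.16 m/s² (equivalently 0.016 g), multiplied by 10, rounded to the
nearest whole number and truncated at 255.  This module re-implements that
computation bit-exactly, stage by stage:

* Vertex Plus samples at 128 Hz; each second is reduced to 32 block means of
  4 consecutive readings, of which the 1st, 9th, 17th and 25th are retained
  (4 retained readings per second).
* Vertex Lite samples at 64 Hz; a single reading per second is retained (the
  first of each second by this package's convention — the vendor does not
  document which).
* The retained readings in each 5-min window are differenced, absolute values
  averaged, and the average quantized to an integer in [0, 255].

The elementwise conversion from a mean absolute first difference to the 8-bit
scale is exposed separately as :func:`first_diff_to_activity` for users whose
collars export raw acceleration instead of activity values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Quantization unit: one activity count is 0.1 of this, per declared unit.
QUANT_UNIT = {"m/s2": 0.16, "g": 0.016}

#: Aliases accepted for the unit argument.
_UNIT_ALIASES = {
    "g": "g",
    "m/s2": "m/s2",
    "m/s^2": "m/s2",
    "m/s²": "m/s2",
    "ms2": "m/s2",
}

SUPPORTED_RATES = (64, 128)
INTERVAL_SECONDS = 300


def _canonical_unit(unit: str) -> str:
    try:
        return _UNIT_ALIASES[str(unit).strip().lower()]
    except KeyError:
        raise ValueError(
            f"unknown unit {unit!r}; allowed units are 'g' and 'm/s2'"
        ) from None


def round_half_away(x):
    """Round to nearest integer, halves away from zero.

    Centralized so that numpy's banker's rounding can never leak into the
    quantizer.  Inputs here are non-negative, but the rule is implemented
    symmetrically for safety.
    """
    x = np.asarray(x, dtype=float)
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


@dataclass
class RawAccelStream:
    """Timestamped triaxial acceleration for one animal at a fixed rate.

    ``samples`` is an (n, 3) array of (ax, ay, az) in the declared ``unit``
    ("g" or "m/s2"); ``rate`` is 64 or 128 samples per second.
    """

    animal_id: str
    t0: pd.Timestamp
    rate: int
    samples: np.ndarray
    unit: str

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2 or self.samples.shape[1] != 3:
            raise ValueError("samples must be an (n, 3) array of (ax, ay, az)")
        if self.rate not in SUPPORTED_RATES:
            raise ValueError(
                f"unsupported sampling rate {self.rate}; expected one of {SUPPORTED_RATES}"
            )
        self.unit = _canonical_unit(self.unit)
        self.t0 = pd.Timestamp(self.t0)

    @property
    def duration_seconds(self) -> int:
        return self.samples.shape[0] // self.rate


@dataclass(frozen=True)
class ActivityRecord:
    """One 5-min interval's 8-bit (X, Y, Z) activity triplet."""

    animal_id: str
    interval_start: pd.Timestamp
    act_x: int
    act_y: int
    act_z: int

    def __post_init__(self) -> None:
        for v in (self.act_x, self.act_y, self.act_z):
            if not (0 <= int(v) <= 255):
                raise ValueError(f"activity value {v} outside [0, 255]")

    def triplet(self) -> tuple[int, int, int]:
        return (self.act_x, self.act_y, self.act_z)


def records_to_frame(records) -> pd.DataFrame:
    """Tabulate ActivityRecords as a DataFrame."""
    return pd.DataFrame(
        {
            "animal_id": [r.animal_id for r in records],
            "interval_start": [r.interval_start for r in records],
            "act_x": [r.act_x for r in records],
            "act_y": [r.act_y for r in records],
            "act_z": [r.act_z for r in records],
        }
    )


def downsample_plus(samples_1s: np.ndarray) -> np.ndarray:
    """Reduce one second of 128 Hz readings (one axis) to 4 retained readings.

    The 128 readings are averaged in blocks of 4 into 32 values; block means
    1, 9, 17 and 25 (1-based) are retained — i.e. the means of raw readings
    1–4, 33–36, 65–68 and 97–100.
    """
    samples_1s = np.asarray(samples_1s, dtype=float)
    if samples_1s.shape[0] != 128:
        raise ValueError(f"expected exactly 128 readings, got {samples_1s.shape[0]}")
    block_means = samples_1s.reshape(32, 4).mean(axis=1)
    return block_means[[0, 8, 16, 24]]


def select_lite(samples_1s: np.ndarray) -> float:
    """Reduce one second of 64 Hz readings (one axis) to 1 retained reading.

    The vendor retains a single reading per second without documenting which;
    this package takes the first reading of the second, consistent with the
    128 Hz path retaining the leading block of each stride.
    """
    samples_1s = np.asarray(samples_1s, dtype=float)
    if samples_1s.shape[0] != 64:
        raise ValueError(f"expected exactly 64 readings, got {samples_1s.shape[0]}")
    return float(samples_1s[0])


def _retained_readings(axis_samples: np.ndarray, rate: int) -> np.ndarray:
    """Retained per-second readings for a whole window of one axis."""
    n_seconds = axis_samples.shape[0] // rate
    per_second = axis_samples[: n_seconds * rate].reshape(n_seconds, rate)
    if rate == 128:
        block_means = per_second.reshape(n_seconds, 32, 4).mean(axis=2)
        return block_means[:, [0, 8, 16, 24]].reshape(-1)
    if rate == 64:
        return per_second[:, 0]
    raise ValueError(f"unsupported sampling rate {rate}")


def mean_abs_first_diff(retained: np.ndarray) -> float:
    """Mean absolute difference between sequential retained readings."""
    retained = np.asarray(retained, dtype=float)
    if retained.shape[0] < 2:
        raise ValueError("need at least 2 retained readings to difference")
    return float(np.mean(np.abs(np.diff(retained))))


def quantize_activity(d: float, unit: str, *, strict_si: bool = False) -> int:
    """Quantize a mean absolute first difference to the 8-bit activity scale.

    ``a = min(255, round(10 * d / u))`` with ``u = 0.16`` for m/s² input and
    ``u = 0.016`` for g input (the vendor's stated equivalence, implying
    g ≈ 10 m/s²).  With ``strict_si=True``, g input is first converted to
    m/s² through the standard constant 9.80665 and quantized with u = 0.16.
    """
    d = float(d)
    if d < 0:
        raise ValueError(f"mean absolute first difference must be >= 0, got {d}")
    unit = _canonical_unit(unit)
    if strict_si and unit == "g":
        d = d * 9.80665
        unit = "m/s2"
    a = round_half_away(10.0 * d / QUANT_UNIT[unit])
    return int(min(255, a))


def first_diff_to_activity(values, unit: str, *, strict_si: bool = False) -> np.ndarray:
    """Elementwise conversion of mean-abs-first-diff values to 8-bit activity.

    Mirrors the published conversion helper: accepts a scalar or vector of
    non-negative first-difference averages plus the unit they were measured
    in ("g" or "m/s2") and returns the corresponding integer activity values.
    """
    unit = _canonical_unit(unit)
    arr = np.atleast_1d(np.asarray(values, dtype=float))
    if np.any(arr < 0):
        bad = np.flatnonzero(arr < 0)
        raise ValueError(f"negative first-difference values at positions {bad.tolist()}")
    return np.array(
        [quantize_activity(v, unit, strict_si=strict_si) for v in arr], dtype=int
    )


def encode_activity_mode1(
    stream: RawAccelStream, *, strict_si: bool = False
) -> list[ActivityRecord]:
    """Encode a raw stream into per-5-min 8-bit activity records.

    Per axis and per complete 5-min window (aligned to the stream start):
    down-sample/select, difference, average, quantize.  First differences do
    not cross window boundaries.  An incomplete trailing window is dropped
    with a log message.
    """
    n_per_interval = stream.rate * INTERVAL_SECONDS
    n_intervals = stream.samples.shape[0] // n_per_interval
    if n_intervals == 0:
        raise ValueError(
            "stream shorter than one complete 5-min interval "
            f"({stream.samples.shape[0]} samples at {stream.rate} Hz)"
        )
    leftover = stream.samples.shape[0] - n_intervals * n_per_interval
    if leftover:
        logger.info(
            "dropping incomplete trailing interval of %d samples for %s",
            leftover,
            stream.animal_id,
        )
    records = []
    for i in range(n_intervals):
        chunk = stream.samples[i * n_per_interval : (i + 1) * n_per_interval]
        acts = []
        for axis in range(3):
            retained = _retained_readings(chunk[:, axis], stream.rate)
            d = mean_abs_first_diff(retained)
            acts.append(quantize_activity(d, stream.unit, strict_si=strict_si))
        records.append(
            ActivityRecord(
                animal_id=stream.animal_id,
                interval_start=stream.t0 + pd.Timedelta(seconds=i * INTERVAL_SECONDS),
                act_x=acts[0],
                act_y=acts[1],
                act_z=acts[2],
            )
        )
    return records
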