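"""Synthetic collared-ungulate data with the structure the pipeline assumes.

Generates, per simulated animal:

* a first-order Markov behavior sequence at 1-min resolution over the states
  stationary / foraging / traveling / other ("other" as brief interruptions);
* a raw triaxial acceleration stream (gravity offset + state-dependent
  sinusoid + Gaussian noise) at 64 or 128 Hz, so the on-collar encoder has
  realistic input;
* 5-min activity records drawn directly from per-state negative-binomial
  emissions on the 0–255 scale, clipped at 255 (a discretized-Gaussian
  alternative is available);
* a planar GPS track whose step lengths are gamma and turning angles
  wrapped-Cauchy, state-dependent — the generative structure the movement
  HMM assumes;
* ground-truth labeled segments and observation bouts for end-to-end tests.

Everything is driven by a single integer seed; two runs with the same config
produce identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .encode import INTERVAL_SECONDS, ActivityRecord, RawAccelStream
from .label import GPSTrack, LabeledSegment, ObservationBout
from .states import BehaviorState

#: Fixed state order for transition matrices and per-state parameter arrays.
SIM_STATES: tuple[BehaviorState, ...] = (
    BehaviorState.STATIONARY,
    BehaviorState.FORAGING,
    BehaviorState.TRAVELING,
    BehaviorState.OTHER,
)

_DEFAULT_T0 = pd.Timestamp("2022-06-01 00:00:00")


@dataclass
class SimConfig:
    """All knobs of the simulator; the defaults are the package's reference
    study conditions.

    Per-state parameter maps are keyed by BehaviorState.  Activity emission
    means live on the 0–255 scale; ``activity_dispersion`` is the
    negative-binomial size parameter (smaller = more overdispersed), or the
    Gaussian sd when ``activity_family="gaussian"``.  Gait parameters are
    (amplitude g, frequency Hz, noise sd g) for the raw-signal sinusoid.
    Movement parameters are gamma (mean, sd) step lengths in meters per fix
    interval and wrapped-Cauchy (location, concentration) turning angles.
    """

    n_animals: int = 10
    duration_hours: float = 12.0
    seed: int = 0
    sampling_rate: int = 128
    fix_interval: int = 600  # seconds
    # rows/cols ordered as SIM_STATES; 1-min resolution
    behavior_transition_matrix: np.ndarray = field(
        default_factory=lambda: np.array(
            [
                [0.90, 0.06, 0.02, 0.02],
                [0.06, 0.90, 0.02, 0.02],
                [0.05, 0.05, 0.88, 0.02],
                [0.40, 0.35, 0.15, 0.10],
            ]
        )
    )
    initial_state_probs: np.ndarray = field(
        default_factory=lambda: np.array([0.4, 0.4, 0.15, 0.05])
    )
    activity_means: dict = field(
        default_factory=lambda: {
            BehaviorState.STATIONARY: (4.0, 3.0, 5.0),
            BehaviorState.FORAGING: (45.0, 40.0, 35.0),
            BehaviorState.TRAVELING: (130.0, 120.0, 110.0),
            BehaviorState.OTHER: (20.0, 20.0, 20.0),
        }
    )
    activity_dispersion: dict = field(
        default_factory=lambda: {
            BehaviorState.STATIONARY: 1.0,
            BehaviorState.FORAGING: 2.0,
            BehaviorState.TRAVELING: 3.0,
            BehaviorState.OTHER: 1.0,
        }
    )
    activity_family: str = "negative_binomial"  # or "gaussian"
    gait_params: dict = field(
        default_factory=lambda: {
            BehaviorState.STATIONARY: (0.01, 0.4, 0.005),
            BehaviorState.FORAGING: (0.12, 1.1, 0.02),
            BehaviorState.TRAVELING: (0.45, 2.3, 0.05),
            BehaviorState.OTHER: (0.06, 0.9, 0.02),
        }
    )
    step_params: dict = field(
        default_factory=lambda: {  # gamma (mean, sd) meters per fix interval
            BehaviorState.STATIONARY: (8.0, 6.0),
            BehaviorState.FORAGING: (60.0, 40.0),
            BehaviorState.TRAVELING: (600.0, 250.0),
            BehaviorState.OTHER: (30.0, 20.0),
        }
    )
    angle_params: dict = field(
        default_factory=lambda: {  # wrapped-Cauchy (location, concentration)
            BehaviorState.STATIONARY: (0.0, 0.0),
            BehaviorState.FORAGING: (0.0, 0.3),
            BehaviorState.TRAVELING: (0.0, 0.85),
            BehaviorState.OTHER: (0.0, 0.1),
        }
    )
    t0: pd.Timestamp = _DEFAULT_T0

    def __post_init__(self) -> None:
        self.behavior_transition_matrix = np.asarray(
            self.behavior_transition_matrix, dtype=float
        )
        self.initial_state_probs = np.asarray(self.initial_state_probs, dtype=float)
        self.validate()

    def validate(self) -> None:
        P = self.behavior_transition_matrix
        if P.shape != (4, 4):
            raise ValueError("behavior_transition_matrix must be 4x4")
        if np.any(P < 0):
            raise ValueError("transition probabilities must be non-negative")
        sums = P.sum(axis=1)
        for i, s in enumerate(sums):
            if abs(s - 1.0) > 1e-12:
                raise ValueError(
                    f"transition matrix row {i} ({SIM_STATES[i].value}) sums to "
                    f"{s!r}, not 1"
                )
        if abs(self.initial_state_probs.sum() - 1.0) > 1e-12:
            raise ValueError("initial_state_probs must sum to 1")
        if self.sampling_rate not in (64, 128):
            raise ValueError("sampling_rate must be 64 or 128")
        if self.activity_family not in ("negative_binomial", "gaussian"):
            raise ValueError(
                "activity_family must be 'negative_binomial' or 'gaussian'"
            )
        for state, means in self.activity_means.items():
            for m in means:
                if not (0 <= m <= 255):
                    raise ValueError(
                        f"activity emission mean {m} for {state} outside [0, 255]"
                    )
        for state, (mean, sd) in self.step_params.items():
            if mean <= 0 or sd <= 0:
                raise ValueError(f"gamma step params for {state} must be positive")
        for state, (_, rho) in self.angle_params.items():
            if not (0.0 <= rho < 1.0):
                raise ValueError(
                    f"wrapped-Cauchy concentration for {state} must be in [0, 1), "
                    f"got {rho}"
                )

    @property
    def n_minutes(self) -> int:
        return int(round(self.duration_hours * 60))


@dataclass
class SimAnimal:
    """One simulated animal's complete data bundle."""

    animal_id: str
    behavior_track: list  # BehaviorState per minute
    raw_stream: RawAccelStream | None
    records: list  # ActivityRecord per 5-min interval
    gps_track: GPSTrack
    truth_segments: list  # LabeledSegment with simulated truth labels
    bouts: list  # ObservationBout merged from the behavior track


def simulate_behavior_sequence(config: SimConfig, rng) -> list[BehaviorState]:
    """First-order Markov behavior chain at 1-min resolution.

    Element i is the behavior during minute i.  Expected dwell time in state
    s is 1 / (1 - P[s, s]) minutes (geometric run lengths).
    """
    config.validate()
    P = config.behavior_transition_matrix
    n = config.n_minutes
    states = np.empty(n, dtype=int)
    states[0] = rng.choice(4, p=config.initial_state_probs)
    for t in range(1, n):
        states[t] = rng.choice(4, p=P[states[t - 1]])
    return [SIM_STATES[s] for s in states]


def sample_wrapped_cauchy(m: float, rho: float, size: int, rng) -> np.ndarray:
    """Sample wrapped-Cauchy angles in (-pi, pi].

    Uses the wrapping construction: a Cauchy variate with scale -ln(rho)
    wrapped to the circle has concentration rho; rho=0 is circular uniform.
    """
    if not (0.0 <= rho < 1.0):
        raise ValueError(f"concentration must be in [0, 1), got {rho}")
    if rho == 0.0:
        raw = rng.uniform(-np.pi, np.pi, size=size)
    else:
        gamma = -np.log(rho)
        raw = m + gamma * rng.standard_cauchy(size=size)
    return wrap_angle(raw)


def wrap_angle(theta) -> np.ndarray:
    """Wrap angles to (-pi, pi]."""
    theta = np.asarray(theta, dtype=float)
    wrapped = -((-theta + np.pi) % (2.0 * np.pi) - np.pi)
    return wrapped


def simulate_raw_stream(
    behavior_track: list,
    config: SimConfig,
    rng,
    animal_id: str = "sim",
) -> RawAccelStream:
    """Raw triaxial acceleration for a behavior track.

    Each axis is a gravity offset plus a state-dependent sinusoid (amplitude,
    frequency from the state's gait parameters, fixed per-axis phases) plus
    white Gaussian noise.  Higher-activity states yield larger encoded
    activity values.
    """
    if not behavior_track:
        raise ValueError("behavior_track must be non-empty")
    rate = config.sampling_rate
    if rate not in (64, 128):
        raise ValueError("sampling_rate must be 64 or 128")
    n_min = len(behavior_track)
    n_samples = n_min * 60 * rate
    t = np.arange(n_samples) / rate
    amp = np.empty(n_samples)
    freq = np.empty(n_samples)
    noise_sd = np.empty(n_samples)
    for i, state in enumerate(behavior_track):
        a, f, sd = config.gait_params[state]
        sl = slice(i * 60 * rate, (i + 1) * 60 * rate)
        amp[sl], freq[sl], noise_sd[sl] = a, f, sd
    gravity = np.array([0.0, 0.0, 1.0])
    phases = np.array([0.0, 2.0 * np.pi / 3.0, 4.0 * np.pi / 3.0])
    samples = np.empty((n_samples, 3))
    for axis in range(3):
        signal = gravity[axis] + amp * np.sin(2.0 * np.pi * freq * t + phases[axis])
        if np.any(noise_sd > 0):
            signal = signal + rng.normal(0.0, 1.0, size=n_samples) * noise_sd
        samples[:, axis] = signal
    return RawAccelStream(
        animal_id=animal_id, t0=config.t0, rate=rate, samples=samples, unit="g"
    )


def _modal_state(chunk: list) -> tuple[BehaviorState, float]:
    """Modal behavior of a list of per-minute states and its coverage fraction."""
    counts: dict[BehaviorState, int] = {}
    for s in chunk:
        counts[s] = counts.get(s, 0) + 1
    modal = max(counts, key=lambda s: (counts[s], s.value))
    return modal, counts[modal] / len(chunk)


def simulate_activity_records(
    behavior_track: list,
    config: SimConfig,
    rng,
    animal_id: str = "sim",
) -> tuple[list[ActivityRecord], list[LabeledSegment]]:
    """Draw per-5-min activity triplets from per-state emissions.

    The behavior of each 5-min interval is the modal per-minute state; the
    (X, Y, Z) triplet is drawn from that state's emission — by default a
    negative binomial with the configured mean and size, clipped at 255
    (matching the convention of simulating 8-bit activity data by truncating
    an overdispersed count distribution); alternatively a rounded Gaussian
    clipped to [0, 255].

    Returns the records together with ground-truth LabeledSegments carrying
    the modal state and its purity (including "other"-modal segments, which
    the labeling stage is responsible for rejecting).
    """
    config.validate()
    n_int = len(behavior_track) // 5
    if n_int == 0:
        raise ValueError("behavior_track shorter than one 5-min interval")
    records: list[ActivityRecord] = []
    truths: list[LabeledSegment] = []
    for i in range(n_int):
        chunk = behavior_track[i * 5 : (i + 1) * 5]
        modal, purity = _modal_state(chunk)
        means = np.asarray(config.activity_means[modal], dtype=float)
        disp = float(config.activity_dispersion[modal])
        vals = np.empty(3, dtype=int)
        for axis in range(3):
            mu = means[axis]
            if config.activity_family == "negative_binomial":
                if mu == 0 or disp == 0:
                    v = 0 if mu == 0 else int(round(mu))
                else:
                    p = disp / (disp + mu)
                    v = int(rng.negative_binomial(disp, p))
            else:
                v = int(np.round(rng.normal(mu, disp))) if disp > 0 else int(round(mu))
            vals[axis] = min(255, max(0, v))
        rec = ActivityRecord(
            animal_id=animal_id,
            interval_start=config.t0 + pd.Timedelta(seconds=i * INTERVAL_SECONDS),
            act_x=int(vals[0]),
            act_y=int(vals[1]),
            act_z=int(vals[2]),
        )
        records.append(rec)
        truths.append(LabeledSegment(record=rec, behavior=modal, purity=purity))
    return records, truths


def simulate_gps_track(
    behavior_track: list,
    config: SimConfig,
    rng,
    animal_id: str = "sim",
) -> GPSTrack:
    """Planar GPS track with state-dependent gamma steps and wrapped-Cauchy turns.

    One step per fix interval; the state of a step is the modal per-minute
    behavior over the interval.  Positions are cumulative: the heading turns
    by a wrapped-Cauchy angle each step and advances by a gamma step length.
    """
    config.validate()
    fix_min = config.fix_interval // 60
    if config.fix_interval % 60 != 0:
        raise ValueError("fix_interval must be a whole number of minutes")
    n_steps = len(behavior_track) // fix_min
    if n_steps < 1:
        raise ValueError("behavior_track shorter than one fix interval")
    heading = rng.uniform(-np.pi, np.pi)
    pos = np.zeros(2)
    xy = [pos.copy()]
    for k in range(n_steps):
        chunk = behavior_track[k * fix_min : (k + 1) * fix_min]
        state, _ = _modal_state(chunk)
        mean, sd = config.step_params[state]
        shape = (mean / sd) ** 2
        scale = sd**2 / mean
        step = rng.gamma(shape, scale)
        m, rho = config.angle_params[state]
        turn = sample_wrapped_cauchy(m, rho, 1, rng)[0]
        heading = wrap_angle(heading + turn)
        pos = pos + step * np.array([np.cos(heading), np.sin(heading)])
        xy.append(pos.copy())
    times = pd.DatetimeIndex(
        [config.t0 + pd.Timedelta(seconds=k * config.fix_interval) for k in range(n_steps + 1)]
    )
    return GPSTrack(animal_id=animal_id, times=times, xy=np.array(xy))


def bouts_from_track(
    behavior_track: list, t0: pd.Timestamp, animal_id: str
) -> list[ObservationBout]:
    """Merge consecutive identical per-minute states into observation bouts."""
    bouts: list[ObservationBout] = []
    start = 0
    for i in range(1, len(behavior_track) + 1):
        if i == len(behavior_track) or behavior_track[i] is not behavior_track[start]:
            bouts.append(
                ObservationBout(
                    animal_id=animal_id,
                    start=t0 + pd.Timedelta(minutes=start),
                    end=t0 + pd.Timedelta(minutes=i),
                    behavior=behavior_track[start],
                )
            )
            start = i
    return bouts


def simulate_animal(
    config: SimConfig,
    rng,
    animal_id: str,
    include_raw: bool = False,
) -> SimAnimal:
    """Simulate one animal's behavior track, records, GPS track and truth.

    Raw streams are bulky (minutes x 60 x rate x 3 floats) and only needed by
    encoder tests, so they are off by default.
    """
    track = simulate_behavior_sequence(config, rng)
    raw = (
        simulate_raw_stream(track, config, rng, animal_id=animal_id)
        if include_raw
        else None
    )
    records, truths = simulate_activity_records(track, config, rng, animal_id=animal_id)
    gps = simulate_gps_track(track, config, rng, animal_id=animal_id)
    bouts = bouts_from_track(track, config.t0, animal_id)
    return SimAnimal(
        animal_id=animal_id,
        behavior_track=track,
        raw_stream=raw,
        records=records,
        gps_track=gps,
        truth_segments=truths,
        bouts=bouts,
    )


def simulate_dataset(config: SimConfig, include_raw: bool = False) -> list[SimAnimal]:
    """Simulate the configured number of animals, deterministically from
    ``config.seed`` (one spawned child generator per animal)."""
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(config.n_animals)
    animals = []
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        animals.append(
            simulate_animal(config, rng, animal_id=f"sim{i:03d}", include_raw=include_raw)
        )
    return animals


def training_segments(animals: list[SimAnimal], min_purity: float = 1.0) -> list:
    """Ground-truth segments usable for training: non-"other" modal behavior
    at or above the purity threshold."""
    out = []
    for a in animals:
        for s in a.truth_segments:
            if s.behavior is not BehaviorState.OTHER and s.purity >= min_purity:
                out.append(s)
    return out
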