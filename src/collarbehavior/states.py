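"""Behavioral state vocabulary shared across the package.

Collared ungulate behavior is reduced to three broad states — ``stationary``
(lying, standing, ruminating), ``foraging`` (grazing, browsing, feeding from
troughs) and ``traveling`` (walking, running) — plus an ``other`` bucket for
brief behaviors (grooming, alert, drinking, ...) that is used by observation
logs and the simulator but never emitted by the classifier.
"""

from __future__ import annotations

from enum import Enum


class BehaviorState(str, Enum):
    """One of the four behavior labels used throughout the pipeline."""

    STATIONARY = "stationary"
    FORAGING = "foraging"
    TRAVELING = "traveling"
    OTHER = "other"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: The three states a classifier may emit, in the fixed (alphabetical) order
#: used for deterministic vote tie-breaking.
CLASSIFIER_STATES: tuple[BehaviorState, ...] = (
    BehaviorState.FORAGING,
    BehaviorState.STATIONARY,
    BehaviorState.TRAVELING,
)

#: Default mapping from raw field-observation labels to broad states.
DEFAULT_CATEGORY_TABLE: dict[str, BehaviorState] = {
    # stationary
    "lying": BehaviorState.STATIONARY,
    "standing": BehaviorState.STATIONARY,
    "ruminating": BehaviorState.STATIONARY,
    # foraging
    "grazing": BehaviorState.FORAGING,
    "browsing": BehaviorState.FORAGING,
    "feeding from troughs": BehaviorState.FORAGING,
    "trough feeding": BehaviorState.FORAGING,
    # traveling
    "walking": BehaviorState.TRAVELING,
    "running": BehaviorState.TRAVELING,
    # other (short-duration behaviors excluded from training)
    "alert": BehaviorState.OTHER,
    "coughing": BehaviorState.OTHER,
    "defecating": BehaviorState.OTHER,
    "digging": BehaviorState.OTHER,
    "drinking": BehaviorState.OTHER,
    "grooming": BehaviorState.OTHER,
    "jumping": BehaviorState.OTHER,
    "shaking": BehaviorState.OTHER,
    "social": BehaviorState.OTHER,
    "swimming": BehaviorState.OTHER,
    "urinating": BehaviorState.OTHER,
}


def as_state(value) -> BehaviorState:
    """Coerce a string or BehaviorState to a BehaviorState."""
    if isinstance(value, BehaviorState):
        return value
    try:
        return BehaviorState(str(value).strip().lower())
    except ValueError as exc:
        raise ValueError(
            f"unknown behavior state {value!r}; expected one of "
            f"{[s.value for s in BehaviorState]}"
        ) from exc
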