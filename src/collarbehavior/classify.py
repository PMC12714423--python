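"""Class-balanced random-forest behavior classifier.

Behavior observation data are strongly imbalanced (captive animals rarely
travel), so each tree in the forest is grown on a balanced bootstrap: for
every tree, an equal number of segments is drawn with replacement from each
behavior class, that number being the size of the smallest class.  An odd
number of trees (default 1001) is used so binary majority votes cannot tie;
residual three-way ties are broken deterministically toward the first class
in the fixed alphabetical order (foraging, stationary, traveling).  Each
split considers ``mtry = floor(sqrt(3)) = 1`` random feature of the three
activity axes, the classical default.  Individual trees are CART trees
(gini impurity, unlimited depth, minimum node size 1); the balanced-bootstrap
ensemble, vote aggregation and out-of-bag bookkeeping are implemented here.

``predict_behaviors`` appends a ``behavior`` column to a user's activity
table, either from a model object or from one of the packaged species-tagged
models.  The packaged models are trained on this package's own synthetic
reference data — clearly tagged as such — since the field training data are
an external deposit; retraining on real labeled segments uses the same
``train_balanced_forest`` entry point.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import joblib
import numpy as np
import pandas as pd
from sklearn.tree import DecisionTreeClassifier


MODEL_FORMAT_VERSION = "1"

SPECIES_TAGS = ("mule deer", "bighorn sheep", "moose", "ungulate")

#: Deterministic seeds for the packaged synthetic species models.
_SPECIES_SEEDS = {"mule deer": 101, "bighorn sheep": 102, "moose": 103, "ungulate": 104}

_species_cache: dict[str, "BehaviorModel"] = {}


@dataclass
class BehaviorModel:
    """A trained balanced-bootstrap forest plus its metadata.

    ``classes`` is the fixed alphabetical class order used for vote
    tie-breaking; ``train_summary`` records per-class sample sizes, the
    per-class bootstrap size (the smallest class count), forest settings and
    the out-of-bag error.
    """

    trees: list
    classes: list
    species_tag: str = "custom"
    train_summary: dict = field(default_factory=dict)
    version: str = MODEL_FORMAT_VERSION

    def vote_counts(self, X) -> np.ndarray:
        """Per-class vote counts over all trees; shape (n, n_classes)."""
        X = _validate_activity_matrix(X)
        counts = np.zeros((X.shape[0], len(self.classes)), dtype=int)
        rows = np.arange(X.shape[0])
        for tree in self.trees:
            counts[rows, tree.predict(X).astype(int)] += 1
        return counts

    def predict_scores(self, X) -> np.ndarray:
        """Vote fractions per class (rows sum to 1)."""
        counts = self.vote_counts(X)
        return counts / counts.sum(axis=1, keepdims=True)

    def predict(self, X) -> np.ndarray:
        """Majority-vote class labels; ties go to the first class in order."""
        counts = self.vote_counts(X)
        return np.asarray(self.classes, dtype=object)[np.argmax(counts, axis=1)]


def _validate_activity_matrix(X) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != 3:
        raise ValueError("expected an (n, 3) matrix of (act_x, act_y, act_z)")
    bad = np.flatnonzero(
        np.any((X < 0) | (X > 255) | (X != np.round(X)), axis=1)
    )
    if bad.size:
        raise ValueError(
            f"activity values must be integers in [0, 255]; offending rows: "
            f"{bad[:20].tolist()}"
        )
    return X


def segments_to_xy(segments) -> tuple[np.ndarray, np.ndarray]:
    """(X, y) arrays from a sequence of LabeledSegments."""
    X = np.array([s.record.triplet() for s in segments], dtype=float)
    y = np.array([s.behavior.value for s in segments], dtype=object)
    return X, y


def train_balanced_forest(
    X,
    y,
    n_trees: int = 1001,
    mtry: int | None = None,
    seed: int = 0,
    species_tag: str = "custom",
) -> BehaviorModel:
    """Grow a balanced-bootstrap classification forest.

    Parameters
    ----------
    X, y
        (n, 3) integer activity triplets and behavior labels (strings or
        BehaviorStates).  A sequence of LabeledSegments may be passed as X
        with ``y=None``.
    n_trees
        Number of trees; must be odd so binary votes cannot tie.
    mtry
        Features tried per split; defaults to floor(sqrt(3)) = 1.
    seed
        Seeds both the per-tree bootstraps and tree growing.
    """
    if y is None:
        X, y = segments_to_xy(X)
    if n_trees % 2 == 0:
        raise ValueError(
            f"n_trees must be odd to avoid tied majority votes, got {n_trees}"
        )
    if mtry is None:
        mtry = int(math.floor(math.sqrt(3)))
    X = _validate_activity_matrix(X)
    y = np.asarray([str(v) for v in y], dtype=object)
    classes = sorted(np.unique(y).tolist())
    if len(classes) < 2:
        raise ValueError("training data must contain at least 2 behavior classes")
    y_idx = np.searchsorted(classes, y)
    class_indices = [np.flatnonzero(y_idx == k) for k in range(len(classes))]
    counts = {c: len(idx) for c, idx in zip(classes, class_indices)}
    for c, n_c in counts.items():
        if n_c < 2:
            raise ValueError(f"class {c!r} has only {n_c} segment(s); need >= 2")
    sampsize = min(counts.values())

    rng = np.random.default_rng(seed)
    n = X.shape[0]
    trees = []
    oob_votes = np.zeros((n, len(classes)), dtype=int)
    in_bag_class_draws = np.zeros(len(classes), dtype=int)
    rows = np.arange(n)
    for _ in range(n_trees):
        boot = np.concatenate(
            [rng.choice(idx, size=sampsize, replace=True) for idx in class_indices]
        )
        for k in range(len(classes)):
            in_bag_class_draws[k] += np.sum(y_idx[boot] == k)
        tree = DecisionTreeClassifier(
            criterion="gini",
            max_features=mtry,
            random_state=int(rng.integers(2**31)),
        )
        tree.fit(X[boot], y_idx[boot])
        trees.append(tree)
        oob_mask = np.ones(n, dtype=bool)
        oob_mask[boot] = False
        if oob_mask.any():
            preds = tree.predict(X[oob_mask]).astype(int)
            oob_votes[rows[oob_mask], preds] += 1

    voted = oob_votes.sum(axis=1) > 0
    oob_pred = np.argmax(oob_votes, axis=1)
    oob_error = (
        float(np.mean(oob_pred[voted] != y_idx[voted])) if voted.any() else float("nan")
    )
    oob_confusion = np.zeros((len(classes), len(classes)), dtype=int)
    for t, p in zip(y_idx[voted], oob_pred[voted]):
        oob_confusion[t, p] += 1

    summary = {
        "per_class_n": counts,
        "per_class_bootstrap_size": sampsize,
        "n_trees": n_trees,
        "mtry": mtry,
        "seed": seed,
        "oob_error": oob_error,
        "oob_confusion": oob_confusion,
        "in_bag_class_draws": dict(zip(classes, in_bag_class_draws.tolist())),
    }
    return BehaviorModel(
        trees=trees, classes=classes, species_tag=species_tag, train_summary=summary
    )


def save_model(model: BehaviorModel, path) -> None:
    """Persist a model as a self-describing archive."""
    payload = {
        "format_version": model.version,
        "classes": model.classes,
        "species_tag": model.species_tag,
        "train_summary": model.train_summary,
        "trees": model.trees,
    }
    joblib.dump(payload, path)


def load_model(path) -> BehaviorModel:
    """Load a model saved by :func:`save_model`; rejects corrupt or
    incompatible files."""
    try:
        payload = joblib.load(path)
    except Exception as exc:
        raise ValueError(f"could not read model file {path}: {exc}") from exc
    if not isinstance(payload, dict) or "format_version" not in payload:
        raise ValueError(f"{path} is not a behavior-model archive")
    if payload["format_version"] != MODEL_FORMAT_VERSION:
        raise ValueError(
            f"model format {payload['format_version']!r} does not match this "
            f"package's format {MODEL_FORMAT_VERSION!r}; retrain or convert the "
            "model with the matching package version"
        )
    return BehaviorModel(
        trees=payload["trees"],
        classes=payload["classes"],
        species_tag=payload["species_tag"],
        train_summary=payload["train_summary"],
        version=payload["format_version"],
    )


def species_model(tag: str) -> BehaviorModel:
    """Packaged classifier for a species tag.

    These models are trained at first use on this package's synthetic
    reference data (deterministic per-species seeds) and are stand-ins for
    field-trained models: they demonstrate the full pipeline and are tagged
    ``synthetic:<species>``.  Training on real labeled segments goes through
    :func:`train_balanced_forest`.
    """
    key = str(tag).strip().lower()
    if key not in SPECIES_TAGS:
        raise ValueError(
            f"unknown species {tag!r}; valid species are {list(SPECIES_TAGS)}"
        )
    if key not in _species_cache:
        from .simulate import SimConfig, simulate_dataset, training_segments

        config = SimConfig(
            n_animals=6, duration_hours=8.0, seed=_SPECIES_SEEDS[key]
        )
        animals = simulate_dataset(config)
        segments = training_segments(animals, min_purity=1.0)
        X, y = segments_to_xy(segments)
        _species_cache[key] = train_balanced_forest(
            X, y, n_trees=1001, seed=_SPECIES_SEEDS[key],
            species_tag=f"synthetic:{key}",
        )
    return _species_cache[key]


def predict_behaviors(
    frame: pd.DataFrame,
    model_or_species,
    x: str = "act_x",
    y: str = "act_y",
    z: str = "act_z",
) -> pd.DataFrame:
    """Append a ``behavior`` column of majority-vote states to a table.

    ``model_or_species`` is a BehaviorModel or one of the species tags.
    All input columns and row order are preserved.
    """
    for col in (x, y, z):
        if col not in frame.columns:
            raise ValueError(
                f"column {col!r} not in table; available columns: "
                f"{list(frame.columns)}"
            )
    model = (
        model_or_species
        if isinstance(model_or_species, BehaviorModel)
        else species_model(model_or_species)
    )
    X = frame[[x, y, z]].to_numpy()
    out = frame.copy()
    out["behavior"] = model.predict(X)
    return out
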