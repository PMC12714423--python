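"""Model evaluation: grouped leave-one-out cross-validation and metrics.

Validation treats the individual animal as the sampling unit: each fold
trains on all other animals and predicts the held-out animal's segments, so
within-individual correlation can never leak between train and test.
Metrics follow the standard suite for this kind of classifier:

* overall accuracy (per animal and pooled);
* the Hand-and-Till multiclass AUC ``M``: the average over all class pairs
  (i, j) of the symmetric pairwise ranking probability
  ``A(i, j) = (A(i|j) + A(j|i)) / 2``, computed from per-class scores (here
  the forest's vote fractions), with ties counted 1/2;
* out-of-bag error of the full-data model;
* per-class error rates (row-normalized confusion-matrix complement).

Per-animal metrics are aggregated as means and medians, by default over
animals contributing at least ``n_min = 30`` segments.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .classify import train_balanced_forest

logger = logging.getLogger(__name__)


def hand_till_auc(y_true, scores, classes=None) -> float:
    """Multiclass AUC by the Hand-and-Till pairwise construction.

    Parameters
    ----------
    y_true
        Length-n class labels.
    scores
        (n, c) per-class scores (e.g. forest vote fractions); column order
        matches ``classes`` (default: sorted unique labels).

    Returns ``M = 2 / (c (c-1)) * sum_{i<j} A(i, j)`` where ``A(i|j)`` is the
    probability that a random class-i item outranks a random class-j item on
    the class-i score, ties counting 1/2.  Classes absent from ``y_true`` are
    excluded from the average with a warning.
    """
    y_true = np.asarray([str(v) for v in y_true], dtype=object)
    scores = np.asarray(scores, dtype=float)
    if classes is None:
        classes = sorted(np.unique(y_true).tolist())
    classes = [str(c) for c in classes]
    if scores.shape != (y_true.shape[0], len(classes)):
        raise ValueError(
            f"scores must be (n, {len(classes)}); got {scores.shape}"
        )
    present = [c for c in classes if np.any(y_true == c)]
    if len(present) < 2:
        raise ValueError("need at least 2 classes present to compute AUC")
    if len(present) < len(classes):
        warnings.warn(
            f"classes with no instances excluded from AUC: "
            f"{sorted(set(classes) - set(present))}",
            stacklevel=2,
        )
    total = 0.0
    n_pairs = 0
    for a in range(len(present)):
        for b in range(a + 1, len(present)):
            ci, cj = present[a], present[b]
            total += (
                _a_given(y_true, scores, classes, ci, cj)
                + _a_given(y_true, scores, classes, cj, ci)
            ) / 2.0
            n_pairs += 1
    return total / n_pairs


def _a_given(y_true, scores, classes, ci, cj) -> float:
    """A(i|j): rank probability of class i over class j on the class-i score."""
    col = classes.index(ci)
    mask = (y_true == ci) | (y_true == cj)
    s = scores[mask, col]
    is_i = y_true[mask] == ci
    n_i = int(is_i.sum())
    n_j = int((~is_i).sum())
    ranks = rankdata(s)  # average ranks give ties weight 1/2
    sum_ranks_i = ranks[is_i].sum()
    u = sum_ranks_i - n_i * (n_i + 1) / 2.0
    return u / (n_i * n_j)


def confusion_matrix(y_true, y_pred, classes) -> np.ndarray:
    """Row = true class, column = predicted class, in ``classes`` order."""
    y_true = np.asarray([str(v) for v in y_true], dtype=object)
    y_pred = np.asarray([str(v) for v in y_pred], dtype=object)
    k = len(classes)
    cm = np.zeros((k, k), dtype=int)
    index = {c: i for i, c in enumerate(classes)}
    for t, p in zip(y_true, y_pred):
        cm[index[t], index[p]] += 1
    return cm


def class_error_rates(cm) -> np.ndarray:
    """Per-class error ``1 - correct_k / total_k`` from a confusion matrix.

    Classes with zero instances get NaN (flagged, never silently 0).
    """
    cm = np.asarray(cm, dtype=float)
    if cm.ndim != 2 or cm.shape[0] != cm.shape[1]:
        raise ValueError("confusion matrix must be square")
    totals = cm.sum(axis=1)
    errors = np.full(cm.shape[0], np.nan)
    for k in range(cm.shape[0]):
        if totals[k] == 0:
            warnings.warn(f"class {k} has zero instances; error undefined", stacklevel=2)
        else:
            errors[k] = 1.0 - cm[k, k] / totals[k]
    return errors


def mean_class_error(class_errors) -> tuple[float, tuple[float, float]]:
    """Arithmetic mean and (min, max) range of a collection of per-class
    error cells, e.g. the per-model, per-class errors of a report table."""
    arr = np.asarray(class_errors, dtype=float).ravel()
    arr = arr[~np.isnan(arr)]
    if arr.size == 0:
        raise ValueError("no class-error values supplied")
    return float(arr.mean()), (float(arr.min()), float(arr.max()))


@dataclass
class EvalReport:
    """Grouped-LOOCV evaluation results."""

    classes: list
    per_animal: pd.DataFrame
    pooled: dict
    aggregates: dict
    confusion: np.ndarray
    skipped_folds: list = field(default_factory=list)
    n_min: int = 30


def _default_train_fn(X, y, *, seed, animal_ids=None, **kwargs):
    return train_balanced_forest(X, y, seed=seed, **kwargs)


def loocv_by_animal(
    segments: pd.DataFrame,
    train_fn=None,
    seed: int = 0,
    n_min: int = 30,
    apply_n_min_to_median: bool = True,
    **train_kwargs,
) -> EvalReport:
    """Leave-one-animal-out cross-validation of the behavior classifier.

    Parameters
    ----------
    segments
        DataFrame with columns animal_id, act_x, act_y, act_z, behavior.
    train_fn
        Callable ``train_fn(X, y, *, seed, animal_ids) -> model`` with
        ``predict`` and ``predict_scores``; defaults to the balanced forest.
    n_min
        Minimum held-out segment count for an animal to enter the mean (and,
        by default, median) aggregates.

    Folds whose training split loses a class are skipped with a warning.
    """
    if train_fn is None:
        train_fn = _default_train_fn
    segments = segments.reset_index(drop=True)
    animals = segments["animal_id"].unique().tolist()
    if len(animals) < 2:
        raise ValueError("grouped LOOCV needs at least 2 animals")
    classes = sorted(segments["behavior"].astype(str).unique().tolist())
    X_all = segments[["act_x", "act_y", "act_z"]].to_numpy()
    y_all = segments["behavior"].astype(str).to_numpy(dtype=object)

    rng = np.random.SeedSequence(seed)
    fold_seeds = [int(s.generate_state(1)[0] % 2**31) for s in rng.spawn(len(animals) + 1)]

    rows = []
    skipped = []
    pooled_true: list = []
    pooled_pred: list = []
    pooled_scores: list = []
    for fold, animal in enumerate(animals):
        held = segments["animal_id"] == animal
        train_classes = set(y_all[~held.to_numpy()])
        if len(train_classes) < len(classes):
            missing = sorted(set(classes) - train_classes)
            logger.warning(
                "skipping fold for animal %s: training split lacks class(es) %s",
                animal,
                missing,
            )
            skipped.append(animal)
            continue
        train_ids = segments.loc[~held, "animal_id"].to_numpy()
        model = train_fn(
            X_all[~held.to_numpy()],
            y_all[~held.to_numpy()],
            seed=fold_seeds[fold],
            animal_ids=train_ids,
            **train_kwargs,
        )
        X_te = X_all[held.to_numpy()]
        y_te = y_all[held.to_numpy()]
        pred = np.asarray([str(v) for v in model.predict(X_te)], dtype=object)
        scores = model.predict_scores(X_te)
        acc = float(np.mean(pred == y_te))
        cm = confusion_matrix(y_te, pred, classes)
        errs = class_error_rates(cm) if np.all(cm.sum(axis=1) > 0) else np.full(
            len(classes), np.nan
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                auc = hand_till_auc(y_te, scores, classes=model.classes)
            except ValueError:
                auc = np.nan
        rows.append(
            {
                "animal_id": animal,
                "n_segments": int(held.sum()),
                "accuracy": acc,
                "auc": auc,
                **{f"error_{c}": errs[i] for i, c in enumerate(classes)},
            }
        )
        pooled_true.append(y_te)
        pooled_pred.append(pred)
        pooled_scores.append(scores)

    if not rows:
        raise ValueError("all folds were skipped; cannot evaluate")
    per_animal = pd.DataFrame(rows)

    y_pool = np.concatenate(pooled_true)
    p_pool = np.concatenate(pooled_pred)
    s_pool = np.vstack(pooled_scores)
    cm_pool = confusion_matrix(y_pool, p_pool, classes)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        pooled_auc = hand_till_auc(y_pool, s_pool, classes=classes)

    # full-data model: OOB error and the train-vs-test overfitting gap
    full_model = train_fn(
        X_all, y_all, seed=fold_seeds[-1],
        animal_ids=segments["animal_id"].to_numpy(), **train_kwargs
    )
    train_acc = float(np.mean(
        np.asarray([str(v) for v in full_model.predict(X_all)], dtype=object) == y_all
    ))
    oob = (
        full_model.train_summary.get("oob_error")
        if hasattr(full_model, "train_summary")
        else None
    )
    pooled_acc = float(np.mean(p_pool == y_pool))
    pooled = {
        "n_segments": int(len(y_pool)),
        "accuracy": pooled_acc,
        "auc_pooled_scores": float(pooled_auc),
        "auc_mean_per_animal": float(np.nanmean(per_animal["auc"])),
        "oob_error": oob,
        "class_errors": dict(zip(classes, class_error_rates(cm_pool))),
        "training_accuracy": train_acc,
        "testing_accuracy": pooled_acc,
        "overfitting_gap": train_acc - pooled_acc,
    }

    metric_cols = [c for c in per_animal.columns if c not in ("animal_id", "n_segments")]
    eligible = per_animal[per_animal["n_segments"] >= n_min]
    median_base = eligible if apply_n_min_to_median else per_animal
    aggregates = {
        "n_animals_total": len(per_animal),
        "n_animals_eligible": len(eligible),
        "mean": {c: float(np.nanmean(eligible[c])) if len(eligible) else np.nan
                 for c in metric_cols},
        "median": {c: float(np.nanmedian(median_base[c])) if len(median_base) else np.nan
                   for c in metric_cols},
    }
    return EvalReport(
        classes=classes,
        per_animal=per_animal,
        pooled=pooled,
        aggregates=aggregates,
        confusion=cm_pool,
        skipped_folds=skipped,
        n_min=n_min,
    )
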