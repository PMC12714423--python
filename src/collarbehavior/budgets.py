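"""Activity budgets and paired comparisons between classification methods.

An activity budget is the proportion of time an animal spends in each
behavioral state over a window — computed equally from 5-min classifier
labels or from hourly Viterbi decodings.  Budgets from two methods are
compared per state with classical paired t-tests across animals
(df = n - 1), reporting mean differences in percentage points.  Because
every budget sums to 1, the three per-state mean differences always sum
to 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


#: Reporting order of the three classifier states within a budget.
BUDGET_STATES = ("stationary", "foraging", "traveling")


@dataclass
class ActivityBudget:
    """Proportion of time in each behavioral state for one animal/window."""

    animal_id: str
    proportions: dict
    method: str = "rf_5min"
    window: tuple | None = None

    def __post_init__(self) -> None:
        total = sum(self.proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"budget proportions sum to {total}, not 1")
        for state, p in self.proportions.items():
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"proportion for {state} out of [0, 1]: {p}")

    def as_vector(self) -> np.ndarray:
        return np.array([self.proportions.get(s, 0.0) for s in BUDGET_STATES])


def budget_from_labels(
    labels, animal_id: str = "", method: str = "rf_5min", window=None
) -> ActivityBudget:
    """Budget from a sequence of state labels on a uniform time grid."""
    labels = [str(v) for v in labels]
    if not labels:
        raise ValueError("cannot compute a budget from an empty label sequence")
    n = len(labels)
    proportions = {s: labels.count(s) / n for s in BUDGET_STATES}
    leftover = 1.0 - sum(proportions.values())
    if leftover > 1e-9:
        raise ValueError(
            "labels outside the three classifier states: "
            f"{sorted(set(labels) - set(BUDGET_STATES))}"
        )
    return ActivityBudget(
        animal_id=animal_id, proportions=proportions, method=method, window=window
    )


@dataclass
class PairedTestResult:
    """Paired t-test of one state's budget proportions between two methods."""

    state: str
    n: int
    mean_difference: float  # proportion scale, method A minus method B
    t: float | None
    df: int
    p: float | None

    @property
    def mean_difference_points(self) -> float:
        """Mean difference in percentage points."""
        return 100.0 * self.mean_difference


def paired_budget_test(a: np.ndarray, b: np.ndarray, state: str = "") -> PairedTestResult:
    """Classical paired t-test on per-animal differences ``a - b``.

    With zero-variance differences the t statistic is undefined and reported
    as None (never +-inf).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired samples must be equal-length vectors")
    n = a.shape[0]
    if n < 2:
        raise ValueError("paired t-test needs at least 2 pairs")
    d = a - b
    mean_d = float(d.mean())
    sd_d = float(d.std(ddof=1))
    df = n - 1
    if sd_d == 0.0:
        return PairedTestResult(state=state, n=n, mean_difference=mean_d,
                                t=None, df=df, p=None)
    t = mean_d / (sd_d / np.sqrt(n))
    from scipy.stats import t as t_dist

    p = 2.0 * t_dist.sf(abs(t), df)
    return PairedTestResult(
        state=state, n=n, mean_difference=mean_d, t=float(t), df=df, p=float(p)
    )


def _budget_matrix(budgets: list, animals: list) -> np.ndarray:
    by_id = {b.animal_id: b for b in budgets}
    return np.array([by_id[a].as_vector() for a in animals])


def compare_methods_report(
    budgets_a: list, budgets_b: list, label_a: str = "rf_5min",
    label_b: str = "hmm_hourly", alpha: float = 0.001
) -> pd.DataFrame:
    """Per-state paired comparison of two sets of matched budgets.

    Budgets must cover the same animals (matched windows); the report has one
    row per state with the mean difference (``a - b``) in percentage points,
    the t statistic, df, p, and a significance flag at ``alpha``.
    """
    ids_a = sorted(b.animal_id for b in budgets_a)
    ids_b = sorted(b.animal_id for b in budgets_b)
    if ids_a != ids_b:
        unmatched = sorted(set(ids_a) ^ set(ids_b))
        raise ValueError(f"budgets cover different animals; unmatched: {unmatched}")
    if len(set(ids_a)) != len(ids_a):
        raise ValueError("duplicate animal ids in budgets")
    animals = ids_a
    A = _budget_matrix(budgets_a, animals)
    B = _budget_matrix(budgets_b, animals)
    rows = []
    for i, state in enumerate(BUDGET_STATES):
        res = paired_budget_test(A[:, i], B[:, i], state=state)
        rows.append(
            {
                "state": state,
                "n_animals": res.n,
                "mean_difference_points": res.mean_difference_points,
                "t": res.t,
                "df": res.df,
                "p": res.p,
                "significant": (res.p is not None and res.p < alpha),
                "method_a": label_a,
                "method_b": label_b,
            }
        )
    return pd.DataFrame(rows)


def select_window(
    times: pd.DatetimeIndex, weeks: int = 2, seed: int = 0
) -> tuple[pd.Timestamp, pd.Timestamp]:
    """Seeded random contiguous window (default 2 weeks) within a time span."""
    times = pd.DatetimeIndex(times)
    span = pd.Timedelta(weeks=weeks)
    t0, t1 = times.min(), times.max()
    latest_start = t1 - span
    if latest_start <= t0:
        return t0, t1
    rng = np.random.default_rng(seed)
    offset_s = rng.uniform(0, (latest_start - t0).total_seconds())
    start = t0 + pd.Timedelta(seconds=float(offset_s))
    return start, start + span
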