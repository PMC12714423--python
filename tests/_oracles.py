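"""Independent brute-force reference implementations used as test oracles.

These are deliberately naive, single-pass re-derivations of the quantities
the package computes with staged/optimized code; they share no code with the
implementation they check.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def brute_force_encode(samples: np.ndarray, rate: int, unit: str) -> list[tuple]:
    """Single-pass reference encoder: raw (n, 3) samples -> activity triplets.

    Walks the stream literally: per 5-min window and axis, collect the
    retained readings second by second, average absolute sequential
    differences, scale by 10/u and round half away from zero, truncate 255.
    """
    u = 0.016 if unit == "g" else 0.16
    n_per_interval = rate * 300
    out = []
    n_windows = samples.shape[0] // n_per_interval
    for w in range(n_windows):
        triplet = []
        for axis in range(3):
            retained = []
            for sec in range(300):
                start = w * n_per_interval + sec * rate
                second = samples[start : start + rate, axis]
                if rate == 128:
                    means = [float(np.mean(second[i * 4 : i * 4 + 4])) for i in range(32)]
                    retained.extend([means[0], means[8], means[16], means[24]])
                else:
                    retained.append(float(second[0]))
            diffs = [abs(retained[i + 1] - retained[i]) for i in range(len(retained) - 1)]
            d = sum(diffs) / len(diffs)
            a = math.floor(10.0 * d / u + 0.5)
            triplet.append(min(255, int(a)))
        out.append(tuple(triplet))
    return out


def brute_force_hand_till(y_true, scores, classes) -> float:
    """Hand-and-Till M by exhaustive pair counting over item pairs."""
    y_true = [str(v) for v in y_true]
    classes = [str(c) for c in classes]
    present = [c for c in classes if c in y_true]
    pair_values = []
    for ci, cj in itertools.combinations(present, 2):
        items_i = [k for k, y in enumerate(y_true) if y == ci]
        items_j = [k for k, y in enumerate(y_true) if y == cj]

        def a_given(c_top, top_items, bottom_items):
            col = classes.index(c_top)
            wins = 0.0
            for a in top_items:
                for b in bottom_items:
                    if scores[a][col] > scores[b][col]:
                        wins += 1.0
                    elif scores[a][col] == scores[b][col]:
                        wins += 0.5
            return wins / (len(top_items) * len(bottom_items))

        pair_values.append(
            (a_given(ci, items_i, items_j) + a_given(cj, items_j, items_i)) / 2.0
        )
    return sum(pair_values) / len(pair_values)


def brute_force_forward(obs: dict, spec) -> float:
    """HMM likelihood by exhaustive summation over all state paths (small T)."""
    from collarbehavior.hmm import _as_obs_matrix, _emission_logprobs

    o = _as_obs_matrix(obs, spec.streams)
    logB = _emission_logprobs(o, spec)
    T = logB.shape[0]
    total = 0.0
    for path in itertools.product(range(3), repeat=T):
        p = spec.delta[path[0]] * math.exp(logB[0, path[0]])
        for t in range(1, T):
            p *= spec.tmat[path[t - 1], path[t]] * math.exp(logB[t, path[t]])
        total += p
    return math.log(total)


def brute_force_viterbi(obs: dict, spec) -> tuple:
    """Most probable path by exhaustive enumeration; ties -> lexicographically
    smallest path (equivalent to lower-state-index tie-breaking)."""
    from collarbehavior.hmm import _as_obs_matrix, _emission_logprobs

    o = _as_obs_matrix(obs, spec.streams)
    logB = _emission_logprobs(o, spec)
    T = logB.shape[0]
    best_path, best_lp = None, -math.inf
    with np.errstate(divide="ignore"):
        log_tmat = np.log(spec.tmat)
        log_delta = np.log(spec.delta)
    for path in itertools.product(range(3), repeat=T):
        lp = log_delta[path[0]] + logB[0, path[0]]
        for t in range(1, T):
            lp += log_tmat[path[t - 1], path[t]] + logB[t, path[t]]
        if lp > best_lp:
            best_lp, best_path = lp, path
    return best_path


def brute_force_steps_angles(xy: np.ndarray):
    """Step lengths and turning angles via literal atan2 bookkeeping."""
    steps, headings = [], []
    for i in range(len(xy) - 1):
        dx = xy[i + 1][0] - xy[i][0]
        dy = xy[i + 1][1] - xy[i][1]
        steps.append(math.hypot(dx, dy))
        headings.append(math.atan2(dy, dx))
    angles = [float("nan")]
    for i in range(1, len(headings)):
        a = headings[i] - headings[i - 1]
        while a <= -math.pi:
            a += 2 * math.pi
        while a > math.pi:
            a -= 2 * math.pi
        angles.append(a)
    return steps, angles


def paired_t_closed_form(a, b):
    """Textbook paired t statistic: mean(d) / (sd(d)/sqrt(n)), sd with n-1."""
    d = [x - y for x, y in zip(a, b)]
    n = len(d)
    mean = sum(d) / n
    var = sum((x - mean) ** 2 for x in d) / (n - 1)
    return mean / math.sqrt(var / n), n - 1
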