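"""Three-state hidden Markov movement model, written from first principles.

The model classifies GPS movement into stationary / foraging / traveling
states from step lengths and turning angles, optionally augmented with
hourly-averaged activity values:

* step length: gamma, parameterized by (mean, sd) at the interface and
  converted to (shape, scale) internally;
* turning angle: wrapped-Cauchy with location m and concentration
  rho in [0, 1) (rho = 0 is circular uniform); m is fixed at 0 by default
  and can be estimated;
* each activity axis: gamma.

Streams are conditionally independent given the state.  The likelihood is a
scaled forward recursion; missing values (the undefined first turning angle,
gap boundaries) contribute likelihood 1.  Fitting maximizes the likelihood
numerically on unconstrained transformed parameters (log for positive
parameters, logit for rho, multinomial logit for transition rows and the
initial distribution) with a quasi-Newton optimizer and multiple random
restarts; the best converged restart is reported with its AIC
(``-2 loglik + 2 k``).  Decoding uses the Viterbi dynamic program.

The forward and Viterbi inner loops are JIT-compiled when numba is
available, with an identical pure-Python fallback.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .label import GPSTrack

logger = logging.getLogger(__name__)

N_STATES = 3
#: Conventional state order for reporting decoded sequences.
STATE_NAMES = ("stationary", "foraging", "traveling")

GAMMA_STREAMS = ("step", "act_x", "act_y", "act_z")


def _maybe_njit(func):
    try:
        from numba import njit

        return njit(cache=False)(func)
    except Exception:  # pragma: no cover - numba present in supported envs
        return func


def wrap_angle(theta):
    """Wrap angles to (-pi, pi]."""
    theta = np.asarray(theta, dtype=float)
    return -((-theta + np.pi) % (2.0 * np.pi) - np.pi)


def steps_and_angles(track: GPSTrack) -> pd.DataFrame:
    """Step lengths (m) and signed turning angles (rad) from a GPS track.

    Step t is the displacement from fix t to fix t+1; the turning angle of
    step t is the signed change in heading from step t-1 (positive =
    left turn), so the first angle is undefined (NaN).
    """
    if len(track.times) < 2:
        raise ValueError("need at least 2 fixes for a step")
    d = np.diff(track.xy, axis=0)
    steps = np.linalg.norm(d, axis=1)
    headings = np.arctan2(d[:, 1], d[:, 0])
    angles = np.full(len(steps), np.nan)
    if len(steps) >= 2:
        angles[1:] = wrap_angle(np.diff(headings))
    return pd.DataFrame(
        {"time": track.times[:-1], "step": steps, "angle": angles}
    )


def wrapped_cauchy_pdf(theta, m: float, rho: float):
    """Wrapped-Cauchy density on (-pi, pi].

    ``f(theta) = (1 / 2 pi) (1 - rho^2) / (1 + rho^2 - 2 rho cos(theta - m))``
    """
    if not (0.0 <= rho < 1.0):
        raise ValueError(f"concentration must be in [0, 1), got {rho}")
    theta = np.asarray(theta, dtype=float)
    return (
        (1.0 - rho**2)
        / (2.0 * np.pi * (1.0 + rho**2 - 2.0 * rho * np.cos(theta - m)))
    )


@dataclass
class HmmSpec:
    """Parameters of the 3-state movement HMM.

    ``emissions`` maps each stream name to its per-state parameter arrays:
    gamma streams ("step", "act_x/y/z") carry ``mean`` and ``sd`` length-3
    arrays; "angle" carries ``mean`` (locations) and ``rho``
    (concentrations).  ``tmat`` is the 3x3 row-stochastic transition matrix,
    ``delta`` the initial state distribution.
    """

    streams: tuple
    emissions: dict
    tmat: np.ndarray
    delta: np.ndarray
    estimate_angle_mean: bool = False

    def __post_init__(self) -> None:
        self.streams = tuple(self.streams)
        self.tmat = np.asarray(self.tmat, dtype=float)
        self.delta = np.asarray(self.delta, dtype=float)
        self.validate()

    def validate(self) -> None:
        if not self.streams:
            raise ValueError("spec needs at least one observation stream")
        for s in self.streams:
            if s not in GAMMA_STREAMS and s != "angle":
                raise ValueError(f"unknown stream {s!r}")
            if s not in self.emissions:
                raise ValueError(f"missing emission parameters for stream {s!r}")
        if self.tmat.shape != (N_STATES, N_STATES) or np.any(self.tmat < 0):
            raise ValueError("tmat must be a non-negative 3x3 matrix")
        if np.max(np.abs(self.tmat.sum(axis=1) - 1.0)) > 1e-9:
            raise ValueError("tmat rows must sum to 1")
        if self.delta.shape != (N_STATES,) or abs(self.delta.sum() - 1.0) > 1e-9:
            raise ValueError("delta must be a length-3 distribution")
        for s in self.streams:
            p = self.emissions[s]
            if s == "angle":
                rho = np.asarray(p["rho"], dtype=float)
                if np.any(rho < 0) or np.any(rho >= 1):
                    raise ValueError("angle concentrations must be in [0, 1)")
            else:
                if np.any(np.asarray(p["mean"]) <= 0) or np.any(
                    np.asarray(p["sd"]) <= 0
                ):
                    raise ValueError(f"gamma parameters for {s!r} must be positive")

    @property
    def n_params(self) -> int:
        """Free parameters: 6 transition + 2 initial + estimated emissions."""
        k = 6 + 2
        for s in self.streams:
            if s == "angle":
                k += N_STATES  # rho
                if self.estimate_angle_mean:
                    k += N_STATES
            else:
                k += 2 * N_STATES  # mean, sd
        return k


@dataclass
class HmmFit:
    """A fitted HMM: best-restart parameters, log-likelihood and AIC."""

    spec: HmmSpec
    loglik: float
    n_obs: int
    restarts: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def aic(self) -> float:
        return -2.0 * self.loglik + 2.0 * self.spec.n_params


def _as_obs_matrix(observations, streams) -> dict:
    obs = {}
    length = None
    for s in streams:
        if s not in observations:
            raise ValueError(f"observations lack stream {s!r}")
        arr = np.asarray(observations[s], dtype=float)
        if length is None:
            length = arr.shape[0]
        elif arr.shape[0] != length:
            raise ValueError("observation streams must have equal length")
        obs[s] = arr
    if length == 0:
        raise ValueError("empty observations")
    all_missing = np.ones(length, dtype=bool)
    for arr in obs.values():
        all_missing &= np.isnan(arr)
    if np.any(all_missing):
        raise ValueError(
            f"time steps with every stream missing: "
            f"{np.flatnonzero(all_missing)[:10].tolist()}"
        )
    return obs


def _emission_logprobs(obs: dict, spec: HmmSpec) -> np.ndarray:
    """(T, 3) log emission densities; missing values contribute log 1 = 0."""
    T = next(iter(obs.values())).shape[0]
    logB = np.zeros((T, N_STATES))
    for s in spec.streams:
        x = obs[s]
        present = ~np.isnan(x)
        p = spec.emissions[s]
        for k in range(N_STATES):
            if s == "angle":
                dens = wrapped_cauchy_pdf(
                    x[present], float(np.asarray(p["mean"])[k]),
                    float(np.asarray(p["rho"])[k]),
                )
                logB[present, k] += np.log(dens)
            else:
                mean = float(np.asarray(p["mean"])[k])
                sd = float(np.asarray(p["sd"])[k])
                shape = (mean / sd) ** 2
                scale = sd**2 / mean
                logB[present, k] += stats.gamma.logpdf(
                    x[present], a=shape, scale=scale
                )
    return logB


@_maybe_njit
def _forward_core(B, shifts, tmat, delta):
    """Scaled forward recursion on pre-shifted emission probabilities.

    ``B[t] = exp(logB[t] - shifts[t])``; returns the total log-likelihood.
    """
    T, K = B.shape
    alpha = delta * B[0]
    c = alpha.sum()
    if c <= 0.0:
        return -np.inf
    ll = np.log(c) + shifts[0]
    alpha = alpha / c
    for t in range(1, T):
        new = np.zeros(K)
        for j in range(K):
            acc = 0.0
            for i in range(K):
                acc += alpha[i] * tmat[i, j]
            new[j] = acc * B[t, j]
        c = new.sum()
        if c <= 0.0:
            return -np.inf
        ll += np.log(c) + shifts[t]
        alpha = new / c
    return ll


@_maybe_njit
def _viterbi_core(logB, log_tmat, log_delta):
    T, K = logB.shape
    score = np.empty((T, K))
    back = np.zeros((T, K), dtype=np.int64)
    for k in range(K):
        score[0, k] = log_delta[k] + logB[0, k]
    for t in range(1, T):
        for j in range(K):
            best_i = 0
            best = score[t - 1, 0] + log_tmat[0, j]
            for i in range(1, K):
                v = score[t - 1, i] + log_tmat[i, j]
                if v > best:  # strict: ties stay at the lower state index
                    best = v
                    best_i = i
            score[t, j] = best + logB[t, j]
            back[t, j] = best_i
    path = np.zeros(T, dtype=np.int64)
    best_k = 0
    best_v = score[T - 1, 0]
    for k in range(1, K):
        if score[T - 1, k] > best_v:
            best_v = score[T - 1, k]
            best_k = k
    path[T - 1] = best_k
    for t in range(T - 2, -1, -1):
        path[t] = back[t + 1, path[t + 1]]
    return path


def forward_loglik(observations, spec: HmmSpec) -> float:
    """Log-likelihood of the observation streams under the spec."""
    obs = _as_obs_matrix(observations, spec.streams)
    logB = _emission_logprobs(obs, spec)
    shifts = logB.max(axis=1)
    if np.any(~np.isfinite(shifts)):
        return -np.inf
    B = np.exp(logB - shifts[:, None])
    return float(_forward_core(B, shifts, np.ascontiguousarray(spec.tmat),
                               np.ascontiguousarray(spec.delta)))


def viterbi(observations, fit_or_spec) -> np.ndarray:
    """Most probable joint state path (indices 0..2, STATE_NAMES order).

    Ties are broken toward the lower state index.
    """
    spec = fit_or_spec.spec if isinstance(fit_or_spec, HmmFit) else fit_or_spec
    obs = _as_obs_matrix(observations, spec.streams)
    logB = _emission_logprobs(obs, spec)
    with np.errstate(divide="ignore"):
        log_tmat = np.log(spec.tmat)
        log_delta = np.log(spec.delta)
    return np.asarray(
        _viterbi_core(logB, np.ascontiguousarray(log_tmat), log_delta), dtype=int
    )


# ---------------------------------------------------------------------------
# parameter transforms


def _pack(spec: HmmSpec) -> np.ndarray:
    parts = []
    for i in range(N_STATES):
        row = spec.tmat[i]
        ref = max(row[i], 1e-300)
        parts.extend(np.log(np.maximum(row[j], 1e-300) / ref)
                     for j in range(N_STATES) if j != i)
    d0 = max(spec.delta[0], 1e-300)
    parts.extend(np.log(max(spec.delta[k], 1e-300) / d0) for k in (1, 2))
    for s in spec.streams:
        p = spec.emissions[s]
        if s == "angle":
            rho = np.clip(np.asarray(p["rho"], dtype=float), 1e-10, 1 - 1e-10)
            parts.extend(np.log(rho / (1 - rho)))
            if spec.estimate_angle_mean:
                parts.extend(np.asarray(p["mean"], dtype=float))
        else:
            parts.extend(np.log(np.asarray(p["mean"], dtype=float)))
            parts.extend(np.log(np.asarray(p["sd"], dtype=float)))
    return np.asarray(parts, dtype=float)


def _unpack(theta: np.ndarray, template: HmmSpec) -> HmmSpec:
    pos = 0
    tmat = np.empty((N_STATES, N_STATES))
    for i in range(N_STATES):
        logits = np.zeros(N_STATES)
        for j in range(N_STATES):
            if j != i:
                logits[j] = theta[pos]
                pos += 1
        ex = np.exp(logits - logits.max())
        tmat[i] = ex / ex.sum()
    dl = np.zeros(N_STATES)
    dl[1] = theta[pos]
    dl[2] = theta[pos + 1]
    pos += 2
    ex = np.exp(dl - dl.max())
    delta = ex / ex.sum()
    emissions = {}
    for s in template.streams:
        if s == "angle":
            rho = 1.0 / (1.0 + np.exp(-theta[pos : pos + 3]))
            pos += 3
            if template.estimate_angle_mean:
                mean = wrap_angle(theta[pos : pos + 3])
                pos += 3
            else:
                mean = np.asarray(template.emissions[s]["mean"], dtype=float)
            emissions[s] = {"mean": mean, "rho": rho}
        else:
            mean = np.exp(theta[pos : pos + 3])
            sd = np.exp(theta[pos + 3 : pos + 6])
            pos += 6
            emissions[s] = {"mean": mean, "sd": sd}
    return HmmSpec(
        streams=template.streams,
        emissions=emissions,
        tmat=tmat,
        delta=delta,
        estimate_angle_mean=template.estimate_angle_mean,
    )


def default_start_sampler(rng, observations, template: HmmSpec) -> HmmSpec:
    """Data-driven random starting parameters.

    Gamma stream means start near the 10/50/90% data quantiles (jittered),
    sds at half the mean; angle concentrations uniform on (0.1, 0.9);
    transition matrix diagonal-dominant; initial distribution uniform with
    jitter.
    """
    emissions = {}
    for s in template.streams:
        if s == "angle":
            rho = rng.uniform(0.1, 0.9, size=N_STATES)
            emissions[s] = {
                "mean": np.asarray(template.emissions[s]["mean"], dtype=float),
                "rho": np.sort(rho),
            }
        else:
            x = np.asarray(observations[s], dtype=float)
            x = x[~np.isnan(x)]
            x = x[x > 0]
            if x.size == 0:
                raise ValueError(f"stream {s!r} has no positive observations")
            q = np.quantile(x, [0.1, 0.5, 0.9])
            mean = np.maximum(q * rng.uniform(0.5, 1.5, size=N_STATES), 1e-6)
            emissions[s] = {"mean": mean, "sd": np.maximum(mean / 2.0, 1e-6)}
    diag = rng.uniform(0.7, 0.95)
    tmat = np.full((N_STATES, N_STATES), (1 - diag) / 2.0)
    np.fill_diagonal(tmat, diag)
    delta = rng.dirichlet(np.ones(N_STATES) * 5.0)
    return HmmSpec(
        streams=template.streams,
        emissions=emissions,
        tmat=tmat,
        delta=delta,
        estimate_angle_mean=template.estimate_angle_mean,
    )


def fit_hmm(
    observations,
    spec_template: HmmSpec,
    n_restarts: int = 50,
    start_sampler=None,
    seed: int = 0,
    maxiter: int = 500,
    tol: float = 1e-8,
) -> HmmFit:
    """Maximum-likelihood fit by multi-restart quasi-Newton optimization.

    Each restart draws starting parameters from ``start_sampler`` (default:
    :func:`default_start_sampler`), maximizes the forward log-likelihood on
    unconstrained transformed parameters with L-BFGS-B, and logs its
    endpoint; the best converged restart is returned.
    """
    if n_restarts < 1:
        raise ValueError("n_restarts must be >= 1")
    if start_sampler is None:
        start_sampler = default_start_sampler
    obs = _as_obs_matrix(observations, spec_template.streams)
    n_obs = next(iter(obs.values())).shape[0]
    rng = np.random.default_rng(seed)

    def negloglik(theta):
        try:
            spec = _unpack(theta, spec_template)
        except ValueError:
            return 1e12
        ll = forward_loglik(obs, spec)
        if not np.isfinite(ll):
            return 1e12
        return -ll

    rows = []
    best = None
    for r in range(n_restarts):
        # restart 0 starts from the template itself (so a fit seeded at the
        # truth can only improve on it); later restarts are sampled
        start = spec_template if r == 0 else start_sampler(rng, obs, spec_template)
        theta0 = _pack(start)
        res = optimize.minimize(
            negloglik,
            theta0,
            method="L-BFGS-B",
            options={"maxiter": maxiter, "ftol": tol, "gtol": 1e-6},
        )
        ll = -res.fun if np.isfinite(res.fun) and res.fun < 1e11 else -np.inf
        converged = bool(res.success) and np.isfinite(ll)
        rows.append(
            {
                "restart": r,
                "start_loglik": -negloglik(theta0),
                "loglik": ll,
                "converged": converged,
                "n_iter": int(res.nit),
            }
        )
        if converged and (best is None or ll > best[0]):
            best = (ll, _unpack(res.x, spec_template))
    restarts = pd.DataFrame(rows)
    if best is None:
        raise RuntimeError(
            "no restart converged to a finite likelihood; restart log:\n"
            f"{restarts.to_string(index=False)}"
        )
    return HmmFit(spec=best[1], loglik=float(best[0]), n_obs=n_obs, restarts=restarts)


def simulate_from_spec(spec: HmmSpec, n: int, rng) -> tuple[dict, np.ndarray]:
    """Sample observation streams and the hidden state path from a spec.

    The generative counterpart of the fit: states follow the Markov chain
    (delta, tmat); each stream draws from its state's emission.  The first
    turning angle is missing (NaN), as in data derived from a real track.
    Returns (observations, states).
    """
    spec.validate()
    states = np.empty(n, dtype=int)
    states[0] = rng.choice(N_STATES, p=spec.delta)
    for t in range(1, n):
        states[t] = rng.choice(N_STATES, p=spec.tmat[states[t - 1]])
    obs: dict = {}
    for s in spec.streams:
        p = spec.emissions[s]
        x = np.empty(n)
        for k in range(N_STATES):
            mask = states == k
            m = int(mask.sum())
            if s == "angle":
                rho = float(np.asarray(p["rho"])[k])
                loc = float(np.asarray(p["mean"])[k])
                if rho == 0.0:
                    draws = rng.uniform(-np.pi, np.pi, size=m)
                else:
                    draws = wrap_angle(loc - np.log(rho) * rng.standard_cauchy(size=m))
                x[mask] = draws
            else:
                mean = float(np.asarray(p["mean"])[k])
                sd = float(np.asarray(p["sd"])[k])
                x[mask] = rng.gamma((mean / sd) ** 2, sd**2 / mean, size=m)
        if s == "angle":
            x[0] = np.nan
        obs[s] = x
    return obs, states


def default_spec(streams=("step", "angle"), estimate_angle_mean: bool = False) -> HmmSpec:
    """A generic valid spec usable as a fitting template.

    Emission parameters are placeholder orders of magnitude (short / medium /
    long steps, increasingly directed angles); multi-restart fitting replaces
    them with data-driven starts.
    """
    emissions = {}
    for s in streams:
        if s == "angle":
            emissions[s] = {
                "mean": np.zeros(N_STATES),
                "rho": np.array([0.1, 0.4, 0.8]),
            }
        else:
            emissions[s] = {
                "mean": np.array([10.0, 100.0, 500.0]),
                "sd": np.array([10.0, 80.0, 250.0]),
            }
    tmat = np.full((N_STATES, N_STATES), 0.1)
    np.fill_diagonal(tmat, 0.8)
    return HmmSpec(
        streams=tuple(streams),
        emissions=emissions,
        tmat=tmat,
        delta=np.full(N_STATES, 1.0 / N_STATES),
        estimate_angle_mean=estimate_angle_mean,
    )


def compare_aic(fit_a: HmmFit, fit_b: HmmFit) -> tuple[HmmFit, float]:
    """Select the lower-AIC fit; returns (chosen, delta_aic >= 0).

    Fits must cover the same observations (checked by length).  Exact AIC
    ties go to the model with fewer parameters.
    """
    if fit_a.n_obs != fit_b.n_obs:
        raise ValueError(
            f"fits cover different data spans ({fit_a.n_obs} vs {fit_b.n_obs} "
            "observations); AIC comparison is not meaningful"
        )
    delta = abs(fit_a.aic - fit_b.aic)
    if fit_a.aic < fit_b.aic:
        return fit_a, delta
    if fit_b.aic < fit_a.aic:
        return fit_b, delta
    chosen = fit_a if fit_a.spec.n_params <= fit_b.spec.n_params else fit_b
    return chosen, 0.0


def hourly_activity_means(records: pd.DataFrame, min_records: int = 9) -> pd.DataFrame:
    """Hourly means of 5-min activity triplets.

    Hours with fewer than ``min_records`` of the 12 possible records are
    dropped (partial hours are unreliable covariates).
    """
    df = records.copy()
    df["hour"] = pd.to_datetime(df["interval_start"]).dt.floor("h")
    grouped = df.groupby("hour")[["act_x", "act_y", "act_z"]].agg(["mean", "count"])
    keep = grouped[("act_x", "count")] >= min_records
    out = grouped.loc[keep].xs("mean", axis=1, level=1).reset_index()
    return out


def movement_observations(
    track: GPSTrack, activity: pd.DataFrame | None = None
) -> dict:
    """Observation streams for the HMM from a GPS track.

    Returns a dict with "step" and "angle" arrays (one entry per step), and
    — when an hourly activity table (from :func:`hourly_activity_means`) is
    given — "act_x/y/z" aligned on the hour of each step's starting fix,
    NaN where no hour matches.
    """
    sa = steps_and_angles(track)
    obs = {"step": sa["step"].to_numpy(), "angle": sa["angle"].to_numpy()}
    if activity is not None:
        hours = pd.to_datetime(sa["time"]).dt.floor("h")
        table = activity.set_index("hour")
        for col in ("act_x", "act_y", "act_z"):
            vals = np.full(len(sa), np.nan)
            for i, h in enumerate(hours):
                if h in table.index:
                    vals[i] = table.loc[h, col]
            # gamma emissions need strictly positive support; an all-zero
            # hour is floored rather than dropped
            obs[col] = np.where(vals == 0.0, 0.01, vals)
    return obs
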