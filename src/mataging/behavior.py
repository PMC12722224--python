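"""Foraging-task session metrics and Bernoulli state-space learning curves.

Sessions are 1-s-resolution zone-event logs from a four-feeder foraging
arena.  Probe-trial metrics quantify goal-directed memory (with chance at
25% for first-choice proportional measures and 1.5 for errors-to-correct,
since there are four feeders); the emergence of consistent foraging across
encode sessions is tracked with a latent Gaussian random-walk state observed
through a Bernoulli likelihood, smoothed by an approximate forward
filter / backward smoother with the process variance estimated by EM.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

FEEDER_ZONES = ("feeder_1", "feeder_2", "feeder_3", "feeder_4")
N_FEEDERS = 4


@dataclass
class ZoneEvent:
    zone: str
    t_start_s: float
    t_end_s: float
    distance_cm: float = 0.0


@dataclass
class ForagingSession:
    """One arena session: ordered zone events plus trial metadata."""

    mouse_id: str
    session: int
    trial_type: str  # encode | probe2h | probe24h | habituation | training
    events: list[ZoneEvent] = field(default_factory=list)
    correct_feeder: Optional[str] = None
    outcome: Optional[int] = None  # encode sessions: 1 = consumed a reward

    def sorted_events(self) -> list[ZoneEvent]:
        return sorted(self.events, key=lambda e: (e.t_start_s, e.zone))


@dataclass
class SessionMetrics:
    prop_correct_visits: Optional[float]
    first_visit_correct: Optional[bool]
    errors_to_correct: Optional[int]
    perimeter_proportion: float
    exit_latency_s: Optional[float]
    mean_speed_cm_s: Optional[float]
    n_feeder_visits: int


def session_metrics(session: ForagingSession) -> SessionMetrics:
    """Per-session behavioral metrics from the zone-event log.

    Feeder visits are ordered by entry time; ``errors_to_correct`` counts
    distinct incorrect feeders entered before the first correct entry
    (bounded by 3, giving the 1.5 chance level).  Sessions without a feeder
    visit have their memory metrics flagged missing rather than zero.
    """
    events = session.sorted_events()
    if not events:
        raise ValueError("session has no events")
    t0 = min(e.t_start_s for e in events)
    t1 = max(e.t_end_s for e in events)
    duration = t1 - t0
    if duration <= 0:
        raise ValueError("session has zero duration")

    feeder_visits = [e for e in events if e.zone in FEEDER_ZONES]
    perimeter_time = sum(e.t_end_s - e.t_start_s for e in events if e.zone == "perimeter")

    exit_latency = None
    box = [e for e in events if e.zone == "start_box"]
    if box:
        exit_latency = box[0].t_end_s - t0

    total_distance = sum(e.distance_cm for e in events)
    mean_speed = total_distance / duration if total_distance > 0 else None

    prop_correct = first_correct = errors = None
    if feeder_visits:
        correct = session.correct_feeder
        n_correct = sum(1 for e in feeder_visits if e.zone == correct)
        prop_correct = n_correct / len(feeder_visits)
        first_correct = feeder_visits[0].zone == correct
        seen: set[str] = set()
        errors = None
        for e in feeder_visits:
            if e.zone == correct:
                errors = len(seen)
                break
            seen.add(e.zone)
        # correct feeder never visited: errors stays missing

    return SessionMetrics(
        prop_correct_visits=prop_correct,
        first_visit_correct=first_correct,
        errors_to_correct=errors,
        perimeter_proportion=perimeter_time / duration,
        exit_latency_s=exit_latency,
        mean_speed_cm_s=mean_speed,
        n_feeder_visits=len(feeder_visits),
    )


_NUMERIC_FIELDS = (
    "prop_correct_visits",
    "errors_to_correct",
    "perimeter_proportion",
    "exit_latency_s",
    "mean_speed_cm_s",
    "n_feeder_visits",
)


def delta_24_2(probe24: SessionMetrics, probe2: SessionMetrics) -> dict[str, Optional[float]]:
    """Within-subject 24 h − 2 h difference for every numeric metric.

    A metric missing on either side yields a missing difference.
    """
    out: dict[str, Optional[float]] = {}
    for name in _NUMERIC_FIELDS:
        a, b = getattr(probe24, name), getattr(probe2, name)
        out[name] = None if a is None or b is None else float(a) - float(b)
    return out


# ---------------------------------------------------------------------------
# Bernoulli state-space learning curve
# ---------------------------------------------------------------------------


def _logistic(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


@dataclass
class LearningCurve:
    p: np.ndarray  # smoothed per-trial success probability
    lo90: np.ndarray
    hi90: np.ndarray
    learning_trial: Optional[int]  # 1-based; None if never sustained above chance
    process_variance: float
    x: np.ndarray  # smoothed latent state (logit scale)
    x_var: np.ndarray
    chance: float


def _filter_smooth(
    n: np.ndarray, x0: float, sigma2: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """One forward-filter / backward-smoother pass at fixed process variance.

    Forward step uses a Gaussian approximation to the Bernoulli posterior
    (posterior mode by Newton iteration, curvature as precision); backward
    pass is the fixed-interval (RTS) smoother.
    Returns smoothed means/variances plus the filtered and predicted
    variances needed by the EM update.
    """
    T = len(n)
    xf = np.empty(T)  # filtered mean
    vf = np.empty(T)  # filtered variance
    vp = np.empty(T)  # predicted (one-step) variance
    x_prev, v_prev = x0, 0.0
    for t in range(T):
        x_pred = x_prev
        v_pred = v_prev + sigma2
        vp[t] = v_pred
        # Newton solve: x = x_pred + v_pred * (n_t - logistic(x))
        x = x_pred
        for _ in range(25):
            p = 1.0 / (1.0 + np.exp(-x))
            f = x - x_pred - v_pred * (n[t] - p)
            fp = 1.0 + v_pred * p * (1.0 - p)
            step = f / fp
            x -= step
            if abs(step) < 1e-12:
                break
        p = 1.0 / (1.0 + np.exp(-x))
        xf[t] = x
        vf[t] = 1.0 / (1.0 / v_pred + p * (1.0 - p))
        x_prev, v_prev = x, vf[t]

    xs = np.empty(T)
    vs = np.empty(T)
    xs[-1], vs[-1] = xf[-1], vf[-1]
    A = np.empty(T)  # A[t] couples t and t+1 (defined for t < T-1)
    for t in range(T - 2, -1, -1):
        A[t] = vf[t] / vp[t + 1]
        xs[t] = xf[t] + A[t] * (xs[t + 1] - xf[t])
        vs[t] = vf[t] + A[t] ** 2 * (vs[t + 1] - vp[t + 1])
    return xs, vs, A, vf, vp


def fit_learning_curve(
    outcomes: Sequence[int],
    chance: float = 0.5,
    max_iter: int = 200,
    tol: float = 1e-5,
    max_process_variance: float = 0.02,
) -> LearningCurve:
    """Smoothed Bernoulli learning curve with EM-estimated process variance.

    The latent state follows a Gaussian random walk anchored at
    ``logit(chance)`` before the first trial; per-trial 90% confidence
    bounds come from the smoothed Gaussian mapped through the logistic.
    The learning trial is the first trial whose lower bound exceeds chance
    and stays above chance for every remaining trial (1-based), or ``None``.

    The process variance is constrained to
    ``[1e-6, max_process_variance]``: for degenerate step-like outcome
    sequences the random-walk variance MLE diverges, and the ceiling acts
    as a weakly informative prior that keeps the estimate in the range
    typical of trial-by-trial learning data, where the Gaussian
    approximation to the smoothing distribution is accurate.
    """
    n = np.asarray(outcomes, dtype=float)
    if n.ndim != 1 or len(n) < 5:
        raise ValueError("need at least 5 trials")
    if not np.isin(n, (0.0, 1.0)).all():
        raise ValueError("outcomes must be binary 0/1")
    if not 0.0 < chance < 1.0:
        raise ValueError("chance must lie in (0, 1)")

    x0 = float(np.log(chance / (1.0 - chance)))
    sigma2 = 0.005
    xs = vs = A = None
    for _ in range(max_iter):
        xs, vs, A, vf, vp = _filter_smooth(n, x0, sigma2)
        T = len(n)
        # E[(x_t - x_{t-1})^2 | data], with x_0 fixed at x0
        sq = (xs[0] - x0) ** 2 + vs[0]
        for t in range(1, T):
            cov = A[t - 1] * vs[t]
            sq += vs[t] + vs[t - 1] + (xs[t] - xs[t - 1]) ** 2 - 2.0 * cov
        new_sigma2 = min(max(sq / T, 1e-6), max_process_variance)
        if abs(new_sigma2 - sigma2) / sigma2 < tol:
            sigma2 = new_sigma2
            break
        sigma2 = new_sigma2
    xs, vs, A, vf, vp = _filter_smooth(n, x0, sigma2)

    sd = np.sqrt(vs)
    z90 = 1.6448536269514722  # two-sided 90% normal quantile
    p = _logistic(xs)
    lo = _logistic(xs - z90 * sd)
    hi = _logistic(xs + z90 * sd)

    above = lo > chance
    learning_trial = None
    for t in range(len(n)):
        if above[t:].all():
            learning_trial = t + 1
            break
    return LearningCurve(p, lo, hi, learning_trial, float(sigma2), xs, vs, chance)


def grid_smoother(
    outcomes: Sequence[int],
    chance: float,
    sigma2: float,
    x_range: tuple[float, float] = (-12.0, 12.0),
    n_grid: int = 1201,
) -> np.ndarray:
    """Exact discretized-state smoother for the same model (reference path).

    The latent state is discretized on a fine grid and the smoothed success
    probability computed by HMM forward-backward with a Gaussian transition
    kernel; used as an independent check of the Gaussian-approximation
    smoother at fixed process variance.
    """
    n = np.asarray(outcomes, dtype=float)
    g = np.linspace(*x_range, n_grid)
    x0 = np.log(chance / (1.0 - chance))
    trans = np.exp(-0.5 * (g[None, :] - g[:, None]) ** 2 / sigma2)
    trans /= trans.sum(axis=1, keepdims=True)
    pg = 1.0 / (1.0 + np.exp(-g))
    prior = np.exp(-0.5 * (g - x0) ** 2 / sigma2)
    prior /= prior.sum()

    T = len(n)
    alpha = np.empty((T, n_grid))
    like = np.where(n[:, None] == 1.0, pg[None, :], 1.0 - pg[None, :])
    a = prior * like[0]
    alpha[0] = a / a.sum()
    for t in range(1, T):
        a = (alpha[t - 1] @ trans) * like[t]
        alpha[t] = a / a.sum()
    beta = np.ones(n_grid)
    post = np.empty((T, n_grid))
    post[-1] = alpha[-1]
    for t in range(T - 2, -1, -1):
        beta = trans @ (like[t + 1] * beta)
        beta /= beta.max()
        q = alpha[t] * beta
        post[t] = q / q.sum()
    return post @ pg
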