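"""Mood-model computations: expectation terms, reward prediction errors,
discounted accumulation, predicted mood series, and influence curves.

All members of the model family predict mood at trial t as a baseline plus
beta-weighted, exponentially discounted sums of per-trial regressor streams;
they differ only in how the expectation stream is built (see
:class:`mooddyn.types.ModelSpec`).
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np

from .types import ModelSpec, Session, SubjectParams, TrialRecord

__all__ = [
    "gamma_from_xi",
    "xi_from_gamma",
    "recency_expectation",
    "primacy_expectation",
    "dynamic_win_probability",
    "dynamic_expectation",
    "decayed_window_expectation",
    "compute_rpe",
    "regressor_streams",
    "discounted_sums",
    "predict_mood_at_trials",
    "predict_mood_series",
    "influence_curve",
]


def gamma_from_xi(xi: float) -> float:
    """Logistic map from the unbounded discount parameter to gamma in (0, 1)."""
    if not math.isfinite(xi):
        raise ValueError(f"xi must be finite, got {xi}")
    return 1.0 / (1.0 + math.exp(-xi))


def xi_from_gamma(gamma: float) -> float:
    """Inverse of :func:`gamma_from_xi` (the logit)."""
    if not 0.0 < gamma < 1.0:
        raise ValueError(f"gamma must be in (0, 1), got {gamma}")
    return math.log(gamma / (1.0 - gamma))


def recency_expectation(trial: TrialRecord) -> float:
    """Expected value of the current gamble: the mean of its two values."""
    return 0.5 * (trial.high + trial.low)


def primacy_expectation(outcome_history: Sequence[float], t: int) -> float:
    """Plain average of all outcomes before trial ``t``.

    ``outcome_history`` holds the outcomes of trials 1..t-1 (gamble and
    certain alike).  The first trial has no history and returns 0 by
    convention.
    """
    if t <= 1 or len(outcome_history) == 0:
        return 0.0
    return float(np.mean(np.asarray(outcome_history[: t - 1], dtype=float)))


def dynamic_win_probability(history: Sequence[TrialRecord]) -> float:
    """Shrunken empirical probability of winning the high gamble value.

    Counts prior gambled trials that resolved high, with a Beta-like prior
    of 10 pseudo-observations at success rate 0.5, so an empty history gives
    exactly 0.5 and the value is always strictly inside (0, 1).
    """
    wins = sum(1 for tr in history if tr.won_high)
    gambles = sum(1 for tr in history if tr.chose_gamble)
    return (wins + 5.0) / (gambles + 10.0)


def dynamic_expectation(trial: TrialRecord, p: float) -> float:
    """Gamble expectation under a learned win probability ``p``."""
    return p * trial.high + (1.0 - p) * trial.low


def decayed_window_expectation(
    outcome_history: Sequence[float], decay: float, t_max: int
) -> float:
    """Decay-weighted mean of the most recent outcomes.

    The most recent outcome gets weight ``decay**0``, the one before
    ``decay**1``, and so on, over the last ``min(t_max, len(history))``
    outcomes; weights are normalized to sum to one.  With ``decay == 1`` and
    a window covering the whole history this is exactly
    :func:`primacy_expectation`.
    """
    if not 0.0 < decay <= 1.0:
        raise ValueError(f"decay must be in (0, 1], got {decay}")
    if t_max < 1:
        raise ValueError(f"t_max must be >= 1, got {t_max}")
    if len(outcome_history) == 0:
        return 0.0
    window = np.asarray(outcome_history, dtype=float)[-t_max:][::-1]
    weights = decay ** np.arange(len(window))
    return float(np.sum(weights * window) / np.sum(weights))


def compute_rpe(outcome: float, expectation: float) -> float:
    """Reward prediction error: how much better the outcome was than expected."""
    return outcome - expectation


def _expectation_series(spec: ModelSpec, trials: Sequence[TrialRecord]) -> np.ndarray:
    """E_j for every trial of a session under ``spec``."""
    kind = spec.expectation_kind
    n = len(trials)
    e = np.zeros(n)
    if kind == "gamble_mean":
        for j, tr in enumerate(trials):
            e[j] = recency_expectation(tr)
    elif kind == "dynamic_win":
        for j, tr in enumerate(trials):
            p = dynamic_win_probability(trials[:j])
            e[j] = dynamic_expectation(tr, p)
    elif kind == "previous_outcome":
        for j, tr in enumerate(trials):
            e[j] = trials[j - 1].outcome if j > 0 else 0.0
    elif kind == "outcome_history_mean":
        running = 0.0
        for j, tr in enumerate(trials):
            e[j] = running / j if j > 0 else 0.0
            running += tr.outcome
    elif kind == "decayed_window":
        outcomes = [tr.outcome for tr in trials]
        for j in range(n):
            e[j] = decayed_window_expectation(
                outcomes[:j], spec.decay, spec.t_max
            )
    else:  # pragma: no cover - guarded by ModelSpec validation
        raise ValueError(f"unknown expectation kind {kind!r}")
    return e


def regressor_streams(spec: ModelSpec, session: Session) -> np.ndarray:
    """Per-trial regressor matrix X of shape (n_trials, p).

    Columns follow ``spec.stream_names``: an optional certain stream C
    (the certain amount on trials where it was chosen, zero elsewhere),
    the expectation stream E, and the prediction-error stream R = A - E.
    When the spec distinguishes gamble trials, E and R are zeroed on
    certain-choice trials.
    """
    trials = session.trials
    n = len(trials)
    e = _expectation_series(spec, trials)
    a = np.array([tr.outcome for tr in trials], dtype=float)
    r = a - e
    gambled = np.array([tr.chose_gamble for tr in trials], dtype=bool)
    if spec.distinguish_gamble_trials:
        e = np.where(gambled, e, 0.0)
        r = np.where(gambled, r, 0.0)
    cols = []
    if spec.include_certain_term:
        c = np.array(
            [0.0 if tr.chose_gamble else tr.certain for tr in trials],
            dtype=float,
        )
        cols.append(c)
    cols.extend([e, r])
    return np.column_stack(cols) if n else np.zeros((0, spec.n_streams))


def discounted_sums(x: np.ndarray, gamma: float) -> np.ndarray:
    """Exponentially discounted running sums S_t = gamma * S_{t-1} + X_t.

    ``x`` has shape (n_trials, p); the result has the same shape, with row t
    equal to sum_{j<=t} gamma^(t-j) X_j.
    """
    s = np.zeros_like(x, dtype=float)
    prev = np.zeros(x.shape[1] if x.ndim == 2 else 1)
    for t in range(x.shape[0]):
        prev = gamma * prev + x[t]
        s[t] = prev
    return s


def predict_mood_at_trials(
    spec: ModelSpec,
    params: SubjectParams,
    session: Session,
    trial_indices: Sequence[int],
) -> np.ndarray:
    """Noise-free model mood at arbitrary (1-based) trial indices, unclamped."""
    idx = np.asarray(trial_indices, dtype=int)
    if len(idx) and (idx.min() < 1 or idx.max() > session.n_trials):
        raise ValueError(
            f"trial indices must lie in 1..{session.n_trials}, got "
            f"[{idx.min()}, {idx.max()}]"
        )
    x = regressor_streams(spec, session)
    s = discounted_sums(x, params.gamma)
    betas = np.asarray(params.betas(spec))
    return params.m0 + s[idx - 1] @ betas


def predict_mood_series(
    spec: ModelSpec, params: SubjectParams, session: Session
) -> np.ndarray:
    """Noise-free predicted mood at each rated trial of the session.

    Returns one value per mood rating, in rating order.  Predictions are not
    clamped to the unit scale; generative simulation clamps, fitting does not.
    """
    rated = [obs.after_trial for obs in session.ratings]
    for obs in session.ratings:
        if obs.after_trial > session.n_trials:
            raise ValueError(
                f"rating {obs.rating_index} references trial "
                f"{obs.after_trial} beyond the session"
            )
    return predict_mood_at_trials(spec, params, session, rated)


_RECENCY_KINDS = {"gamble_mean", "dynamic_win"}


def _reference_session(n_trials: int) -> Session:
    """Deterministic all-gamble session used to probe influence curves."""
    trials = [
        TrialRecord(
            index=t,
            high=2.0,
            low=0.0,
            certain=1.0,
            chose_gamble=True,
            outcome=2.0,
        )
        for t in range(1, n_trials + 1)
    ]
    return Session("reference", "random", trials, [])


def influence_curve(
    spec: ModelSpec,
    params: SubjectParams,
    n_trials: int,
    step: float = 1e-4,
) -> np.ndarray:
    """Sensitivity of final-trial mood to a unit perturbation of each trial.

    Computed by central finite differences on a deterministic reference
    session: for history-based expectations (primacy, decayed window,
    previous outcome) the perturbed quantity is the trial's outcome; for
    current-gamble expectations (recency family) the trial's offered values
    and outcome are shifted together, probing the trial's overall value.
    The resulting curve is the model's theoretical weighting of early versus
    recent events.
    """
    if n_trials < 2:
        raise ValueError("n_trials must be >= 2")
    base = _reference_session(n_trials)
    perturb_values = spec.expectation_kind in _RECENCY_KINDS

    def mood_with(i: int, h: float) -> float:
        trials = [
            TrialRecord(
                index=tr.index,
                high=tr.high,
                low=tr.low,
                certain=tr.certain,
                chose_gamble=tr.chose_gamble,
                outcome=tr.outcome,
            )
            for tr in base.trials
        ]
        tr = trials[i - 1]
        tr.outcome += h
        if perturb_values:
            tr.high += h
            tr.low += h
        sess = Session("reference", "random", trials, [])
        return float(
            predict_mood_at_trials(spec, params, sess, [n_trials])[0]
        )

    weights = np.empty(n_trials)
    for i in range(1, n_trials + 1):
        weights[i - 1] = (mood_with(i, step) - mood_with(i, -step)) / (2 * step)
    return weights
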