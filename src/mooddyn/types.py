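"""Core domain types: trials, mood ratings, sessions, model specifications,
and per-subject parameters.

Monetary quantities are kept in raw task points; mood ratings live on the
normalized unit scale [0, 1] (the rating cursor's range mapped to 0..1).
Trial and rating indices are 1-based throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

__all__ = [
    "TrialRecord",
    "MoodObservation",
    "Session",
    "ModelSpec",
    "SubjectParams",
    "PRIMACY",
    "RECENCY",
    "RECENCY_DYNAMIC_WIN",
    "RECENCY_NO_CERTAIN",
    "RECENCY_PREV_OUTCOME",
    "RECENCY_DYNAMIC_NO_CERTAIN",
    "decayed_window_spec",
    "CANONICAL_SPECS",
]

TaskKind = Literal["random", "structured", "structured_adaptive"]

ExpectationKind = Literal[
    "gamble_mean",
    "outcome_history_mean",
    "dynamic_win",
    "previous_outcome",
    "decayed_window",
]

_FLOAT_TOL = 1e-9


@dataclass
class TrialRecord:
    """One gambling trial: the offered values, the choice, and the outcome.

    ``outcome`` is the realized amount A_t: one of the two gamble values when
    the participant gambled, otherwise the certain amount.
    """

    index: int
    high: float
    low: float
    certain: float
    chose_gamble: bool
    outcome: float
    block_id: int = 0
    congruent: bool = True

    def validate(self) -> None:
        if self.high < self.low - _FLOAT_TOL:
            raise ValueError(
                f"trial {self.index}: high ({self.high}) < low ({self.low})"
            )
        if self.chose_gamble:
            if not (
                math.isclose(self.outcome, self.high, abs_tol=_FLOAT_TOL)
                or math.isclose(self.outcome, self.low, abs_tol=_FLOAT_TOL)
            ):
                raise ValueError(
                    f"trial {self.index}: gamble outcome {self.outcome} is "
                    f"neither high ({self.high}) nor low ({self.low})"
                )
        elif not math.isclose(self.outcome, self.certain, abs_tol=_FLOAT_TOL):
            raise ValueError(
                f"trial {self.index}: certain-choice outcome {self.outcome} "
                f"!= certain ({self.certain})"
            )

    @property
    def gamble_mean(self) -> float:
        return 0.5 * (self.high + self.low)

    @property
    def won_high(self) -> bool:
        """Whether a gambled trial resolved to the higher value."""
        return self.chose_gamble and math.isclose(
            self.outcome, self.high, abs_tol=_FLOAT_TOL
        )


@dataclass
class MoodObservation:
    """A sparse momentary mood rating on the unit scale.

    ``after_trial`` is the index of the last trial played before the rating;
    the task design places ratings every 2-3 trials.
    """

    rating_index: int
    after_trial: int
    value: float

    @property
    def is_filled(self) -> bool:
        return not math.isnan(self.value)

    def validate(self, allow_unrated: bool = False) -> None:
        if allow_unrated and not self.is_filled:
            pass
        elif not 0.0 <= self.value <= 1.0:
            raise ValueError(
                f"rating {self.rating_index}: mood {self.value} outside [0, 1]"
            )
        if self.after_trial < 1:
            raise ValueError(
                f"rating {self.rating_index}: after_trial must be >= 1"
            )


@dataclass
class Session:
    """One participant's full task record: ordered trials plus sparse ratings."""

    subject_id: str
    task_kind: TaskKind
    trials: list[TrialRecord] = field(default_factory=list)
    ratings: list[MoodObservation] = field(default_factory=list)

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    @property
    def n_ratings(self) -> int:
        return len(self.ratings)

    def outcomes(self) -> list[float]:
        return [t.outcome for t in self.trials]

    def validate(
        self,
        rating_gaps: Sequence[int] = (2, 3),
        allow_unrated: bool = False,
    ) -> None:
        for i, trial in enumerate(self.trials, start=1):
            if trial.index != i:
                raise ValueError(
                    f"session {self.subject_id}: trial index {trial.index} "
                    f"at position {i} is not consecutive"
                )
            trial.validate()
        prev_after = 0
        for k, obs in enumerate(self.ratings, start=1):
            if obs.rating_index != k:
                raise ValueError(
                    f"session {self.subject_id}: rating index "
                    f"{obs.rating_index} at position {k} is not consecutive"
                )
            obs.validate(allow_unrated=allow_unrated)
            if obs.after_trial > self.n_trials:
                raise ValueError(
                    f"session {self.subject_id}: rating {k} follows trial "
                    f"{obs.after_trial} but session has {self.n_trials} trials"
                )
            gap = obs.after_trial - prev_after
            if gap not in rating_gaps:
                raise ValueError(
                    f"session {self.subject_id}: rating {k} gap of {gap} "
                    f"trials (allowed: {tuple(rating_gaps)})"
                )
            prev_after = obs.after_trial

    def truncated(self, n_ratings: int) -> "Session":
        """Copy of the session keeping only the first ``n_ratings`` ratings
        and the trials up to the last kept rating."""
        kept = self.ratings[:n_ratings]
        last_trial = kept[-1].after_trial if kept else 0
        return Session(
            subject_id=self.subject_id,
            task_kind=self.task_kind,
            trials=self.trials[:last_trial],
            ratings=kept,
        )


@dataclass(frozen=True)
class ModelSpec:
    """Declarative description of one member of the mood-model family.

    The family shares the form

        M_t = m0 + sum_v beta_v * sum_{j<=t} gamma^(t-j) X_v(j)

    and members differ in which regressor streams X_v are active and how the
    expectation term E_j is formed:

    - ``gamble_mean``: E is the mean of the trial's two gamble values
      (the recency family's expectation).
    - ``outcome_history_mean``: E is the plain average of all previous
      outcomes (the primacy model's expectation).
    - ``dynamic_win``: E weights the gamble values by a shrunken empirical
      win probability learned from the gamble history.
    - ``previous_outcome``: E is the immediately preceding trial's outcome.
    - ``decayed_window``: E is a decay-weighted mean of the last ``t_max``
      outcomes (weight ``decay**k`` on the outcome k steps back).

    ``include_certain_term`` adds a beta_C stream carrying the certain amount
    on trials where it was chosen.  ``distinguish_gamble_trials`` zeroes the
    E and R streams on certain-choice trials (the recency convention); the
    primacy model treats all trials alike.
    """

    name: str
    expectation_kind: ExpectationKind
    include_certain_term: bool
    distinguish_gamble_trials: bool
    decay: float | None = None
    t_max: int | None = None

    def __post_init__(self) -> None:
        if self.expectation_kind == "decayed_window":
            if self.decay is None or self.t_max is None:
                raise ValueError("decayed_window requires decay and t_max")
            if not 0.0 < self.decay <= 1.0:
                raise ValueError(f"decay must be in (0, 1], got {self.decay}")
            if self.t_max < 1:
                raise ValueError(f"t_max must be >= 1, got {self.t_max}")
        elif self.decay is not None or self.t_max is not None:
            raise ValueError(
                "decay/t_max are only meaningful for decayed_window"
            )

    @property
    def stream_names(self) -> tuple[str, ...]:
        """Active regressor streams, in the order used everywhere."""
        names: tuple[str, ...] = ("E", "R")
        if self.include_certain_term:
            names = ("C",) + names
        return names

    @property
    def n_streams(self) -> int:
        return len(self.stream_names)


#: Canonical primacy model: expectation = running mean of all prior outcomes,
#: no certain term, gamble and certain trials treated alike.
PRIMACY = ModelSpec("primacy", "outcome_history_mean", False, False)

#: Canonical recency model: expectation = current trial's gamble mean,
#: certain term included, E/R active on gamble trials only.
RECENCY = ModelSpec("recency", "gamble_mean", True, True)

RECENCY_DYNAMIC_WIN = ModelSpec("recency_dynamic_win", "dynamic_win", True, True)
RECENCY_NO_CERTAIN = ModelSpec("recency_no_certain", "gamble_mean", False, True)
RECENCY_PREV_OUTCOME = ModelSpec(
    "recency_prev_outcome", "previous_outcome", True, True
)
RECENCY_DYNAMIC_NO_CERTAIN = ModelSpec(
    "recency_dynamic_no_certain", "dynamic_win", False, True
)

CANONICAL_SPECS: dict[str, ModelSpec] = {
    s.name: s
    for s in (
        PRIMACY,
        RECENCY,
        RECENCY_DYNAMIC_WIN,
        RECENCY_NO_CERTAIN,
        RECENCY_PREV_OUTCOME,
        RECENCY_DYNAMIC_NO_CERTAIN,
    )
}


def decayed_window_spec(decay: float, t_max: int) -> ModelSpec:
    """A decayed-window alternative: primacy-like accumulation with an
    expectation restricted to a decaying window of recent outcomes."""
    return ModelSpec(
        name=f"decayed_window_w{decay:g}_t{t_max}",
        expectation_kind="decayed_window",
        include_certain_term=False,
        distinguish_gamble_trials=False,
        decay=decay,
        t_max=t_max,
    )


@dataclass
class SubjectParams:
    """Per-subject generative/fitted parameters.

    ``xi`` is the unbounded reparameterization of the exponential discount
    factor, gamma = 1 / (1 + exp(-xi)).  ``sigma`` is the standard deviation
    of the additive mood-rating noise and is only used generatively.
    """

    m0: float
    beta_e: float
    beta_r: float
    beta_c: float = 0.0
    xi: float = 0.0
    sigma: float = 0.0

    def __post_init__(self) -> None:
        if min(self.beta_e, self.beta_r, self.beta_c) < 0:
            raise ValueError("beta coefficients must be non-negative")
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")
        if not math.isfinite(self.xi):
            raise ValueError("xi must be finite")

    @property
    def gamma(self) -> float:
        return 1.0 / (1.0 + math.exp(-self.xi))

    def betas(self, spec: ModelSpec) -> list[float]:
        """Coefficients ordered to match ``spec.stream_names``."""
        by_name = {"C": self.beta_c, "E": self.beta_e, "R": self.beta_r}
        return [by_name[n] for n in spec.stream_names]

    def with_(self, **kw) -> "SubjectParams":
        return replace(self, **kw)
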