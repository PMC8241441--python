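"""Reward-environment generators: the random task, the structured (blocked)
task, and the structured-adaptive task whose reward prediction errors are set
in real time by a proportional-integral controller tracking the gap between
rated mood and a per-block mood target.

All generators are pure functions of (config, seed[, agent]) and emit
:class:`~mooddyn.types.Session` objects.  Congruency and outcome assignment
are scheduled at exact design proportions (shuffled positions) rather than
sampled independently per trial, so the printed design constants hold exactly
in every generated session.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .types import MoodObservation, Session, TrialRecord

__all__ = [
    "TaskConfig",
    "BlockSpec",
    "ControllerState",
    "ConfigError",
    "SessionAbortError",
    "generate_random_task",
    "generate_structured_task",
    "controller_mood_error",
    "controller_rpe_update",
    "realize_gamble",
    "assign_outcome",
    "run_adaptive_session",
]

#: Signature for an externally supplied gamble/certain choice rule.
ChoiceFn = Callable[[float, float, float, np.random.Generator], bool]


class ConfigError(ValueError):
    """Raised when a task configuration is internally infeasible."""


class SessionAbortError(RuntimeError):
    """Agent failure mid-session; carries the partial session log."""

    def __init__(self, message: str, partial: Session):
        super().__init__(message)
        self.partial_session = partial


@dataclass(frozen=True)
class TaskConfig:
    """Design constants of the three task variants.

    Defaults are the study conditions: 81 trials and 34 sparse mood ratings
    per session; three 27-trial blocks for the structured variants with
    block RPEs of +5 / -5 / +5 diluted by 30% incongruent trials of
    magnitude 1.5; and, for the adaptive variant, a controller gain
    (``rpe_baseline``) of 14 task points, high gamble values drawn from the
    grid [-1.5, 14] in steps of 0.2, a 2-point cap on the certain value, and
    mood targets at the top, bottom, top of the unit scale.
    """

    n_trials: int = 81
    n_ratings: int = 34
    rating_gap_choices: tuple[int, ...] = (2, 3)
    n_blocks: int = 3
    block_rpes: tuple[float, ...] = (5.0, -5.0, 5.0)
    incongruent_rpe: float = 1.5
    incongruent_fraction: float = 0.30
    random_rpe_range: float = 2.5
    random_rpe_step: float = 0.1
    random_mean_grid: tuple[float, float, float] = (0.0, 10.0, 0.2)
    rpe_baseline: float = 14.0
    high_grid: tuple[float, float, float] = (-1.5, 14.0, 0.2)
    certain_cap: float = 2.0
    mood_targets: tuple[float, ...] = (1.0, 0.0, 1.0)

    def __post_init__(self) -> None:
        if not 0.0 <= self.incongruent_fraction <= 1.0:
            raise ConfigError("incongruent_fraction must be in [0, 1]")
        if self.n_trials < self.n_ratings * min(self.rating_gap_choices):
            raise ConfigError(
                f"{self.n_ratings} ratings with gaps "
                f"{self.rating_gap_choices} cannot fit in {self.n_trials} trials"
            )
        if self.n_blocks != len(self.block_rpes) or self.n_blocks != len(
            self.mood_targets
        ):
            raise ConfigError("block_rpes/mood_targets must match n_blocks")

    @property
    def trials_per_block(self) -> int:
        if self.n_trials % self.n_blocks:
            raise ConfigError(
                f"{self.n_trials} trials do not divide into {self.n_blocks} blocks"
            )
        return self.n_trials // self.n_blocks

    def block_of_trial(self, t: int) -> int:
        """1-based block id of 1-based trial index ``t``."""
        return (t - 1) // self.trials_per_block + 1

    def block_valence(self, block_id: int) -> int:
        return 1 if self.block_rpes[block_id - 1] > 0 else -1

    def high_values(self) -> np.ndarray:
        lo, hi, step = self.high_grid
        return np.round(np.arange(lo, hi + step / 2, step), 10)

    def random_means(self) -> np.ndarray:
        lo, hi, step = self.random_mean_grid
        return np.round(np.arange(lo, hi + step / 2, step), 10)


@dataclass(frozen=True)
class BlockSpec:
    block_id: int
    valence: int
    n_trials: int
    n_ratings: int

    @property
    def congruent_outcome_is_high(self) -> bool:
        return self.valence > 0


@dataclass
class ControllerState:
    """Proportional-integral controller bookkeeping for one block."""

    block_id: int
    mood_target: float
    integral_accumulator: float = 0.0
    rpe_baseline: float = 14.0


def controller_mood_error(state: ControllerState, mood: float) -> float:
    """Normalized distance of the rated mood from the block's target.

    With the mood scale normalized to unit range the error is simply
    target - mood when the target sits at the top of the scale and
    mood - target when it sits at the bottom; either way it lies in [0, 1].
    """
    if not 0.0 <= mood <= 1.0:
        raise ValueError(f"mood {mood} outside the unit scale")
    if state.mood_target >= 0.5:
        return state.mood_target - mood
    return mood - state.mood_target


def controller_rpe_update(
    state: ControllerState, mood_error: float, congruent: bool
) -> float:
    """Signed RPE for the next trial group.

    The magnitude combines a proportional term (baseline gain times the
    current mood error) with the block's integral of past mood errors; on
    incongruent trials the integral term is divided by 3 and the sign is
    flipped relative to the block valence.  ``state.integral_accumulator``
    must already include ``mood_error``.
    """
    integral = state.integral_accumulator
    magnitude = state.rpe_baseline * mood_error + (
        integral if congruent else integral / 3.0
    )
    valence = 1.0 if state.mood_target >= 0.5 else -1.0
    return magnitude * (valence if congruent else -valence)


def realize_gamble(
    rpe: float, cfg: TaskConfig, rng: np.random.Generator
) -> tuple[float, float, float]:
    """Turn a controller RPE into (high, low, certain) gamble values.

    The high value is drawn from the configured grid and the low value sits
    ``|rpe|`` below it.  The certain amount is the gamble mean unless that
    exceeds the cap, in which case it is half the low value.
    """
    h = float(rng.choice(cfg.high_values()))
    l = h - abs(rpe)
    high, low = max(h, l), min(h, l)
    certain = 0.5 * (high + low)
    if certain > cfg.certain_cap:
        certain = low / 2.0
    return high, low, certain


def assign_outcome(
    valence: int, congruent: bool, high: float, low: float
) -> float:
    """Scheduled gamble outcome: high in positive blocks on congruent trials,
    low in negative blocks, and the reverse on incongruent trials."""
    if (valence > 0) == congruent:
        return high
    return low


# ---------------------------------------------------------------------------
# rating-slot placement


def _sample_rating_positions(
    n_trials: int,
    n_ratings: int,
    gap_choices: Sequence[int],
    rng: np.random.Generator,
    block_edges: Sequence[int] | None = None,
    per_block_counts: Sequence[int] | None = None,
) -> list[int]:
    """Randomized backtracking placement of rating slots.

    Consecutive slots (and the first slot) are separated by a gap drawn from
    ``gap_choices``; with block constraints, each block must receive exactly
    its quota of ratings.  Raises :class:`ConfigError` when infeasible.
    """
    gaps = list(gap_choices)
    min_gap = min(gaps)
    edges = list(block_edges) if block_edges else [n_trials]
    quotas = list(per_block_counts) if per_block_counts else [n_ratings]

    def block_of(pos: int) -> int:
        for b, edge in enumerate(edges):
            if pos <= edge:
                return b
        raise AssertionError("position beyond last block edge")

    def search(pos: int, k: int, counts: list[int]) -> list[int] | None:
        if k == n_ratings:
            return [] if counts == quotas else None
        for gap in rng.permutation(gaps):
            npos = pos + int(gap)
            if npos > n_trials:
                continue
            if npos + (n_ratings - k - 1) * min_gap > n_trials:
                continue
            b = block_of(npos)
            if counts[b] + 1 > quotas[b]:
                continue
            if any(counts[i] != quotas[i] for i in range(b)):
                continue
            counts[b] += 1
            rest = search(npos, k + 1, counts)
            counts[b] -= 1
            if rest is not None:
                return [npos] + rest
        return None

    result = search(0, 0, [0] * len(quotas))
    if result is None:
        raise ConfigError(
            f"cannot place {n_ratings} ratings with gaps {tuple(gaps)} "
            f"in {n_trials} trials under block quotas {quotas}"
        )
    return result


def _block_rating_quotas(cfg: TaskConfig, rng: np.random.Generator) -> list[int]:
    """Split the rating budget across blocks, 11-12 per 27-trial block."""
    base = cfg.n_ratings // cfg.n_blocks
    extra = cfg.n_ratings - base * cfg.n_blocks
    quotas = [base] * cfg.n_blocks
    for b in rng.permutation(cfg.n_blocks)[:extra]:
        quotas[b] += 1
    return quotas


def _congruency_schedule(cfg: TaskConfig, rng: np.random.Generator) -> list[bool]:
    """Exact-proportion congruent/incongruent flags, shuffled within block."""
    per_block = cfg.trials_per_block
    n_inc = round(cfg.incongruent_fraction * per_block)
    flags: list[bool] = []
    for _ in range(cfg.n_blocks):
        block = np.ones(per_block, dtype=bool)
        block[rng.permutation(per_block)[:n_inc]] = False
        flags.extend(block.tolist())
    return flags


def _make_ratings(positions: Sequence[int]) -> list[MoodObservation]:
    return [
        MoodObservation(rating_index=k, after_trial=pos, value=float("nan"))
        for k, pos in enumerate(positions, start=1)
    ]


# ---------------------------------------------------------------------------
# open-loop generators


def generate_random_task(
    cfg: TaskConfig,
    seed: int,
    choice_fn: ChoiceFn | None = None,
    subject_id: str = "sim",
) -> Session:
    """Random reward environment: i.i.d. gambles with RPEs bounded by
    ``cfg.random_rpe_range`` and a 50% win probability.

    The gamble mean is drawn from a uniform grid, the two values sit
    symmetrically around it, and the certain amount equals the mean exactly.
    Rating values are left NaN for an agent to fill in.
    """
    rng = np.random.default_rng(seed)
    positions = _sample_rating_positions(
        cfg.n_trials, cfg.n_ratings, cfg.rating_gap_choices, rng
    )
    means = cfg.random_means()
    mags = np.round(
        np.arange(cfg.random_rpe_step, cfg.random_rpe_range + 1e-9, cfg.random_rpe_step),
        10,
    )
    trials = []
    for t in range(1, cfg.n_trials + 1):
        mean = float(rng.choice(means))
        mag = float(rng.choice(mags))
        high, low = mean + mag, mean - mag
        certain = mean
        win = bool(rng.random() < 0.5)
        gamble = True if choice_fn is None else bool(
            choice_fn(high, low, certain, rng)
        )
        outcome = (high if win else low) if gamble else certain
        trials.append(
            TrialRecord(
                index=t,
                high=high,
                low=low,
                certain=certain,
                chose_gamble=gamble,
                outcome=outcome,
                block_id=0,
            )
        )
    return Session(subject_id, "random", trials, _make_ratings(positions))


def generate_structured_task(
    cfg: TaskConfig,
    seed: int,
    choice_fn: ChoiceFn | None = None,
    subject_id: str = "sim",
) -> Session:
    """Structured reward environment: three blocks of predetermined RPEs
    (+5, -5, +5) with exactly 30% incongruent trials of magnitude 1.5.

    The scheduled RPE is realized relative to the gamble mean: a congruent
    trial of a positive block resolves to the high value with
    high - mean = +5, and symmetrically for the other cases.  Certain equals
    the gamble mean.
    """
    rng = np.random.default_rng(seed)
    quotas = _block_rating_quotas(cfg, rng)
    edges = [cfg.trials_per_block * (b + 1) for b in range(cfg.n_blocks)]
    positions = _sample_rating_positions(
        cfg.n_trials, cfg.n_ratings, cfg.rating_gap_choices, rng, edges, quotas
    )
    congruent_flags = _congruency_schedule(cfg, rng)
    highs = cfg.high_values()
    trials = []
    for t in range(1, cfg.n_trials + 1):
        block = cfg.block_of_trial(t)
        valence = cfg.block_valence(block)
        congruent = congruent_flags[t - 1]
        rpe_mag = abs(cfg.block_rpes[block - 1]) if congruent else cfg.incongruent_rpe
        h = float(rng.choice(highs))
        # outcome - gamble_mean = +/-rpe_mag requires a value gap of 2*rpe_mag
        low = h - 2.0 * rpe_mag
        certain = 0.5 * (h + low)
        scheduled = assign_outcome(valence, congruent, h, low)
        gamble = True if choice_fn is None else bool(
            choice_fn(h, low, certain, rng)
        )
        outcome = scheduled if gamble else certain
        trials.append(
            TrialRecord(
                index=t,
                high=h,
                low=low,
                certain=certain,
                chose_gamble=gamble,
                outcome=outcome,
                block_id=block,
                congruent=congruent,
            )
        )
    return Session(subject_id, "structured", trials, _make_ratings(positions))


# ---------------------------------------------------------------------------
# closed loop


def run_adaptive_session(
    cfg: TaskConfig,
    agent,
    seed: int,
    subject_id: str = "sim",
    controller_log: list | None = None,
) -> Session:
    """Structured-adaptive environment: the PI controller sets each trial
    group's RPE from the latest mood rating.

    ``agent`` must provide ``choose(high, low, certain, rng) -> bool`` and
    ``rate(session_prefix) -> float`` (a mood value on the unit scale).
    After every rating the controller converts the mood error into a signed
    RPE for the following 2-3 trials; the integral accumulator resets at
    each block boundary.  Before the first rating a neutral mid-scale mood
    error of 0.5 is assumed (proportional term only).
    """
    rng = np.random.default_rng(seed)
    quotas = _block_rating_quotas(cfg, rng)
    edges = [cfg.trials_per_block * (b + 1) for b in range(cfg.n_blocks)]
    positions = _sample_rating_positions(
        cfg.n_trials, cfg.n_ratings, cfg.rating_gap_choices, rng, edges, quotas
    )
    rating_at = {pos: k for k, pos in enumerate(positions, start=1)}
    congruent_flags = _congruency_schedule(cfg, rng)

    session = Session(subject_id, "structured_adaptive", [], [])
    state = ControllerState(
        block_id=1,
        mood_target=cfg.mood_targets[0],
        integral_accumulator=0.0,
        rpe_baseline=cfg.rpe_baseline,
    )
    mood_error: float | None = None  # None until the first rating
    last_mood: float | None = None

    for t in range(1, cfg.n_trials + 1):
        block = cfg.block_of_trial(t)
        if block != state.block_id:
            # new block: fresh integral, error re-aimed at the new target
            state = ControllerState(
                block_id=block,
                mood_target=cfg.mood_targets[block - 1],
                integral_accumulator=0.0,
                rpe_baseline=cfg.rpe_baseline,
            )
            if last_mood is not None:
                mood_error = controller_mood_error(state, last_mood)
        congruent = congruent_flags[t - 1]
        if mood_error is None:
            me, proxy = 0.5, ControllerState(
                block, state.mood_target, 0.0, cfg.rpe_baseline
            )
            rpe = controller_rpe_update(proxy, me, congruent)
        else:
            rpe = controller_rpe_update(state, mood_error, congruent)
        high, low, certain = realize_gamble(rpe, cfg, rng)
        if controller_log is not None:
            controller_log.append(
                {
                    "trial": t,
                    "block": block,
                    "mood_error": mood_error,
                    "integral": state.integral_accumulator,
                    "rpe": rpe,
                }
            )
        valence = cfg.block_valence(block)
        try:
            gamble = bool(agent.choose(high, low, certain, rng))
        except Exception as err:  # noqa: BLE001 - report with partial log
            raise SessionAbortError(
                f"agent choice failed at trial {t}: {err}", session
            ) from err
        outcome = (
            assign_outcome(valence, congruent, high, low) if gamble else certain
        )
        session.trials.append(
            TrialRecord(
                index=t,
                high=high,
                low=low,
                certain=certain,
                chose_gamble=gamble,
                outcome=outcome,
                block_id=block,
                congruent=congruent,
            )
        )
        if t in rating_at:
            try:
                mood = float(agent.rate(session))
            except Exception as err:  # noqa: BLE001
                raise SessionAbortError(
                    f"agent rating failed after trial {t}: {err}", session
                ) from err
            session.ratings.append(
                MoodObservation(
                    rating_index=rating_at[t], after_trial=t, value=mood
                )
            )
            last_mood = mood
            # aim at the block the next trials belong to
            next_block = cfg.block_of_trial(min(t + 1, cfg.n_trials))
            target = cfg.mood_targets[next_block - 1]
            aim = state if next_block == state.block_id else ControllerState(
                next_block, target, state.integral_accumulator, cfg.rpe_baseline
            )
            mood_error = controller_mood_error(aim, mood)
            state.integral_accumulator += mood_error
    return session
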