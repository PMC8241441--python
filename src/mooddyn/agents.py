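"""Synthetic participants: choice policies and model-based mood raters.

A cohort simulated here is the ground-truth test bed for fitting and model
comparison: each subject's mood ratings are generated by a known member of
the model family with known parameters, plus Gaussian rating noise, clamped
to the unit scale.  Clamping is the only nonlinearity, so noise-free
in-range ratings equal the model's predictions exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np

from .models import predict_mood_at_trials
from .tasks import (
    TaskConfig,
    generate_random_task,
    generate_structured_task,
    run_adaptive_session,
)
from .types import ModelSpec, PRIMACY, Session, SubjectParams

__all__ = [
    "ChoicePolicy",
    "PopulationSpec",
    "ModelAgent",
    "choose_gamble",
    "simulate_mood",
    "sample_population",
    "simulate_cohort",
]


@dataclass(frozen=True)
class ChoicePolicy:
    """How a synthetic participant decides between gambling and the certain
    amount.  The study's models do not describe choice, so policies are
    deliberately simple; the default elsewhere is fixed_probability at 0.7,
    which keeps certain-choice trials present for the certain-term stream."""

    kind: Literal["always_gamble", "fixed_probability", "value_greedy"] = (
        "fixed_probability"
    )
    p_gamble: float = 0.7

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_gamble <= 1.0:
            raise ValueError(f"p_gamble must be in [0, 1], got {self.p_gamble}")


def choose_gamble(
    policy: ChoicePolicy,
    high: float,
    low: float,
    certain: float,
    rng: np.random.Generator,
) -> bool:
    if policy.kind == "always_gamble":
        return True
    if policy.kind == "fixed_probability":
        return bool(rng.random() < policy.p_gamble)
    if policy.kind == "value_greedy":
        return 0.5 * (high + low) > certain
    raise ValueError(f"unknown policy kind {policy.kind!r}")


@dataclass(frozen=True)
class PopulationSpec:
    """Distributions from which a synthetic cohort's parameters are drawn.

    Defaults keep noise-free mood predictions mostly inside the unit scale
    for the default task configurations: baseline mood uniform mid-scale,
    half-normal sensitivities on the order of 0.01 per task point, standard
    normal xi (so gamma centers on 0.5), and rating noise of 0.05 on the
    unit mood scale.
    """

    n_subjects: int = 40
    generating_model: ModelSpec = PRIMACY
    m0_range: tuple[float, float] = (0.3, 0.7)
    beta_scales: tuple[tuple[str, float], ...] = (
        ("C", 0.01),
        ("E", 0.01),
        ("R", 0.01),
    )
    xi_mean: float = 0.0
    xi_sd: float = 1.0
    sigma: float = 0.05
    choice_policy: ChoicePolicy = field(default_factory=ChoicePolicy)

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")

    @property
    def beta_scale_map(self) -> dict[str, float]:
        return dict(self.beta_scales)

    def with_(self, **kw) -> "PopulationSpec":
        return replace(self, **kw)


def simulate_mood(
    params: SubjectParams,
    spec: ModelSpec,
    session_prefix: Session,
    rng: np.random.Generator,
) -> float:
    """One noisy mood rating at the end of ``session_prefix``.

    The model's noise-free prediction at the last played trial, plus
    Normal(0, sigma) rating noise, clamped to the unit scale.
    """
    t = session_prefix.n_trials
    if t < 1:
        raise ValueError("session prefix contains no trials")
    value = float(
        predict_mood_at_trials(spec, params, session_prefix, [t])[0]
    )
    if params.sigma > 0:
        value += rng.normal(0.0, params.sigma)
    return float(np.clip(value, 0.0, 1.0))


def _draw_params(pop: PopulationSpec, rng: np.random.Generator) -> SubjectParams:
    scales = pop.beta_scale_map
    active = set(pop.generating_model.stream_names)
    m0 = float(rng.uniform(*pop.m0_range))
    betas = {
        name: (
            abs(float(rng.normal(0.0, scales.get(name, 0.0))))
            if name in active
            else 0.0
        )
        for name in ("C", "E", "R")
    }
    xi = float(rng.normal(pop.xi_mean, pop.xi_sd))
    return SubjectParams(
        m0=m0,
        beta_e=betas["E"],
        beta_r=betas["R"],
        beta_c=betas["C"],
        xi=xi,
        sigma=pop.sigma,
    )


def sample_population(pop: PopulationSpec, seed: int) -> list[SubjectParams]:
    """Draw ``pop.n_subjects`` ground-truth parameter sets, reproducibly."""
    rng = np.random.default_rng(seed)
    return [_draw_params(pop, rng) for _ in range(pop.n_subjects)]


class ModelAgent:
    """A synthetic participant driven by a mood model.

    Supplies gamble/certain choices from a :class:`ChoicePolicy` and mood
    ratings from the generating model via :func:`simulate_mood`; usable both
    open-loop (filling ratings after the fact) and closed-loop inside
    :func:`mooddyn.tasks.run_adaptive_session`, where its ratings steer the
    controller.
    """

    def __init__(
        self,
        params: SubjectParams,
        spec: ModelSpec,
        policy: ChoicePolicy,
        rng: np.random.Generator,
    ):
        self.params = params
        self.spec = spec
        self.policy = policy
        self.rng = rng

    def choose(
        self, high: float, low: float, certain: float, rng: np.random.Generator
    ) -> bool:
        return choose_gamble(self.policy, high, low, certain, self.rng)

    def rate(self, session_prefix: Session) -> float:
        return simulate_mood(self.params, self.spec, session_prefix, self.rng)


def simulate_cohort(
    pop: PopulationSpec,
    task_kind: str,
    seed: int,
    cfg: TaskConfig | None = None,
    require_interior: bool = False,
) -> tuple[list[Session], list[SubjectParams]]:
    """Simulate a full cohort on one task, returning sessions paired with the
    ground-truth parameters that generated their ratings.

    Random and structured tasks are generated open-loop and the rating slots
    filled by the generating model; the structured-adaptive task runs the
    full closed loop, with this agent's ratings driving the controller.

    With ``require_interior`` (open-loop tasks only), a subject's parameters
    are redrawn until the noise-free predicted mood stays strictly inside the
    unit scale on their session, so the rating clamp is never active and the
    observations are an exact realization of the linear model — the regime in
    which parameter recovery is well defined.
    """
    cfg = cfg or TaskConfig()
    truth = sample_population(pop, seed)
    child_seeds = np.random.SeedSequence(seed).spawn(pop.n_subjects)
    spec = pop.generating_model
    sessions = []
    for i, (params, ss) in enumerate(zip(truth, child_seeds)):
        rng = np.random.default_rng(ss)
        task_seed = int(rng.integers(0, 2**31 - 1))
        agent = ModelAgent(params, spec, pop.choice_policy, rng)
        sid = f"sim{i:03d}"
        if task_kind == "structured_adaptive":
            if require_interior:
                raise ValueError(
                    "require_interior is only defined for open-loop tasks"
                )
            session = run_adaptive_session(cfg, agent, task_seed, subject_id=sid)
        elif task_kind in ("random", "structured"):
            gen = (
                generate_random_task
                if task_kind == "random"
                else generate_structured_task
            )
            session = gen(
                cfg,
                task_seed,
                choice_fn=lambda h, l, c, r: agent.choose(h, l, c, r),
                subject_id=sid,
            )
            if require_interior:
                from .models import predict_mood_series

                rated = [o.after_trial for o in session.ratings]
                for attempt in range(1000):
                    pred = predict_mood_at_trials(spec, params, session, rated)
                    if np.all((pred > 0.0) & (pred < 1.0)):
                        break
                    params = _draw_params(pop, rng)
                else:
                    raise RuntimeError(
                        "could not draw interior parameters in 1000 tries"
                    )
                truth[i] = params
                agent.params = params
            for obs in session.ratings:
                obs.value = agent.rate(session.truncated(obs.rating_index))
        else:
            raise ValueError(f"unknown task kind {task_kind!r}")
        session.validate()
        sessions.append(session)
    return sessions, truth
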