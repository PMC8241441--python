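"""Model comparison: training error, streaming one-step-ahead prediction,
paired Wilcoxon signed-rank tests, model recovery, and coefficient contrasts.

The streaming criterion is strictly causal: the prediction of mood rating k
uses a model refit on ratings 1..k-1 only (trial regressors are task data
and known throughout).  Prediction errors at rating indices below 11 are
discarded from the summary MSE, where the criterion is unstable for want of
data.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .fitting import FitConfig, FitResult, GroupData, build_regressors, fit_group
from .types import ModelSpec, Session

__all__ = [
    "StreamingResult",
    "ComparisonResult",
    "RecoveryResult",
    "ContrastResult",
    "training_error",
    "streaming_prediction",
    "compare_models",
    "model_recovery",
    "coefficient_contrast",
]

logger = logging.getLogger(__name__)

#: First rating index at which streaming refits begin (three ratings of
#: history, roughly 15 gambling trials, suffice to fit all parameters).
FIRST_FIT_RATING = 4

#: Rating indices below this are excluded from the streaming MSE.
MSE_FROM_RATING = 11


def training_error(fit_result: FitResult) -> np.ndarray:
    """Per-subject mean squared residual over the fitted rating set T."""
    return fit_result.training_mse


@dataclass
class StreamingResult:
    """Prospective prediction record for one model over a cohort.

    ``predicted``/``observed``/``squared_error`` have one row per subject and
    one column per predicted rating index (``rating_indices``); entries are
    NaN where a subject has no such rating.  ``mse`` summarizes each subject
    over rating indices >= 11.
    """

    spec_name: str
    subject_ids: list[str]
    rating_indices: np.ndarray
    predicted: np.ndarray
    observed: np.ndarray
    squared_error: np.ndarray
    mse: np.ndarray


def _predict_matrix(theta: np.ndarray, data: GroupData) -> np.ndarray:
    """Model predictions at every rated trial for every subject."""
    from .fitting import _sigmoid, _softplus, _unpack

    n_s, p = data.n_subjects, data.p
    mu, xi, b = _unpack(theta, n_s, p)
    gamma = _sigmoid(xi)[:, None]
    beta = _softplus(b)
    s_run = np.zeros((n_s, p))
    s_all = np.empty_like(data.x)
    for t in range(data.x.shape[1]):
        s_run = gamma * s_run + data.x[:, t, :]
        s_all[:, t, :] = s_run
    s_k = np.take_along_axis(s_all, (data.idx - 1)[:, :, None], axis=1)
    return mu[:, None] + np.einsum("skp,sp->sk", s_k, beta)


def streaming_prediction(
    sessions: Sequence[Session],
    spec: ModelSpec,
    cfg: FitConfig | None = None,
    warm_start: bool = True,
) -> StreamingResult:
    """Within-subject one-step-ahead prediction of each mood rating.

    For each rating index k starting at 4, the model is refit jointly across
    the cohort on ratings 1..k-1 (prefix fits place no early-trial discard
    on T, unlike the final training fit) and each subject's rating k is
    predicted from their full trial history.  Prefix fits are warm-started
    from the previous prefix's solution by default; the first prefix uses
    the configured multi-start.
    """
    cfg = cfg or FitConfig()
    usable, skipped = [], []
    for s in sessions:
        (usable if s.n_ratings >= MSE_FROM_RATING else skipped).append(s)
    if skipped:
        logger.warning(
            "excluding %d session(s) with fewer than %d ratings: %s",
            len(skipped),
            MSE_FROM_RATING,
            [s.subject_id for s in skipped],
        )
    if not usable:
        raise ValueError("no session has enough ratings for streaming MSE")

    regs = [build_regressors(spec, s, min_trial=1) for s in usable]
    data = GroupData(regs)
    n_s, n_k = data.valid.shape
    k_values = np.arange(FIRST_FIT_RATING, n_k + 1)
    predicted = np.full((n_s, len(k_values)), np.nan)
    observed = np.full((n_s, len(k_values)), np.nan)

    theta = None
    for col, k in enumerate(k_values):
        keep = np.zeros_like(data.valid)
        keep[:, : k - 1] = True
        prefix = data.masked(keep)
        fit = fit_group(
            usable,
            spec,
            cfg,
            init_theta=theta if (warm_start and theta is not None) else None,
            data=prefix,
        )
        theta = fit.theta
        preds = _predict_matrix(theta, data)
        has_k = data.valid[:, k - 1]
        predicted[has_k, col] = preds[has_k, k - 1]
        observed[has_k, col] = data.y[has_k, k - 1]

    sq_err = (predicted - observed) ** 2
    scored = k_values >= MSE_FROM_RATING
    mse = np.nanmean(sq_err[:, scored], axis=1)
    return StreamingResult(
        spec_name=spec.name,
        subject_ids=[s.subject_id for s in usable],
        rating_indices=k_values,
        predicted=predicted,
        observed=observed,
        squared_error=sq_err,
        mse=mse,
    )


@dataclass
class ComparisonResult:
    """Paired one-sided Wilcoxon signed-rank comparison of per-subject MSEs.

    ``p_value`` tests the hypothesis that model A's errors are smaller;
    positive ``z`` favors model A.  ``winner`` is whichever model beats the
    other at ``alpha``, "none" when neither does, or "tie" when every paired
    difference is zero (no test possible).
    """

    label_a: str
    label_b: str
    n: int
    n_effective: int
    median_a: float
    iqr_a: float
    median_b: float
    iqr_b: float
    z: float | None
    p_value: float | None
    p_value_reverse: float | None
    winner: str
    method: str


def _exact_signed_rank_p(d: np.ndarray, alternative: str) -> float:
    """Exact one-sided signed-rank p by enumerating the null distribution of
    the positive-rank sum over all 2^n sign patterns (dynamic programming on
    doubled midranks, so tied magnitudes are handled exactly)."""
    ranks2 = np.round(2 * stats.rankdata(np.abs(d))).astype(int)
    t_obs = int(ranks2[d > 0].sum())
    total = int(ranks2.sum())
    dist = np.zeros(total + 1)
    dist[0] = 1.0
    for r in ranks2:
        shifted = np.zeros_like(dist)
        shifted[r:] = dist[: total + 1 - r]
        dist = dist + shifted
    dist /= 2 ** len(d)
    if alternative == "less":
        return float(dist[: t_obs + 1].sum())
    return float(dist[t_obs:].sum())


def _signed_rank_z(d: np.ndarray) -> float:
    """Normal-approximation z for the signed-rank test with continuity and
    tie corrections; positive when the differences are predominantly
    negative (model A's errors smaller)."""
    n = len(d)
    ranks = stats.rankdata(np.abs(d))
    t_plus = float(ranks[d > 0].sum())
    mu = n * (n + 1) / 4.0
    var = n * (n + 1) * (2 * n + 1) / 24.0
    _, counts = np.unique(ranks, return_counts=True)
    var -= float(np.sum(counts**3 - counts)) / 48.0
    shift = mu - t_plus
    correction = 0.5 * np.sign(shift)
    return float((shift - correction) / math.sqrt(var)) if var > 0 else 0.0


def compare_models(
    errors_a: Sequence[float],
    errors_b: Sequence[float],
    label_a: str = "A",
    label_b: str = "B",
    alpha: float = 0.05,
) -> ComparisonResult:
    """Compare paired per-subject errors of two models.

    Zero differences are dropped (standard signed-rank practice); with 25 or
    fewer effective pairs the exact tie-aware null distribution is
    enumerated, otherwise the normal approximation with continuity and tie
    corrections is used.
    """
    a = np.asarray(errors_a, dtype=float)
    b = np.asarray(errors_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired error vectors must have equal length")
    q1a, q3a = np.percentile(a, [25, 75])
    q1b, q3b = np.percentile(b, [25, 75])
    summary = dict(
        label_a=label_a,
        label_b=label_b,
        n=len(a),
        median_a=float(np.median(a)),
        iqr_a=float(q3a - q1a),
        median_b=float(np.median(b)),
        iqr_b=float(q3b - q1b),
    )
    d = a - b
    d_nz = d[d != 0]
    n_eff = len(d_nz)
    if n_eff == 0:
        return ComparisonResult(
            **summary,
            n_effective=0,
            z=None,
            p_value=None,
            p_value_reverse=None,
            winner="tie",
            method="tie",
        )
    exact = n_eff <= 25
    method = "exact" if exact else "approx"
    if exact:
        p_ab = _exact_signed_rank_p(d_nz, "less")
        p_ba = _exact_signed_rank_p(d_nz, "greater")
    else:
        p_ab = float(
            stats.wilcoxon(
                d_nz, alternative="less", method="approx", correction=True
            ).pvalue
        )
        p_ba = float(
            stats.wilcoxon(
                d_nz, alternative="greater", method="approx", correction=True
            ).pvalue
        )
    z = _signed_rank_z(d_nz)
    if p_ab < alpha:
        winner = label_a
    elif p_ba < alpha:
        winner = label_b
    else:
        winner = "none"
    return ComparisonResult(
        **summary,
        n_effective=n_eff,
        z=z,
        p_value=p_ab,
        p_value_reverse=p_ba,
        winner=winner,
        method=method,
    )


@dataclass
class RecoveryResult:
    """Generating-model by fitted-model recovery grid.

    ``cells`` maps (generating model, alternative model, criterion) to the
    ComparisonResult of generating-model errors versus alternative-model
    errors on data the generating model produced; ``recovered`` records, per
    generating model, whether it beat every alternative on every criterion.
    """

    cells: dict[tuple[str, str, str], ComparisonResult]
    recovered: dict[str, bool]
    seed: int
    n_subjects: dict[str, int]

    @property
    def all_recovered(self) -> bool:
        return all(self.recovered.values())


def model_recovery(
    pop_specs: Sequence,
    spec_list: Sequence[ModelSpec],
    task_kind: str,
    seed: int,
    cfg: FitConfig | None = None,
    criteria: Sequence[str] = ("training", "streaming"),
    alpha: float = 0.05,
) -> RecoveryResult:
    """Simulate data from each candidate model and check that the comparison
    machinery identifies the generator.

    ``pop_specs`` are PopulationSpecs whose ``generating_model`` must appear
    in ``spec_list``.  For each simulated cohort every candidate is fit and
    scored by the requested criteria; recovery succeeds for a generator when
    it attains significantly smaller errors than every alternative on every
    criterion.
    """
    from .agents import simulate_cohort

    cfg = cfg or FitConfig()
    cells: dict[tuple[str, str, str], ComparisonResult] = {}
    recovered: dict[str, bool] = {}
    n_subjects: dict[str, int] = {}
    for i, pop in enumerate(pop_specs):
        gen = pop.generating_model
        if gen.name not in [s.name for s in spec_list]:
            raise ValueError(f"generating model {gen.name} not in spec_list")
        sessions, _ = simulate_cohort(pop, task_kind, seed + i)
        n_subjects[gen.name] = len(sessions)
        errors: dict[tuple[str, str], np.ndarray] = {}
        for spec in spec_list:
            if "training" in criteria:
                fit = fit_group(sessions, spec, cfg)
                errors[(spec.name, "training")] = training_error(fit)
            if "streaming" in criteria:
                stream = streaming_prediction(sessions, spec, cfg)
                errors[(spec.name, "streaming")] = stream.mse
        ok = True
        for spec in spec_list:
            if spec.name == gen.name:
                continue
            for crit in criteria:
                cmp = compare_models(
                    errors[(gen.name, crit)],
                    errors[(spec.name, crit)],
                    label_a=gen.name,
                    label_b=spec.name,
                    alpha=alpha,
                )
                cells[(gen.name, spec.name, crit)] = cmp
                ok = ok and cmp.winner == gen.name
        recovered[gen.name] = ok
    return RecoveryResult(
        cells=cells, recovered=recovered, seed=seed, n_subjects=n_subjects
    )


@dataclass
class ContrastResult:
    """Paired-t contrast of the expectation versus RPE coefficients."""

    t: float
    p_value: float | None
    ci_low: float
    ci_high: float
    mean_difference: float
    n: int
    zero_variance: bool


def coefficient_contrast(fit_result: FitResult) -> ContrastResult:
    """Paired t-test of beta_E against beta_R across subjects.

    A positive mean difference says the expectation term carries more weight
    than the prediction-error term.  Constant differences have no sampling
    variance; the statistic is then flagged and reported as infinite.
    """
    be = np.array([p.beta_e for p in fit_result.params])
    br = np.array([p.beta_r for p in fit_result.params])
    n = len(be)
    if n < 3:
        raise ValueError("coefficient contrast needs at least 3 subjects")
    d = be - br
    mean_d = float(d.mean())
    sd = float(d.std(ddof=1))
    if sd <= 1e-12 * max(1.0, abs(mean_d)):
        t = 0.0 if mean_d == 0.0 else math.copysign(math.inf, mean_d)
        return ContrastResult(
            t=t,
            p_value=None,
            ci_low=mean_d,
            ci_high=mean_d,
            mean_difference=mean_d,
            n=n,
            zero_variance=True,
        )
    res = stats.ttest_rel(be, br)
    se = sd / math.sqrt(n)
    t_crit = stats.t.ppf(0.975, n - 1)
    return ContrastResult(
        t=float(res.statistic),
        p_value=float(res.pvalue),
        ci_low=mean_d - t_crit * se,
        ci_high=mean_d + t_crit * se,
        mean_difference=mean_d,
        n=n,
        zero_variance=False,
    )
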