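"""Unit and property tests for the mood-model family's building blocks."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mooddyn import (
    PRIMACY,
    RECENCY,
    ModelSpec,
    Session,
    SubjectParams,
    TrialRecord,
    compute_rpe,
    decayed_window_expectation,
    decayed_window_spec,
    discounted_sums,
    dynamic_expectation,
    dynamic_win_probability,
    gamma_from_xi,
    influence_curve,
    predict_mood_at_trials,
    predict_mood_series,
    primacy_expectation,
    recency_expectation,
    regressor_streams,
    xi_from_gamma,
)
from conftest import make_session


def gamble(i, high, low, outcome, won=None):
    return TrialRecord(i, high, low, 0.5 * (high + low), True, outcome)


class TestDiscountReparameterization:
    @pytest.mark.parametrize(
        "xi, gamma",
        [(0.0, 0.5), (math.log(3), 0.75), (40.0, 1.0), (-40.0, 0.0)],
    )
    def test_logistic_map(self, xi, gamma):
        assert gamma_from_xi(xi) == pytest.approx(gamma, abs=1e-12)

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            gamma_from_xi(float("nan"))
        with pytest.raises(ValueError):
            gamma_from_xi(float("inf"))

    @given(st.floats(-15, 15), st.floats(-15, 15))
    def test_strictly_monotone(self, a, b):
        if a + 1e-6 < b:
            assert gamma_from_xi(a) < gamma_from_xi(b)

    @given(st.floats(-15, 15))
    def test_round_trip(self, xi):
        assert xi_from_gamma(gamma_from_xi(xi)) == pytest.approx(xi, abs=1e-6)


class TestExpectationTerms:
    @pytest.mark.parametrize(
        "high, low, expected", [(10, 0, 5), (4, 4, 4), (3, -1, 1)]
    )
    def test_recency_is_gamble_mean(self, high, low, expected):
        tr = gamble(1, high, low, high)
        assert recency_expectation(tr) == expected

    @pytest.mark.parametrize(
        "history, t, expected",
        [([2, 4], 3, 3.0), ([], 1, 0.0), ([7, 7, 7, 7], 5, 7.0)],
    )
    def test_primacy_is_history_mean(self, history, t, expected):
        assert primacy_expectation(history, t) == pytest.approx(expected)

    @given(st.lists(st.floats(-10, 10), min_size=1, max_size=20))
    def test_primacy_order_invariant(self, history):
        t = len(history) + 1
        forward = primacy_expectation(history, t)
        backward = primacy_expectation(history[::-1], t)
        assert forward == pytest.approx(backward, abs=1e-9)

    @pytest.mark.parametrize("p, high, low, expected", [
        (0.5, 10, 0, 5), (1.0, 8, -3, 8), (0.75, 10, 2, 8),
    ])
    def test_dynamic_expectation(self, p, high, low, expected):
        assert dynamic_expectation(gamble(1, high, low, high), p) == expected


class TestDynamicWinProbability:
    def test_empty_history_gives_prior(self):
        assert dynamic_win_probability([]) == 0.5

    def test_ten_straight_wins(self):
        history = [gamble(i, 2, 0, 2) for i in range(1, 11)]
        assert dynamic_win_probability(history) == 0.75

    def test_partial_wins(self):
        wins = [gamble(i, 2, 0, 2) for i in (1, 2)]
        losses = [gamble(i, 2, 0, 0) for i in (3, 4)]
        assert dynamic_win_probability(wins + losses) == 0.5

    def test_certain_trials_do_not_count(self):
        certain = [TrialRecord(i, 2, 0, 1, False, 1) for i in range(1, 6)]
        assert dynamic_win_probability(certain) == 0.5

    @given(st.lists(st.booleans(), max_size=40))
    def test_bounded_and_win_monotone(self, results):
        history = [
            gamble(i, 2, 0, 2 if won else 0)
            for i, won in enumerate(results, start=1)
        ]
        p = dynamic_win_probability(history)
        assert 0 < p < 1
        extra_win = history + [gamble(len(history) + 1, 2, 0, 2)]
        assert dynamic_win_probability(extra_win) >= p


class TestDecayedWindow:
    def test_reduces_to_primacy_when_undamped(self):
        assert decayed_window_expectation([2, 4], 1.0, 10) == pytest.approx(3.0)

    def test_small_decay_keeps_most_recent(self):
        value = decayed_window_expectation([0, 4], 1e-9, 5)
        assert value == pytest.approx(4.0, abs=1e-6)

    def test_hand_weighted_example(self):
        # weights 1 on the last outcome (4), 0.5 on the one before (0)
        value = decayed_window_expectation([1, 1, 0, 4], 0.5, 2)
        assert value == pytest.approx(8.0 / 3.0)

    @pytest.mark.parametrize("decay, t_max", [(0.0, 2), (1.5, 2), (0.5, 0)])
    def test_invalid_parameters_rejected(self, decay, t_max):
        with pytest.raises(ValueError):
            decayed_window_expectation([1.0], decay, t_max)

    @given(st.lists(st.floats(-5, 5), min_size=1, max_size=30))
    def test_equals_primacy_at_full_undamped_window(self, outcomes):
        t = len(outcomes) + 1
        full = decayed_window_expectation(outcomes, 1.0, len(outcomes))
        assert full == pytest.approx(
            primacy_expectation(outcomes, t), rel=1e-12, abs=1e-12
        )


@pytest.mark.parametrize(
    "outcome, expectation, expected", [(5, 5, 0), (10, 5, 5), (0, 5, -5)]
)
def test_rpe_is_outcome_minus_expectation(outcome, expectation, expected):
    assert compute_rpe(outcome, expectation) == expected


class TestPredictMoodSeries:
    def test_zero_betas_give_constant_baseline(self):
        session = make_session([2.0, 4.0, 1.0, 3.0])
        params = SubjectParams(m0=0.37, beta_e=0, beta_r=0, xi=0.3)
        pred = predict_mood_series(PRIMACY, params, session)
        assert np.allclose(pred, 0.37)

    def test_single_trial_primacy_hand_value(self):
        # first trial: E=0 (no history), R = outcome = 2, so mood is
        # m0 + beta_e*0 + beta_r*2 = 2.5, unclamped
        session = Session(
            "s", "random",
            [TrialRecord(1, 2.0, 0.0, 1.0, True, 2.0)],
            [],
        )
        params = SubjectParams(m0=0.5, beta_e=1.0, beta_r=1.0, xi=1.3)
        pred = predict_mood_at_trials(PRIMACY, params, session, [1])
        assert pred[0] == pytest.approx(2.5)

    def test_rating_beyond_session_rejected(self):
        session = make_session([1.0, 2.0, 3.0, 4.0])
        session.ratings[-1].after_trial = 99
        params = SubjectParams(m0=0.5, beta_e=0.01, beta_r=0.01)
        with pytest.raises(ValueError):
            predict_mood_series(PRIMACY, params, session)

    def test_certain_trials_route_streams_per_model(self):
        flags = [True, False, True, False]
        session = make_session([2.0, 1.0, 4.0, 1.0], gamble_flags=flags)
        x_rec = regressor_streams(RECENCY, session)
        # recency: C only on certain trials, E/R only on gamble trials
        assert np.all((x_rec[:, 0] != 0) == ~np.array(flags))
        assert np.all((x_rec[:, 1] == 0) == ~np.array(flags))
        x_pri = regressor_streams(PRIMACY, session)
        # primacy: E on every trial past the first, no C stream
        assert x_pri.shape[1] == 2
        assert np.all(x_pri[1:, 0] != 0)

    @settings(max_examples=200, deadline=None)
    @given(st.data())
    def test_direct_summation_matches_incremental(self, data):
        """Brute-force O(t^2) discounted sums agree with the recursion."""
        n = data.draw(st.integers(2, 20))
        outcomes = data.draw(
            st.lists(st.floats(-5, 5), min_size=n, max_size=n)
        )
        gamma = data.draw(st.floats(0.05, 0.95))
        spec = data.draw(st.sampled_from([PRIMACY, RECENCY]))
        session = make_session(outcomes)
        x = regressor_streams(spec, session)
        s_inc = discounted_sums(x, gamma)
        t_idx = n - 1
        direct = sum(
            gamma ** (t_idx - j) * x[j] for j in range(t_idx + 1)
        )
        assert np.allclose(s_inc[t_idx], direct, atol=1e-10)

    def test_against_naive_reimplementation(self):
        """Full-stack oracle: an independent pure-python evaluation of the
        recency and primacy predictions on a mixed-choice session."""
        flags = [True, False, True, True, False, True]
        outcomes = [2.0, 1.5, 4.0, 0.5, 2.5, 3.0]
        session = make_session(outcomes, gamble_flags=flags)
        params = SubjectParams(
            m0=0.4, beta_e=0.03, beta_r=0.02, beta_c=0.05, xi=0.4
        )
        gamma = params.gamma

        def naive(spec, t):
            total = params.m0
            for j in range(1, t + 1):
                tr = session.trials[j - 1]
                disc = gamma ** (t - j)
                if spec is RECENCY:
                    if tr.chose_gamble:
                        e = (tr.high + tr.low) / 2
                        total += disc * (
                            params.beta_e * e
                            + params.beta_r * (tr.outcome - e)
                        )
                    else:
                        total += disc * params.beta_c * tr.certain
                else:
                    prior = [x.outcome for x in session.trials[: j - 1]]
                    e = sum(prior) / len(prior) if prior else 0.0
                    total += disc * (
                        params.beta_e * e + params.beta_r * (tr.outcome - e)
                    )
            return total

        for spec in (RECENCY, PRIMACY):
            got = predict_mood_at_trials(spec, params, session, [4, 6])
            assert got[0] == pytest.approx(naive(spec, 4), abs=1e-12)
            assert got[1] == pytest.approx(naive(spec, 6), abs=1e-12)


class TestInfluenceCurve:
    @pytest.mark.parametrize("gamma", [0.1, 0.5, 0.9])
    def test_recency_weights_increase_with_trial(self, gamma):
        params = SubjectParams(
            m0=0.5, beta_e=0.05, beta_r=0.03, beta_c=0.02,
            xi=xi_from_gamma(gamma),
        )
        # the model is linear in the perturbed trial values, so a coarse
        # step is exact and keeps the smallest weights above float noise
        w = influence_curve(RECENCY, params, 12, step=0.25)
        assert np.all(np.diff(w) > 0)
        # closed form: weights proportional to gamma^(n-i)
        ratio = w[1:] / w[:-1]
        assert np.allclose(ratio, 1 / gamma, rtol=1e-3)

    @pytest.mark.parametrize("gamma", [0.1, 0.5, 0.9])
    def test_primacy_expectation_weights_decrease(self, gamma):
        params = SubjectParams(
            m0=0.5, beta_e=0.05, beta_r=0.0, xi=xi_from_gamma(gamma)
        )
        w = influence_curve(PRIMACY, params, 12, step=0.25)
        assert np.all(np.diff(w) < 0)

    def test_final_outcome_has_no_expectation_influence(self):
        # the last outcome enters no expectation term yet
        params = SubjectParams(m0=0.5, beta_e=0.05, beta_r=0.0, xi=0.0)
        w = influence_curve(PRIMACY, params, 15)
        assert w[-1] == pytest.approx(0.0, abs=1e-8)

    def test_too_short_curve_rejected(self):
        params = SubjectParams(m0=0.5, beta_e=0.05, beta_r=0.0)
        with pytest.raises(ValueError):
            influence_curve(PRIMACY, params, 1)


def test_decayed_window_spec_reduces_to_primacy_prediction():
    session = make_session([1.0, 3.0, 2.0, 4.0, 0.5, 2.0])
    params = SubjectParams(m0=0.5, beta_e=0.02, beta_r=0.01, xi=0.2)
    wide = decayed_window_spec(1.0, 10_000)
    got = predict_mood_series(wide, params, session)
    want = predict_mood_series(PRIMACY, params, session)
    assert np.allclose(got, want, atol=1e-12)


def test_model_spec_validation():
    with pytest.raises(ValueError):
        ModelSpec("bad", "decayed_window", False, False)  # missing decay
    with pytest.raises(ValueError):
        ModelSpec("bad", "gamble_mean", True, True, decay=0.5, t_max=3)
    assert RECENCY.stream_names == ("C", "E", "R")
    assert PRIMACY.stream_names == ("E", "R")
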