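"""Value updating, the biased choice rule, and sequence likelihoods."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from punishlearn.core import (
    ActionValue,
    choice_probability,
    initial_values_from_pretest,
    prediction_error,
    sequence_log_likelihood,
    update_value,
)
from punishlearn.data import ConfigError, DataError, TrialObservation
from punishlearn.models import ParamVector, model_spec

from conftest import make_dataset, pretest_trials
from oracles import brute_force_loglik

values = st.floats(0.0, 1.0, allow_nan=False)
betas = st.floats(0.01, 10.0, allow_nan=False)
biases = st.floats(-3.0, 3.0, allow_nan=False)


@pytest.mark.parametrize("value, reward, expected", [
    (0.5, 1, 0.5),
    (1.0, 1, 0.0),
    (0.0, 0, 0.0),
    (0.25, 0, -0.25),
])
def test_prediction_error_is_reward_minus_value(value, reward, expected):
    assert prediction_error(value, reward) == pytest.approx(expected)


@pytest.mark.parametrize("bad", [2, -1, 0.5])
def test_prediction_error_rejects_non_binary_reward(bad):
    with pytest.raises(ValueError):
        prediction_error(0.5, bad)


def test_update_moves_chosen_value_by_alpha_times_pe():
    v = ActionValue(0.1, 0.5, "ingroup")
    out = update_value(v, "punish", 0.5, 1)
    assert out.v_punish == pytest.approx(0.75)
    assert out.v_accept == pytest.approx(0.1)  # unchosen value untouched


@pytest.mark.parametrize("alpha, reward, expected", [
    (0.0, 1, 0.2),   # no learning
    (1.0, 1, 1.0),   # full update to the reward
    (0.25, 0, 0.15),
])
def test_update_value_limits(alpha, reward, expected):
    v = ActionValue(0.9, 0.2, "outgroup")
    assert update_value(v, "punish", alpha, reward).v_punish == \
        pytest.approx(expected)


def test_update_value_rejects_alpha_outside_unit_interval():
    with pytest.raises(ValueError):
        update_value(ActionValue(0.5, 0.5), "accept", 1.5, 1)


def test_equal_values_give_even_odds():
    p_acc, p_pun = choice_probability(ActionValue(0.4, 0.4), beta=0.7)
    assert p_acc == pytest.approx(0.5)
    assert p_pun == pytest.approx(0.5)


def test_choice_probability_known_point():
    # 1 / (1 + exp(-(0.75 - 0.25) / 1)) evaluated independently
    p_acc, _ = choice_probability(ActionValue(0.75, 0.25), beta=1.0)
    assert p_acc == pytest.approx(0.622459331, abs=1e-9)


def test_large_ingroup_bias_forces_acceptance():
    v = ActionValue(0.5, 0.5, "ingroup")
    p_acc, _ = choice_probability(v, beta=1.0, bias=1e4)
    assert p_acc == pytest.approx(1.0, abs=1e-12)
    # the bias never touches outgroup trials
    p_out, _ = choice_probability(v, beta=1.0, bias=1e4, group="outgroup")
    assert p_out == pytest.approx(0.5)


def test_choice_probability_rejects_nonpositive_temperature():
    with pytest.raises(ValueError):
        choice_probability(ActionValue(0.5, 0.5), beta=0.0)


@settings(max_examples=200, deadline=None)
@given(va=values, vp=values, beta=betas, bias=biases)
def test_probabilities_normalize_and_match_softmax_at_zero_bias(
        va, vp, beta, bias):
    v = ActionValue(va, vp, "ingroup")
    p_acc, p_pun = choice_probability(v, beta, bias)
    assert p_acc + p_pun == pytest.approx(1.0, abs=0.0)
    # with the bias off, the rule must equal the plain two-action softmax
    p0, _ = choice_probability(v, beta, bias=0.0)
    ref = math.exp(va / beta) / (math.exp(va / beta) + math.exp(vp / beta))
    assert abs(p0 - ref) < 1e-12


def test_accept_probability_increases_with_value_difference_and_bias():
    diffs = np.linspace(-1, 1, 21)
    ps = [choice_probability(ActionValue(0.5 + d / 2, 0.5 - d / 2), 0.8)[0]
          for d in diffs]
    assert np.all(np.diff(ps) > 0)
    ps_bias = [choice_probability(ActionValue(0.5, 0.5, "ingroup"), 0.8, b)[0]
               for b in np.linspace(-2, 2, 21)]
    assert np.all(np.diff(ps_bias) > 0)


@settings(max_examples=100, deadline=None)
@given(steps=st.lists(st.tuples(st.sampled_from(["accept", "punish"]),
                                st.integers(0, 1),
                                st.floats(0.0, 1.0)),
                      max_size=50),
       v0=st.tuples(values, values))
def test_values_stay_in_unit_interval_under_any_update_sequence(steps, v0):
    v = ActionValue(v0[0], v0[1])
    for action, reward, alpha in steps:
        v = update_value(v, action, alpha, reward)
        assert 0.0 <= v.v_accept <= 1.0
        assert 0.0 <= v.v_punish <= 1.0


@pytest.mark.parametrize("n_punish, expected_vp", [(5, 1.0), (2, 0.4), (0, 0.0)])
def test_initial_values_are_pretest_choice_proportions(n_punish, expected_vp):
    trials = pretest_trials({"ingroup": n_punish})
    av = initial_values_from_pretest(trials, "ingroup")
    assert av.v_punish == pytest.approx(expected_vp)
    assert av.v_accept == pytest.approx(1.0 - expected_vp)


def test_initial_values_require_pretest_trials_for_the_group():
    with pytest.raises(ConfigError):
        initial_values_from_pretest(pretest_trials({"ingroup": 2}), "outgroup")


def test_single_balanced_trial_likelihood_is_log_half():
    # 4 pre-test trials with 2 punishes -> v_accept = v_punish = 0.5
    ds = make_dataset(pretest_punish=(2, 2), n_pretest=4,
                      learning=[("ingroup", 1, "punish", "positive")])
    spec = model_spec("1a1b")
    params = ParamVector([0.3], [1.0])
    assert sequence_log_likelihood(ds, spec, params) == \
        pytest.approx(math.log(0.5))


def test_empty_learning_phase_gives_zero_loglik():
    ds = make_dataset(learning=[])
    assert sequence_log_likelihood(ds, model_spec("4a2b"),
                                   ParamVector([0.1] * 4, [1.0, 1.0])) == 0.0


def test_missing_feedback_on_learning_trial_is_a_data_error():
    ds = make_dataset()
    ds.trials.append(TrialObservation(phase="learning",
                                      divider_group="ingroup", block=1,
                                      trial_index=1, action="punish"))
    with pytest.raises(DataError):
        sequence_log_likelihood(ds, model_spec("1a1b"),
                                ParamVector([0.5], [1.0]))


def test_four_trial_sequence_matches_hand_unrolled_recursion():
    rows = [("ingroup", 1, "punish", "positive"),
            ("ingroup", 1, "accept", "negative"),
            ("outgroup", 1, "punish", "negative"),
            ("outgroup", 2, "punish", "positive")]
    ds = make_dataset(pretest_punish=(1, 3), learning=rows)
    spec = model_spec("4a2b")
    params = ParamVector([1.0, 1.0, 1.0, 1.0], [1.0, 1.0])
    expected = brute_force_loglik(
        [{"group": g, "block": b, "action": a,
          "reward": 1 if f == "positive" else 0} for g, b, a, f in rows],
        v0={"ingroup": (0.8, 0.2), "outgroup": (0.4, 0.6)},
        alphas={(g, b): 1.0 for g in ("ingroup", "outgroup") for b in (1, 2)},
        betas={"ingroup": 1.0, "outgroup": 1.0})
    assert sequence_log_likelihood(ds, spec, params) == \
        pytest.approx(expected, abs=1e-12)


def test_all_32_five_trial_sequences_match_brute_force():
    """Exhaustive check of the recursion against an independent oracle."""
    spec = model_spec("4a2b_bias")
    params = ParamVector([0.3, 0.5, 0.7, 0.2], [0.5, 1.3], 0.3)
    layout = [("ingroup", 1), ("ingroup", 1), ("ingroup", 2),
              ("outgroup", 1), ("outgroup", 2)]
    rewards = [1, 0, 1, 1, 0]
    for actions in itertools.product(["accept", "punish"], repeat=5):
        rows = [(g, b, a, "positive" if r == 1 else "negative")
                for (g, b), a, r in zip(layout, actions, rewards)]
        ds = make_dataset(pretest_punish=(2, 4), learning=rows)
        got = sequence_log_likelihood(ds, spec, params)
        want = brute_force_loglik(
            [{"group": g, "block": b, "action": a, "reward": r}
             for (g, b), a, r in zip(layout, actions, rewards)],
            v0={"ingroup": (0.6, 0.4), "outgroup": (0.2, 0.8)},
            alphas={("ingroup", 1): 0.3, ("ingroup", 2): 0.5,
                    ("outgroup", 1): 0.7, ("outgroup", 2): 0.2},
            betas={"ingroup": 0.5, "outgroup": 1.3}, bias=0.3)
        assert abs(got - want) < 1e-10
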