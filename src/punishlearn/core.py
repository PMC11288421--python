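"""Rescorla-Wagner value learning and the biased choice rule.

On each learning trial the chosen action's expected value is updated by
a fraction alpha of the prediction error (reward minus expectation),

    V[t+1](a) = V[t](a) + alpha * (R[t] - V[t](a)),

with R = 1 for positive and 0 for negative social feedback.  Choice
probabilities follow a two-action softmax on the accept-minus-punish
value difference divided by the temperature beta; for ingroup dividers
an additive bias term shifts that difference toward acceptance:

    P(accept) = logistic((V(accept) - V(punish) + Bias(group)) / beta),

where Bias(group) = bias for ingroup dividers (when the model carries a
bias term) and 0 otherwise.  This is the unique normalized two-action
form of the biased rule: P(accept) + P(punish) = 1 for every parameter
setting and it reduces to the plain softmax at bias = 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np

from . import _kernel
from .data import (
    ConfigError,
    DataError,
    GROUPS,
    ParticipantDataset,
    TrialObservation,
    compile_learning_arrays,
)
from .models import ModelSpec, ParamVector

__all__ = [
    "ActionValue",
    "prediction_error",
    "update_value",
    "choice_probability",
    "initial_values_from_pretest",
    "sequence_log_likelihood",
]


@dataclass(frozen=True)
class ActionValue:
    """Expected values of the two actions in one divider-group context."""

    v_accept: float
    v_punish: float
    context: str = "ingroup"

    def __post_init__(self) -> None:
        if self.context not in GROUPS:
            raise ValueError(f"unknown divider group {self.context!r}")

    def chosen(self, action: str) -> float:
        return self.v_accept if action == "accept" else self.v_punish


def prediction_error(value: float, reward: int) -> float:
    """Reward minus the chosen action's expected value; lies in [-1, 1]."""
    if reward not in (0, 1):
        raise ValueError(f"reward must be 0 or 1, got {reward!r}")
    return float(reward) - float(value)


def update_value(value: ActionValue, chosen_action: str, alpha: float,
                 reward: int) -> ActionValue:
    """Update only the chosen action's value by alpha times the PE."""
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"learning rate must lie in [0, 1], got {alpha}")
    if chosen_action not in ("accept", "punish"):
        raise ValueError(f"unknown action {chosen_action!r}")
    pe = prediction_error(value.chosen(chosen_action), reward)
    if chosen_action == "accept":
        return ActionValue(value.v_accept + alpha * pe, value.v_punish,
                           value.context)
    return ActionValue(value.v_accept, value.v_punish + alpha * pe,
                       value.context)


def choice_probability(values: ActionValue, beta: float,
                       bias: Optional[float] = None,
                       group: Optional[str] = None) -> Tuple[float, float]:
    """(P(accept), P(punish)) under the biased two-action softmax.

    The bias enters only for ingroup dividers; pass ``bias=None`` (or 0)
    for models without the term.  ``group`` defaults to the context of
    ``values``.
    """
    if beta <= 0:
        raise ValueError(f"temperature must be strictly positive, got {beta}")
    if group is None:
        group = values.context
    if group not in GROUPS:
        raise ValueError(f"unknown divider group {group!r}")
    shift = bias if (bias is not None and group == "ingroup") else 0.0
    x = (values.v_accept - values.v_punish + shift) / beta
    if x >= 0.0:
        p_accept = 1.0 / (1.0 + math.exp(-x))
    else:
        e = math.exp(x)
        p_accept = e / (1.0 + e)
    return p_accept, 1.0 - p_accept


def initial_values_from_pretest(pretest_trials: Sequence[TrialObservation],
                                group: str) -> ActionValue:
    """Initial values: the pre-test choice proportions for one group.

    v_punish is the fraction of pre-test trials of ``group`` on which the
    participant punished; v_accept is its complement.
    """
    if group not in GROUPS:
        raise ValueError(f"unknown divider group {group!r}")
    relevant = [t for t in pretest_trials
                if t.phase == "pretest" and t.divider_group == group]
    if not relevant:
        raise ConfigError(
            f"no pre-test trials for {group}; supply explicit initial values"
        )
    if any(t.action is None for t in relevant):
        raise DataError("pre-test trials must carry actions")
    n_punish = sum(1 for t in relevant if t.action == "punish")
    v_punish = n_punish / len(relevant)
    return ActionValue(1.0 - v_punish, v_punish, group)


def sequence_log_likelihood(dataset: ParticipantDataset, spec: ModelSpec,
                            params: ParamVector) -> float:
    """Summed log probability of the observed learning-phase choices.

    Values are initialized per divider group from the participant's
    pre-test choice proportions and updated after every learning trial
    with the alpha slot selected by (group, block).  Pre- and post-test
    trials do not contribute.  An empty learning phase yields 0.0.
    """
    params.validate_for(spec)
    if dataset.n_learning_trials == 0:
        return 0.0
    arrays = compile_learning_arrays(dataset, spec)
    bias = params.bias if spec.has_bias else 0.0
    return float(_kernel.trial_log_likelihood(
        np.asarray(params.alphas, dtype=float),
        np.asarray(params.betas, dtype=float),
        float(bias), spec.has_bias,
        arrays["a_slot"], arrays["b_slot"], arrays["ingroup"],
        arrays["choice"], arrays["reward"], arrays["v0"],
    ))
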