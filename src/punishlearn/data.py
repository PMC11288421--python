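"""Trial-level data containers for the third-party punishment learning task.

The task has three phases. In the pre-test phase the participant (a
third-party observer) accepts or punishes 10 unfair allocations (5 by an
ingroup divider, 5 by an outgroup divider) without feedback. In the
learning phase there are 60 trials (2 divider groups x 2 blocks x 15
trials) and every choice is followed by probabilistic social feedback.
The post-test phase repeats the pre-test structure.

All categorical fields are lowercase string enums; this keeps CSV files
self-describing and prevents silent integer-coding swaps.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

PHASES = ("pretest", "learning", "posttest")
GROUPS = ("ingroup", "outgroup")
ACTIONS = ("accept", "punish")
FEEDBACKS = ("positive", "negative")
CONDITIONS = ("punish_enc", "accept_enc")


class DataError(ValueError):
    """Malformed trial data (schema violation, impossible field combination)."""


class ConfigError(ValueError):
    """Invalid configuration (distribution hyperparameters, missing defaults)."""


@dataclass(frozen=True)
class TrialObservation:
    """One task trial.

    ``trial_index`` is 1-based within (phase, divider_group); for the
    learning phase it spans both blocks (1-15 in block 1, 16-30 in
    block 2).  ``block`` is defined only for learning trials and
    ``feedback`` is present only on learning trials.  ``action`` or
    ``feedback`` may be ``None`` on schedule skeletons that have not been
    simulated yet.
    """

    phase: str
    divider_group: str
    trial_index: int
    block: Optional[int] = None
    action: Optional[str] = None
    feedback: Optional[str] = None

    def __post_init__(self) -> None:
        if self.phase not in PHASES:
            raise DataError(f"unknown phase {self.phase!r}")
        if self.divider_group not in GROUPS:
            raise DataError(f"unknown divider_group {self.divider_group!r}")
        if self.action is not None and self.action not in ACTIONS:
            raise DataError(f"unknown action {self.action!r}")
        if self.feedback is not None and self.feedback not in FEEDBACKS:
            raise DataError(f"unknown feedback {self.feedback!r}")
        if self.phase == "learning":
            if self.block not in (1, 2):
                raise DataError("learning trials must carry block 1 or 2")
        else:
            if self.block is not None:
                raise DataError(f"{self.phase} trials must not carry a block")
            if self.feedback is not None:
                raise DataError(f"{self.phase} trials must not carry feedback")
        if self.trial_index < 1:
            raise DataError("trial_index is 1-based")


@dataclass
class ParticipantDataset:
    """One participant's full trial sequence.

    Simulated participants additionally carry their generating parameters
    (``true_params``, a :class:`punishlearn.models.ParamVector`) and the
    ``model_id`` used to generate them.
    """

    participant_id: str
    condition: str
    trials: list = field(default_factory=list)
    true_params: Optional[object] = None
    model_id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise DataError(f"unknown condition {self.condition!r}")

    def phase_trials(self, phase: str) -> list:
        return [t for t in self.trials if t.phase == phase]

    @property
    def n_learning_trials(self) -> int:
        return sum(1 for t in self.trials if t.phase == "learning")

    def sorted_learning_trials(self) -> list:
        """Learning trials ordered by divider group, block, trial index.

        The two divider groups have independent value dynamics, so any
        interleaving of groups yields the same likelihood; within a group
        the block/trial order is the causal order and must be respected.
        """
        order = {g: i for i, g in enumerate(GROUPS)}
        return sorted(
            self.phase_trials("learning"),
            key=lambda t: (order[t.divider_group], t.block, t.trial_index),
        )


def compile_learning_arrays(dataset: ParticipantDataset, spec) -> dict:
    """Flatten a dataset's learning phase into numpy arrays for the kernels.

    Returns a dict with per-trial slot indices under ``spec``'s parameter
    sharing scheme, the choice/reward codes (choice 1 = accept, reward
    1 = positive feedback) and the pre-test-derived initial values
    ``v0 = [va_in, vp_in, va_out, vp_out]``.
    """
    from .core import initial_values_from_pretest

    trials = dataset.sorted_learning_trials()
    n = len(trials)
    a_slot = np.empty(n, dtype=np.int64)
    b_slot = np.empty(n, dtype=np.int64)
    ingroup = np.empty(n, dtype=np.int64)
    choice = np.empty(n, dtype=np.int64)
    reward = np.empty(n, dtype=np.float64)
    for i, t in enumerate(trials):
        if t.action is None or t.feedback is None:
            raise DataError(
                f"learning trial {t.trial_index} ({t.divider_group}) of "
                f"participant {dataset.participant_id} lacks action or feedback"
            )
        a_slot[i] = spec.alpha_index_map[(t.divider_group, t.block)]
        b_slot[i] = spec.beta_index_map[t.divider_group]
        ingroup[i] = 1 if t.divider_group == "ingroup" else 0
        choice[i] = 1 if t.action == "accept" else 0
        reward[i] = 1.0 if t.feedback == "positive" else 0.0

    v0 = np.empty(4, dtype=np.float64)
    pretest = dataset.phase_trials("pretest")
    for g, (ia, ip) in zip(GROUPS, ((0, 1), (2, 3))):
        av = initial_values_from_pretest(pretest, g)
        v0[ia] = av.v_accept
        v0[ip] = av.v_punish
    return {
        "a_slot": a_slot,
        "b_slot": b_slot,
        "ingroup": ingroup,
        "choice": choice,
        "reward": reward,
        "v0": v0,
    }


__all__ = [
    "PHASES",
    "GROUPS",
    "ACTIONS",
    "FEEDBACKS",
    "CONDITIONS",
    "DataError",
    "ConfigError",
    "TrialObservation",
    "ParticipantDataset",
    "compile_learning_arrays",
]
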