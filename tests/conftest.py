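"""Shared builders for compact hand-written trial datasets."""

from typing import Dict, Iterable, Optional, Sequence, Tuple

import pytest

from punishlearn.data import ParticipantDataset, TrialObservation


def pretest_trials(n_punish: Dict[str, int],
                   n_per_group: int = 5) -> list:
    """Pre-test trials with a given punish count per divider group."""
    trials = []
    for g, k in n_punish.items():
        for i in range(n_per_group):
            trials.append(TrialObservation(
                phase="pretest", divider_group=g, trial_index=i + 1,
                action="punish" if i < k else "accept"))
    return trials


def make_dataset(pid: str = "p1", condition: str = "punish_enc",
                 pretest_punish: Tuple[int, int] = (2, 2),
                 learning: Sequence[Tuple[str, int, str, str]] = (),
                 n_pretest: int = 5) -> ParticipantDataset:
    """Build a dataset from (group, block, action, feedback) learning rows.

    Learning trial indices are assigned 1-based per divider group in the
    listed order.
    """
    trials = pretest_trials({"ingroup": pretest_punish[0],
                             "outgroup": pretest_punish[1]}, n_pretest)
    counters: Dict[str, int] = {}
    for g, b, a, f in learning:
        counters[g] = counters.get(g, 0) + 1
        trials.append(TrialObservation(
            phase="learning", divider_group=g, block=b,
            trial_index=counters[g], action=a, feedback=f))
    return ParticipantDataset(participant_id=pid, condition=condition,
                              trials=trials)
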