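"""Task schedules, probabilistic social feedback, and simulated agents.

The generator reproduces the study design exactly: 10 pre-test trials
(5 per divider group, no feedback), 60 learning trials (2 divider
groups x 2 blocks x 15 trials) with probabilistic social feedback, and
10 post-test trials; every trial presents an unfair allocation.  Under
the punishment-encouragement condition, punishing yields positive
feedback with probability 0.8 and accepting with probability 0.2; the
acceptance-encouragement condition reverses the contingency.

Agents behave according to the Rescorla-Wagner family in
:mod:`punishlearn.core`.  Their pre-test choices are drawn from the
biased choice rule at neutral initial values (0.5/0.5); learning-phase
values are then initialized from the agent's own simulated pre-test,
exactly as the fitting pipeline initializes them for real participants.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np

from .core import ActionValue, choice_probability, initial_values_from_pretest, update_value
from .data import (
    CONDITIONS,
    ConfigError,
    GROUPS,
    ParticipantDataset,
    TrialObservation,
)
from .models import ModelSpec, ParamVector, model_spec

__all__ = [
    "TaskConfig",
    "PopulationSpec",
    "generate_schedule",
    "generate_feedback",
    "simulate_participant",
    "sample_population",
    "simulate_cohort",
]


@dataclass(frozen=True)
class TaskConfig:
    """Structure of the task; defaults are the study's design constants."""

    n_pretest_per_group: int = 5
    n_blocks: int = 2
    trials_per_block: int = 15
    condition: str = "punish_enc"
    p_positive_given_encouraged: float = 0.8
    p_positive_given_other: float = 0.2
    group_order: str = "randomized"  # ingroup_first | outgroup_first | randomized

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ConfigError(f"unknown condition {self.condition!r}")
        for p in (self.p_positive_given_encouraged, self.p_positive_given_other):
            if not 0.0 <= p <= 1.0:
                raise ConfigError("feedback probabilities must lie in [0, 1]")
        if self.group_order not in ("ingroup_first", "outgroup_first",
                                    "randomized"):
            raise ConfigError(f"unknown group_order {self.group_order!r}")

    @property
    def n_learning_trials(self) -> int:
        return len(GROUPS) * self.n_blocks * self.trials_per_block

    @property
    def encouraged_action(self) -> str:
        return "punish" if self.condition == "punish_enc" else "accept"


#: supported distribution families: (name, *hyperparameters)
_FAMILIES = ("beta", "gamma", "normal", "point", "uniform")


@dataclass(frozen=True)
class PopulationSpec:
    """Distributions the agent population is drawn from.

    Each entry is ``(family, *hyperparameters)``: ``("beta", a, b)``,
    ``("gamma", shape, scale)``, ``("normal", mean, sd)``,
    ``("uniform", lo, hi)`` or ``("point", value)``.  Defaults: alpha
    near-uniform on (0, 1), beta with mass over the empirically plausible
    0-2 range, and a small positive ingroup-acceptance bias.
    """

    alpha_dist: Tuple = ("beta", 1.1, 1.1)
    beta_dist: Tuple = ("gamma", 2.0, 0.5)
    bias_dist: Tuple = ("normal", 0.05, 0.05)
    n_participants: int = 100
    condition_rule: str = "alternate"  # alternate | punish_enc | accept_enc
    seed: int = 0

    def __post_init__(self) -> None:
        for d in (self.alpha_dist, self.beta_dist, self.bias_dist):
            if not d or d[0] not in _FAMILIES:
                raise ConfigError(f"unknown distribution spec {d!r}")
            if d[0] == "point" and len(d) != 2:
                raise ConfigError("point distribution takes exactly one value")
            if d[0] != "point" and len(d) != 3:
                raise ConfigError(f"{d[0]} distribution takes two hyperparameters")
        if self.n_participants < 1:
            raise ConfigError("need at least one participant")
        if self.condition_rule not in ("alternate",) + CONDITIONS:
            raise ConfigError(f"unknown condition rule {self.condition_rule!r}")


def _draw(dist: Tuple, rng: np.random.Generator, size: int) -> np.ndarray:
    family = dist[0]
    if family == "point":
        return np.full(size, float(dist[1]))
    a, b = float(dist[1]), float(dist[2])
    if family == "beta":
        return rng.beta(a, b, size)
    if family == "gamma":
        if a <= 0 or b <= 0:
            raise ConfigError("gamma hyperparameters must be positive")
        return rng.gamma(a, b, size)
    if family == "normal":
        if b < 0:
            raise ConfigError("normal sd must be non-negative")
        return rng.normal(a, b, size)
    if family == "uniform":
        return rng.uniform(a, b, size)
    raise ConfigError(f"unknown family {family!r}")


def _clip_open_unit(x: np.ndarray) -> np.ndarray:
    return np.clip(x, 1e-9, 1.0 - 1e-9)


def sample_population(spec: PopulationSpec, model: ModelSpec,
                      rng: Optional[np.random.Generator] = None
                      ) -> List[ParamVector]:
    """Draw one ParamVector per participant; each alpha slot independent."""
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    n = spec.n_participants
    alphas = _clip_open_unit(
        np.column_stack([_draw(spec.alpha_dist, rng, n)
                         for _ in range(model.n_alpha)]))
    betas = np.column_stack([np.maximum(_draw(spec.beta_dist, rng, n), 1e-6)
                             for _ in range(model.n_beta)])
    biases = _draw(spec.bias_dist, rng, n) if model.has_bias else None
    out = []
    for i in range(n):
        out.append(ParamVector(
            alphas=alphas[i], betas=betas[i],
            bias=float(biases[i]) if biases is not None else None))
    return out


def _resolve_order(config: TaskConfig, rng: np.random.Generator
                   ) -> Tuple[str, str]:
    if config.group_order == "ingroup_first":
        return ("ingroup", "outgroup")
    if config.group_order == "outgroup_first":
        return ("outgroup", "ingroup")
    return ("ingroup", "outgroup") if rng.random() < 0.5 else \
        ("outgroup", "ingroup")


def generate_schedule(config: TaskConfig = TaskConfig(),
                      seed: Union[int, np.random.Generator, None] = 0
                      ) -> List[TrialObservation]:
    """Emit the ordered trial skeleton (actions/feedback left unset).

    Pre- and post-test trials alternate divider groups; learning blocks
    alternate groups within each block round (first group, second group,
    then block 2 in the same group order).  Which group comes first is
    the per-participant randomized group order.
    """
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    first, second = _resolve_order(config, rng)
    trials: List[TrialObservation] = []

    def test_phase(phase: str) -> None:
        idx = {g: 0 for g in GROUPS}
        for i in range(2 * config.n_pretest_per_group):
            g = (first, second)[i % 2]
            idx[g] += 1
            trials.append(TrialObservation(phase=phase, divider_group=g,
                                           trial_index=idx[g]))

    test_phase("pretest")
    for block in range(1, config.n_blocks + 1):
        for g in (first, second):
            base = (block - 1) * config.trials_per_block
            for k in range(1, config.trials_per_block + 1):
                trials.append(TrialObservation(
                    phase="learning", divider_group=g, block=block,
                    trial_index=base + k))
    test_phase("posttest")
    return trials


def generate_feedback(action: str, condition: str,
                      rng: np.random.Generator,
                      config: Optional[TaskConfig] = None) -> str:
    """Bernoulli social feedback for one learning-phase choice."""
    cfg = config or TaskConfig(condition=condition)
    encouraged = "punish" if condition == "punish_enc" else "accept"
    p_pos = cfg.p_positive_given_encouraged if action == encouraged \
        else cfg.p_positive_given_other
    return "positive" if rng.random() < p_pos else "negative"


def simulate_participant(params: ParamVector, spec: ModelSpec,
                         schedule: Sequence[TrialObservation],
                         condition: str,
                         seed: Union[int, np.random.Generator, None] = 0,
                         participant_id: str = "sim",
                         pretest_initial: Tuple[float, float] = (0.5, 0.5),
                         task: Optional[TaskConfig] = None
                         ) -> ParticipantDataset:
    """Play the schedule with a Rescorla-Wagner agent; store ground truth.

    ``pretest_initial`` is the (v_accept, v_punish) pair used during the
    pre-test phase (the agent has no experience yet); learning-phase
    values are initialized from the agent's own simulated pre-test.
    """
    params.validate_for(spec)
    if condition not in CONDITIONS:
        raise ConfigError(f"unknown condition {condition!r}")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    task = task or TaskConfig(condition=condition)
    bias = params.bias if spec.has_bias else None

    values = {g: ActionValue(pretest_initial[0], pretest_initial[1], g)
              for g in GROUPS}
    out: List[TrialObservation] = []
    initialized = False
    for t in schedule:
        g = t.divider_group
        if t.phase == "learning" and not initialized:
            pre = [x for x in out if x.phase == "pretest"]
            values = {gr: initial_values_from_pretest(pre, gr)
                      for gr in GROUPS}
            initialized = True
        beta = params.betas[spec.beta_index_map[g]]
        p_accept, _ = choice_probability(values[g], beta, bias, g)
        action = "accept" if rng.random() < p_accept else "punish"
        if t.phase == "learning":
            feedback = generate_feedback(action, condition, rng, task)
            reward = 1 if feedback == "positive" else 0
            alpha = params.alphas[spec.alpha_index_map[(g, t.block)]]
            values[g] = update_value(values[g], action, alpha, reward)
            out.append(replace(t, action=action, feedback=feedback))
        else:
            out.append(replace(t, action=action))
    return ParticipantDataset(
        participant_id=participant_id, condition=condition, trials=out,
        true_params=params, model_id=spec.model_id)


def simulate_cohort(population: PopulationSpec,
                    model: Union[ModelSpec, str] = "4a2b_bias",
                    task: Optional[TaskConfig] = None,
                    seed: Optional[int] = None,
                    id_prefix: str = "sim") -> List[ParticipantDataset]:
    """Sample a population and simulate every agent through the task.

    The condition is assigned by ``population.condition_rule``
    (alternating, or fixed).  ``seed`` overrides ``population.seed``.
    """
    spec = model if isinstance(model, ModelSpec) else model_spec(model)
    root = np.random.default_rng(
        population.seed if seed is None else seed)
    params = sample_population(population, spec, rng=root)
    datasets = []
    for i, p in enumerate(params):
        if population.condition_rule == "alternate":
            condition = CONDITIONS[i % 2]
        else:
            condition = population.condition_rule
        cfg = task if task is not None else TaskConfig(condition=condition)
        if cfg.condition != condition:
            cfg = replace(cfg, condition=condition)
        schedule = generate_schedule(cfg, root)
        datasets.append(simulate_participant(
            p, spec, schedule, condition, seed=root,
            participant_id=f"{id_prefix}{i:05d}", task=cfg))
    return datasets
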