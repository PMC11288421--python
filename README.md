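# punishlearn

Reinforcement-learning models of group-biased altruistic punishment.

Third-party punishment tasks ask a bystander to accept or costly-punish
an unfair allocation made by an ingroup or outgroup member, while
probabilistic social feedback (thumbs up / thumbs down) encourages
either punishment or acceptance.  `punishlearn` provides, for
researchers studying social norm learning:

- an exact simulator of this task — 10 pre-test trials (5 per divider
  group, no feedback), 60 learning trials (2 divider groups × 2 blocks ×
  15 trials) with an 80%/20% feedback contingency, 10 post-test trials,
  all with unfair allocations — and agent populations with configurable
  parameter distributions;
- a six-member Rescorla–Wagner model family whose variants share or
  separate the learning rate α across divider groups and blocks, share
  or separate the temperature β across groups, and optionally include
  an ingroup acceptance bias;
- hierarchical MAP–EM fitting (empirical Bayes) and integrated-BIC
  model comparison, exposed as sklearn-style estimators;
- the validation experiments that accompany such an analysis:
  parameter-recovery confusion matrices and quadratic
  parameter-to-punishment-rate curves.

## The model

Values of the two actions (accept, punish) are updated after each
learning trial by a fraction α of the prediction error,

    V[t+1](a) = V[t](a) + α_{i(j)} · (R[t] − V[t](a)),

with R = 1 for positive and 0 for negative feedback, and only the chosen
action's value updated.  The subscript i is the divider group and j the
block, so the richest variants carry four learning rates.  Values are
initialized from each participant's pre-test choice proportions.
Choices follow a temperature-scaled two-action softmax with an additive
ingroup acceptance bias:

    P(accept) = 1 / (1 + exp(−(V(accept) − V(punish) + Bias(i)) / β)),

where Bias(i) = bias for ingroup dividers (in the bias-augmented model)
and 0 otherwise.  Subject-level parameters are estimated on an
unconstrained scale (logit for α, log for β) by maximizing the log
likelihood plus an independent Gaussian group prior; the prior's means
and variances are re-estimated from the subject estimates and their
inverse-Hessian uncertainty (EM), and models are compared by the
integrated BIC: a Monte-Carlo marginal likelihood under the fitted
group prior penalized by the group-level parameter count.

## Worked example

```python
from punishlearn import (PopulationSpec, simulate_cohort,
                         HierarchicalRescorlaWagner, punishment_rate)
from punishlearn.models import to_natural

pop = PopulationSpec(n_participants=40, condition_rule="punish_enc", seed=7)
cohort = simulate_cohort(pop, "4a2b_bias", seed=7)
print(punishment_rate(cohort, by=("divider_group",)).round(3))

est = HierarchicalRescorlaWagner(model="4a2b_bias", max_iterations=10,
                                 n_restarts=3, random_state=7).fit(cohort)
for k, v in to_natural(est.prior_.mu, est.spec_).as_dict(est.spec_).items():
    print(f"{k:12s} {v: .3f}")
```

prints

```
divider_group
ingroup     0.623
outgroup    0.624
alpha_in_b1   0.281
alpha_in_b2   0.227
alpha_out_b1  0.403
alpha_out_b2  0.374
beta_in       0.303
beta_out      0.582
bias          0.246
```

The punishment rates are each agent's proportion of punish choices per
divider group (averaged across blocks), here averaged over the cohort:
under punishment-encouragement the simulated agents punish well above
chance.  The fitted group-level means are the Gaussian prior means
mapped back to the natural scale — learning rates around 0.2–0.4,
temperatures below 1 (value-guided choice), and a positive ingroup
acceptance bias, i.e. the population-level tendencies of the generating
distributions as seen through 60 learning trials per agent.

A command line wraps the same pipeline:

```bash
punishlearn simulate --seed 1 --out runs/sim
punishlearn fit --trials runs/sim/trials.csv --model 4a2b_bias --out runs/fit
punishlearn compare --trials runs/sim/trials.csv --out runs/cmp
punishlearn recover --out runs/recovery
punishlearn curves --out runs/curves
```

## Layout

- `punishlearn.core` — value updates, prediction errors, the biased
  choice rule, sequence log likelihoods
- `punishlearn.models` — the six model specifications and link
  transforms
- `punishlearn.fit` — subject-level MAP, moment-matching M-step, the
  `HierarchicalRescorlaWagner` estimator
- `punishlearn.selection` — integrated BIC and `IntegratedBICComparison`
- `punishlearn.simulate` — schedules, feedback, agents, populations
- `punishlearn.experiments` — punishment rates, parameter recovery,
  rate curves
- `punishlearn.io`, `punishlearn.cli` — CSV/JSON readers and writers
  and the `punishlearn` command

See `docs/methods.md` for modelling assumptions, defaults, and known
limitations.
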