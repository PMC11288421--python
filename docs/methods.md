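# Methods

## Task and generative model

The simulated task reproduces the third-party punishment design the
package targets.  Each participant sees 80 unfair allocations: 10
pre-test trials (5 by an ingroup divider, 5 by an outgroup divider, no
feedback), 60 learning trials (2 divider groups × 2 blocks × 15 trials)
with probabilistic social feedback, and 10 post-test trials.  Under
punishment-encouragement, punishing draws positive feedback with
probability 0.8 and accepting with probability 0.2; under
acceptance-encouragement the contingency is reversed.  The on-screen
"60% approval" narrative of the original task is cover story; the
generative contingency is the 80/20 scheme and only that is modelled.
Which divider group comes first is a per-participant fair coin (seeded);
because the two groups' value dynamics are independent, this ordering
affects labels only, never likelihoods.

Agents are Rescorla–Wagner learners.  Only the chosen action's value is
updated, by `alpha * (reward - value)`; with rewards in {0, 1} and
`alpha` in [0, 1] values provably stay inside [0, 1].  Choice follows a
normalized two-action softmax on the accept-minus-punish value
difference divided by the temperature `beta`, with an additive ingroup
acceptance bias.  The published form of the biased rule applies the bias
inside the probability of only one action and therefore does not
normalize over two actions; we implement the unique normalized reading —
the bias shifts the value difference inside a single logistic and
P(punish) is the complement — which preserves the term's intended
direction (more ingroup acceptance, less ingroup punishment) and reduces
exactly to the plain softmax at bias = 0.  `beta` is a temperature
(values are divided by it), not an inverse temperature.

Six model variants share or separate parameters: `1a1b`, `2a1b`,
`2a2b`, `4a1b`, `4a2b` and `4a2b_bias` (α per group × block, β per
group, plus the bias).  Values are initialized per divider group from
the participant's pre-test punish proportion (`v_punish` = punish
count / 5, `v_accept` its complement).  Simulated agents' pre-test
choices are drawn from the biased rule at neutral 0.5/0.5 values, and
their learning phase then starts from their own simulated pre-test —
exactly how empirical data are initialized, so fitting treats simulated
and real participants identically.  Post-test trials are stored but
never enter likelihoods.

## Population distributions

Defaults for simulated populations: each α slot i.i.d. Beta(1.1, 1.1)
(near-uniform, spanning (0, 1)); β ~ Gamma(shape 2, scale 0.5) (mean 1,
mass over the plausible 0–2 range); bias ~ Normal(0.05, 0.05) (a small,
predominantly positive ingroup-acceptance bias).  All are overridable
per experiment.

The recovery and model-recovery studies use a deliberately different
population (`well_separated_population`): β ~ Gamma(2, 0.2) (mean 0.4,
matching the between-subject temperature means and spreads typically
estimated on this task) and bias ~ Normal(0.25, 0.25).  The reasoning:
at β near 1 the bounded value differences (at most 1) barely move the
choice probabilities, so 15-trial blocks carry almost no information
about α and no fitter could recover it — recovery should be assessed in
the regime where the model actually operates.  The bias must be clearly
non-zero on average to be decision-relevant (otherwise the bias model is
indistinguishable from `4a2b` and the model comparison is uninformative)
and must have spread above its single-subject estimation noise to be
recoverable, yet a much larger bias saturates ingroup choices and
erases the ingroup learning-rate information.

## Fitting

Bounded parameters are estimated on an unconstrained scale: logit link
for α, log link for β, identity for the bias.  The group prior is an
independent Gaussian per transformed parameter — this is what makes the
Gaussian prior density well-defined for bounded parameters.

E-step: each subject's transformed parameters maximize the sequence log
likelihood plus the log prior.  Optimization is L-BFGS-B with multiple
starts (prior mean plus seeded Gaussian jitter, sd 1.0; 5 starts by
default; later EM iterations warm-start from the previous estimate plus
the prior mean).  The best posterior wins, ties broken by first-found;
if every start fails the best evaluated point is returned flagged
non-converged.  The Hessian of the negative objective at the optimum is
computed by symmetrized central differences (step 1e-4), pseudo-inverted
(singular-value cutoff 1e-10), and negative diagonal entries are clamped
to zero (they indicate non-positive-definite local curvature).

M-step: `mu` is the mean of the subject estimates; `sigma2` is the mean
of (estimate² + inverse-Hessian diagonal) minus `mu²`, floored at 1e-6
to prevent prior collapse.  The loop starts from a near-flat prior
(means 0.1 plus seeded Normal(0, 0.01) noise, variances 100) and stops
when the summed per-subject log posterior changes by less than 0.001,
or after 800 iterations (both configurable; the convergence metric is
the absolute change of that sum).  A NaN total aborts with a diagnostic
naming the offending subject.  Per-trial choice probabilities are
floored at 1e-12 before logs; unconstrained parameters are clipped at
±40 before exponentiation inside the kernel.  The inner likelihood
loops are numba-compiled when numba is importable and fall back to pure
Python otherwise; the test suite checks them against an independent
brute-force recursion.

## Model comparison

The integrated BIC of a model is
`-2 * sum_i log p(D_i | prior) + 2 * n_params * log(N_choices)`, where
the per-subject marginal likelihood is a Monte-Carlo average of the
likelihood over draws from the fitted group prior (1,000 draws per
subject by default, log-sum-exp guarded, seeded) and the penalty counts
one mean and one variance per model parameter.  `N_choices` is the
total number of learning-phase choices across subjects; using the
number of subjects instead is a config option.  Only the ordinal
outcome of the comparison (which model ranks first) is treated as a
reproducible quantity; the absolute scores depend on the Monte-Carlo
sample count.

## Simulation experiments

Punishment rate is always the per-participant proportion of punish
choices per divider group within a block, averaged across blocks;
aggregates are means of participant-level rates.

Parameter recovery simulates agents from the bias-augmented model,
refits them with the hierarchical pipeline, and reports the full
Pearson correlation matrix between simulated and fitted parameters.
Zero-variance inputs yield NaN (undefined) entries rather than errors.
The historical reference ran 15,625 simulated participants; that count
is 5^6, suggesting a five-level factorial grid over six parameters, but
the construction is not recoverable, so the default here is random
sampling from the population spec with configurable n (200 in the
shipped validation run, which keeps the fit under a minute per EM
iteration on one CPU).

The rate-curve experiment simulates 5,000 agents per feedback condition
under the default population, pools (parameter value, punishment rate)
pairs across agents and parameter slots (each α slot pairs with its
divider group's across-block rate: 20,000 α pairs and 10,000 β pairs
per condition), and fits pooled agent-level OLS quadratics
`rate ~ p + p²` — pooled points rather than binned means.  The vertex
is `-b1/(2 b2)`; its uncertainty is assessed by seed-replicate spread,
not analytic standard errors, and a non-significant quadratic term
(p > 0.05) flags the fit degenerate.

Observed behavior of the shipped defaults: the α curves have an
interior maximum (punishment-encouragement) / minimum
(acceptance-encouragement) near 0.63–0.68.  The β relation is monotone
toward chance level in both conditions over the sampled range, so while
the fitted quadratic's curvature sign (and hence extremum type) is
stable, its vertex lands where the curve flattens, around 2.5–2.7 —
the vertex location for β is highly sensitive to the sampling
distribution of β and should be interpreted with that caveat.

## What the generator does and does not emulate

The generator reproduces the task structure, feedback contingencies and
the generative choice model exactly, so passing tests demonstrate
internal consistency of simulation, likelihood and fitting, and the
identifiability properties of the design.  It does not emulate human
data: no cultural or age covariates, no motivated deviation from the
RL policy, no fair allocations, no Player-2 compensation, no attention
lapses.  Conclusions about empirical effect sizes or group differences
require the human dataset and are out of scope.

## Known limitations

- Ingroup learning rates are intrinsically harder to recover than
  outgroup ones whenever the acceptance bias is positive: the bias
  tilts ingroup choices toward accept and 15-trial blocks then carry
  little information about ingroup value updating.  At the shipped
  recovery design their self-correlations sit near 0.4 while all other
  parameters exceed 0.5; more EM iterations or optimizer restarts do
  not change this (it is estimation noise, not optimizer quality).
- The group prior is independent per parameter; group-level covariance
  is not modelled.
- The EM point prior plus inverse-Hessian correction approximates, but
  is not, a full posterior; no MCMC or variational alternative is
  provided.
- The reader for the original study's deposited data format is not
  implemented (schema unknown); the long-format CSV defined in
  `punishlearn.io` is the interchange format.
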