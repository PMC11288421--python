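"""Hierarchical MAP estimation: E-step, M-step, and the EM loop."""

import math

import numpy as np
import pytest
from sklearn.base import clone

from punishlearn.data import ParticipantDataset
from punishlearn.fit import (
    EMConfig,
    GroupPrior,
    HierarchicalRescorlaWagner,
    SubjectFit,
    em_fit,
    m_step,
    subject_map_estimate,
)
from punishlearn.models import ParamVector, model_spec, to_natural
from punishlearn.simulate import (
    PopulationSpec,
    generate_schedule,
    simulate_cohort,
    simulate_participant,
    TaskConfig,
)

from conftest import make_dataset
from oracles import brute_force_loglik, logistic


def _toy_1a1b_dataset(alpha=0.6, beta=1.0, seed=5):
    """One simulated subject under the shared-parameter model."""
    spec = model_spec("1a1b")
    params = ParamVector([alpha], [beta])
    cfg = TaskConfig(condition="punish_enc", group_order="ingroup_first")
    schedule = generate_schedule(cfg, seed)
    return simulate_participant(params, spec, schedule, "punish_enc",
                                seed=seed), spec


def test_map_with_no_learning_trials_returns_prior_mean():
    ds = make_dataset(learning=[])
    spec = model_spec("2a1b")
    prior = GroupPrior(mu=np.array([-0.3, 0.4, 0.1]),
                       sigma2=np.array([0.5, 1.0, 2.0]))
    fit = subject_map_estimate(ds, spec, prior,
                               EMConfig(n_optimizer_restarts=2, seed=0))
    assert np.allclose(fit.eta, prior.mu, atol=1e-6)


def _pinned_beta_prior(sigma2_alpha):
    # beta pinned at 1 through a near-point prior on its log
    return GroupPrior(mu=np.array([0.0, 0.0]),
                      sigma2=np.array([sigma2_alpha, 1e-6]))


def _grid_search_alpha(ds, prior):
    """Exhaustive oracle for the 1-parameter toy posterior."""
    trials = [{"group": t.divider_group, "block": t.block,
               "action": t.action,
               "reward": 1 if t.feedback == "positive" else 0}
              for t in ds.sorted_learning_trials()]
    n_pun_in = sum(1 for t in ds.trials
                   if t.phase == "pretest" and t.divider_group == "ingroup"
                   and t.action == "punish") / 5.0
    n_pun_out = sum(1 for t in ds.trials
                    if t.phase == "pretest" and t.divider_group == "outgroup"
                    and t.action == "punish") / 5.0
    v0 = {"ingroup": (1 - n_pun_in, n_pun_in),
          "outgroup": (1 - n_pun_out, n_pun_out)}
    grid = np.arange(0.001, 1.0, 0.001)
    best, best_val = None, -np.inf
    for a in grid:
        eta = math.log(a / (1 - a))
        ll = brute_force_loglik(
            trials, v0,
            alphas={(g, b): a for g in ("ingroup", "outgroup")
                    for b in (1, 2)},
            betas={"ingroup": 1.0, "outgroup": 1.0})
        post = ll - 0.5 * eta ** 2 / prior.sigma2[0]
        if post > best_val:
            best, best_val = a, post
    return best


def test_map_estimate_matches_grid_search_on_one_parameter_toy():
    ds, spec = _toy_1a1b_dataset()
    prior = _pinned_beta_prior(1e6)  # effectively flat prior on alpha
    fit = subject_map_estimate(ds, spec, prior,
                               EMConfig(n_optimizer_restarts=3, seed=1))
    oracle_alpha = _grid_search_alpha(ds, prior)
    assert abs(fit.natural.alphas[0] - oracle_alpha) <= 1.5e-3


def test_strong_prior_shrinks_estimate_between_mle_and_prior_mean():
    ds, spec = _toy_1a1b_dataset(alpha=0.95, seed=11)
    flat = subject_map_estimate(ds, spec, _pinned_beta_prior(1e6),
                                EMConfig(n_optimizer_restarts=3, seed=2))
    tight = subject_map_estimate(ds, spec, _pinned_beta_prior(0.25),
                                 EMConfig(n_optimizer_restarts=3, seed=2))
    mle = flat.natural.alphas[0]
    shrunk = tight.natural.alphas[0]
    prior_mean_natural = logistic(0.0)
    lo, hi = sorted([prior_mean_natural, mle])
    assert lo < shrunk < hi


def test_hessian_corrections_are_non_negative():
    ds, spec = _toy_1a1b_dataset()
    fit = subject_map_estimate(ds, spec, _pinned_beta_prior(1.0),
                               EMConfig(n_optimizer_restarts=2, seed=3))
    assert np.all(fit.hessian_diag_inv >= 0)


def _stub_fit(eta, corr):
    eta = np.atleast_1d(np.asarray(eta, dtype=float))
    return SubjectFit("s", eta, None, 0.0,
                      np.atleast_1d(np.asarray(corr, dtype=float)), True, 1)


def test_m_step_two_point_moments():
    prior = m_step([_stub_fit(0.0, 0.0), _stub_fit(2.0, 0.0)])
    assert prior.mu[0] == pytest.approx(1.0)
    assert prior.sigma2[0] == pytest.approx(1.0)  # biased (/N) variance


def test_m_step_identical_subjects_hit_variance_floor():
    prior = m_step([_stub_fit(0.7, 0.0)] * 4)
    assert prior.mu[0] == pytest.approx(0.7)
    assert prior.sigma2[0] == pytest.approx(1e-6)


def test_m_step_matches_hand_computed_moment_formula():
    fits = [_stub_fit(0.5, 0.1), _stub_fit(1.0, 0.2), _stub_fit(1.5, 0.3)]
    prior = m_step(fits)
    # mean(eta^2 + corr) - mean(eta)^2 = (0.35 + 1.2 + 2.55)/3 - 1
    assert prior.mu[0] == pytest.approx(1.0)
    assert prior.sigma2[0] == pytest.approx(4.1 / 3.0 - 1.0)


def test_m_step_rejects_empty_input():
    with pytest.raises(ValueError):
        m_step([])


def test_em_recovers_population_mean_on_toy_cohort():
    """N=50 shared-alpha agents with mean 0.4: the fitted group mean on
    the natural scale lands within +/-0.1."""
    pop = PopulationSpec(alpha_dist=("beta", 8.0, 12.0),
                         beta_dist=("point", 0.5),
                         n_participants=50, seed=21)
    datasets = simulate_cohort(pop, "1a1b", seed=21)
    prior, fits, trace = em_fit(
        datasets, "1a1b",
        EMConfig(max_iterations=10, n_optimizer_restarts=2, seed=4))
    recovered = logistic(prior.mu[0])
    assert abs(recovered - 0.4) < 0.1
    assert len(trace) <= 10
    assert all(np.isfinite(trace))


def test_em_variance_collapses_for_identical_subjects():
    # an informative subject (low temperature) cloned five times: the
    # group variance keeps shrinking toward its floor across iterations
    ds, spec = _toy_1a1b_dataset(alpha=0.4, beta=0.3, seed=3)
    cohort = [ParticipantDataset(f"c{i}", ds.condition, list(ds.trials))
              for i in range(5)]
    short = HierarchicalRescorlaWagner(
        model="1a1b", max_iterations=3, n_restarts=2, random_state=5
    ).fit(cohort)
    long = HierarchicalRescorlaWagner(
        model="1a1b", max_iterations=12, n_restarts=2, random_state=5
    ).fit(cohort)
    assert np.all(long.prior_.sigma2 < 0.05)
    assert np.all(long.prior_.sigma2 <= short.prior_.sigma2 + 1e-12)


def test_em_is_bit_reproducible_given_the_seed():
    pop = PopulationSpec(n_participants=6, seed=9)
    datasets = simulate_cohort(pop, "4a2b_bias", seed=9)
    fit_a = HierarchicalRescorlaWagner(max_iterations=3, n_restarts=2,
                                       random_state=7).fit(datasets)
    fit_b = HierarchicalRescorlaWagner(max_iterations=3, n_restarts=2,
                                       random_state=7).fit(datasets)
    for a, b in zip(fit_a.subject_fits_, fit_b.subject_fits_):
        assert np.array_equal(a.eta, b.eta)
    assert np.array_equal(fit_a.prior_.mu, fit_b.prior_.mu)
    assert fit_a.trace_ == fit_b.trace_


def test_em_converges_on_small_cohort_before_iteration_cap():
    pop = PopulationSpec(alpha_dist=("beta", 2.0, 3.0),
                         beta_dist=("point", 0.5),
                         n_participants=12, seed=13)
    datasets = simulate_cohort(pop, "1a1b", seed=13)
    est = HierarchicalRescorlaWagner(
        model="1a1b", tolerance=0.3, max_iterations=80, n_restarts=2,
        random_state=8).fit(datasets)
    assert est.converged_
    assert est.n_iter_ < 80


def test_estimator_follows_sklearn_parameter_conventions():
    est = HierarchicalRescorlaWagner(model="2a2b", max_iterations=5)
    params = est.get_params()
    assert params["model"] == "2a2b"
    cloned = clone(est)
    assert cloned.get_params() == params
    cloned.set_params(model="1a1b")
    assert cloned.model == "1a1b"


def test_fit_requires_at_least_two_participants():
    ds = make_dataset()
    with pytest.raises(ValueError):
        HierarchicalRescorlaWagner().fit([ds])
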