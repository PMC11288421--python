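"""Hierarchical MAP estimation of model parameters (empirical Bayes EM).

Subject-level parameters eta (on the unconstrained scale) are estimated
by maximizing the per-subject log posterior

    sum_t log p_t(choice_t | eta, V0)  +  sum_k log N(eta_k | mu_k, sigma2_k)

(E-step), and the group-level Gaussian prior is then re-estimated by
moment matching (M-step):

    mu     = mean_i(eta_i)
    sigma2 = mean_i(eta_i^2 + diag(pinv(H_i))) - mu^2,

where H_i is the Hessian of the negative per-subject objective at the
optimum; its pseudo-inverted diagonal corrects the second moment for the
per-subject estimation uncertainty.  The two steps alternate until the
total posterior changes by less than the tolerance, or the iteration cap
is reached.

The public entry point is :class:`HierarchicalRescorlaWagner`, an
sklearn-style estimator whose ``fit`` takes a list of
:class:`~punishlearn.data.ParticipantDataset`.  The module-level
functions ``subject_map_estimate``, ``m_step`` and ``em_fit`` expose the
individual steps.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np
from scipy.optimize import minimize
from sklearn.base import BaseEstimator

from . import _kernel
from .data import ParticipantDataset, compile_learning_arrays
from .models import ModelSpec, ParamVector, model_spec, to_natural

logger = logging.getLogger(__name__)

#: elementwise floor applied to the group-level variances
SIGMA2_FLOOR = 1e-6
#: central finite-difference step for the Hessian, on the eta scale
HESSIAN_STEP = 1e-4
#: singular-value cutoff for the Hessian pseudo-inverse
PINV_RCOND = 1e-10
#: standard deviation of the jitter around the prior mean for restarts
RESTART_JITTER_SD = 1.0


@dataclass
class GroupPrior:
    """Independent Gaussian population prior on the transformed scale."""

    mu: np.ndarray
    sigma2: np.ndarray

    def __post_init__(self) -> None:
        self.mu = np.asarray(self.mu, dtype=float)
        self.sigma2 = np.asarray(self.sigma2, dtype=float)
        if self.mu.shape != self.sigma2.shape:
            raise ValueError("mu and sigma2 must have the same length")
        if np.any(self.sigma2 <= 0):
            raise ValueError("prior variances must be strictly positive")


@dataclass
class SubjectFit:
    """One subject's MAP estimate and curvature correction."""

    participant_id: str
    eta: np.ndarray
    natural: ParamVector
    log_posterior: float
    hessian_diag_inv: np.ndarray
    converged: bool
    n_restarts_used: int


@dataclass
class EMConfig:
    """Fitting configuration; defaults follow the hierarchical scheme's
    published settings (tolerance 0.001, at most 800 iterations, prior
    initialized at mu = 0.1 plus noise with variance 100)."""

    tolerance: float = 1e-3
    max_iterations: int = 800
    init_mu: float = 0.1
    init_mu_noise_sd: float = 0.01
    init_sigma2: float = 100.0
    n_optimizer_restarts: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be at least 1")
        if self.init_mu_noise_sd < 0 or self.init_sigma2 <= 0:
            raise ValueError("invalid prior initialization")
        if self.n_optimizer_restarts < 1:
            raise ValueError("need at least one optimizer start")


def _objective_args(dataset: ParticipantDataset, spec: ModelSpec):
    arrays = compile_learning_arrays(dataset, spec)
    return (spec.n_alpha, spec.n_beta, spec.has_bias,
            arrays["a_slot"], arrays["b_slot"], arrays["ingroup"],
            arrays["choice"], arrays["reward"], arrays["v0"])


def _finite_diff_hessian(fun, x: np.ndarray, step: float = HESSIAN_STEP
                         ) -> np.ndarray:
    """Central-difference Hessian, symmetrized."""
    n = x.size
    h = np.zeros((n, n))
    f0 = fun(x)
    for i in range(n):
        for j in range(i, n):
            if i == j:
                fp = fun(x + step * _unit(n, i))
                fm = fun(x - step * _unit(n, i))
                h[i, i] = (fp - 2.0 * f0 + fm) / step ** 2
            else:
                e_i, e_j = _unit(n, i), _unit(n, j)
                fpp = fun(x + step * e_i + step * e_j)
                fpm = fun(x + step * e_i - step * e_j)
                fmp = fun(x - step * e_i + step * e_j)
                fmm = fun(x - step * e_i - step * e_j)
                h[i, j] = h[j, i] = (fpp - fpm - fmp + fmm) / (4.0 * step ** 2)
    return 0.5 * (h + h.T)


def _unit(n: int, i: int) -> np.ndarray:
    e = np.zeros(n)
    e[i] = 1.0
    return e


def subject_map_estimate(dataset: ParticipantDataset, spec: ModelSpec,
                         prior: GroupPrior, config: EMConfig,
                         rng: Optional[np.random.Generator] = None,
                         extra_starts: Sequence[np.ndarray] = ()
                         ) -> SubjectFit:
    """Maximize one subject's log posterior over eta (multi-start).

    Starts are the prior mean plus seeded Gaussian jitters (and any
    ``extra_starts``, e.g. a warm start from the previous EM iteration);
    the best posterior wins, ties broken by first-found.  If every
    optimizer run fails the best evaluated point is returned with
    ``converged=False`` rather than raising.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if prior.mu.size != spec.n_params:
        raise ValueError("prior length does not match the model")
    args = _objective_args(dataset, spec)

    def nll(eta: np.ndarray) -> float:
        return _kernel.negative_log_posterior(
            np.ascontiguousarray(eta, dtype=float),
            prior.mu, prior.sigma2, *args)

    starts = [np.array(s, dtype=float) for s in extra_starts]
    starts.append(prior.mu.copy())
    for _ in range(config.n_optimizer_restarts - 1):
        starts.append(prior.mu + rng.normal(0.0, RESTART_JITTER_SD,
                                            size=prior.mu.size))

    best_x, best_f, ok, used = None, np.inf, False, 0
    for x0 in starts:
        used += 1
        try:
            res = minimize(nll, x0, method="L-BFGS-B")
        except Exception:  # pragma: no cover - optimizer blow-up guard
            continue
        f = float(res.fun)
        if np.isfinite(f) and f < best_f - 1e-12:
            best_x, best_f = np.asarray(res.x, dtype=float), f
            ok = ok or bool(res.success)
        elif best_x is None and np.isfinite(f):
            best_x, best_f = np.asarray(res.x, dtype=float), f
            ok = ok or bool(res.success)
    if best_x is None:  # every run failed; fall back to the best start
        fs = [nll(s) for s in starts]
        k = int(np.argmin(fs))
        best_x, best_f, ok = starts[k], float(fs[k]), False

    hess = _finite_diff_hessian(nll, best_x)
    diag = np.diag(np.linalg.pinv(hess, rcond=PINV_RCOND)).copy()
    diag[diag < 0] = 0.0  # negative curvature: not a PD local optimum
    return SubjectFit(
        participant_id=dataset.participant_id,
        eta=best_x,
        natural=to_natural(best_x, spec),
        log_posterior=-best_f,
        hessian_diag_inv=diag,
        converged=ok,
        n_restarts_used=used,
    )


def m_step(fits: Sequence[SubjectFit]) -> GroupPrior:
    """Moment-matching update of the group prior from subject fits."""
    if len(fits) == 0:
        raise ValueError("m_step requires at least one subject fit")
    etas = np.stack([f.eta for f in fits])
    corrections = np.stack([f.hessian_diag_inv for f in fits])
    mu = etas.mean(axis=0)
    sigma2 = (etas ** 2 + corrections).mean(axis=0) - mu ** 2
    sigma2 = np.maximum(sigma2, SIGMA2_FLOOR)
    return GroupPrior(mu=mu, sigma2=sigma2)


class HierarchicalRescorlaWagner(BaseEstimator):
    """Hierarchical MAP-EM fit of one candidate model to a cohort.

    Parameters
    ----------
    model : str, default "4a2b_bias"
        One of the six candidate model ids.
    tolerance : float
        Convergence threshold on the absolute change of the summed
        per-subject log posteriors between EM iterations.
    max_iterations : int
        EM iteration cap.
    init_mu, init_mu_noise_sd, init_sigma2 : float
        Prior initialization: every transformed-scale mean starts at
        ``init_mu`` plus seeded Gaussian noise; every variance at
        ``init_sigma2`` (a near-flat prior).
    n_restarts : int
        Optimizer starts per subject in the first E-step.  Later
        iterations warm-start from the previous estimate.
    random_state : int
        Seed for all randomness (prior jitter, restart jitter).

    Attributes
    ----------
    spec_ : ModelSpec
    prior_ : GroupPrior
    subject_fits_ : list of SubjectFit
    trace_ : list of float
        Total log posterior after each EM iteration.
    n_iter_ : int
    converged_ : bool
    """

    def __init__(self, model: str = "4a2b_bias", tolerance: float = 1e-3,
                 max_iterations: int = 800, init_mu: float = 0.1,
                 init_mu_noise_sd: float = 0.01, init_sigma2: float = 100.0,
                 n_restarts: int = 5, random_state: int = 0):
        self.model = model
        self.tolerance = tolerance
        self.max_iterations = max_iterations
        self.init_mu = init_mu
        self.init_mu_noise_sd = init_mu_noise_sd
        self.init_sigma2 = init_sigma2
        self.n_restarts = n_restarts
        self.random_state = random_state

    def _config(self) -> EMConfig:
        return EMConfig(
            tolerance=self.tolerance, max_iterations=self.max_iterations,
            init_mu=self.init_mu, init_mu_noise_sd=self.init_mu_noise_sd,
            init_sigma2=self.init_sigma2,
            n_optimizer_restarts=self.n_restarts, seed=self.random_state,
        )

    def fit(self, X: Sequence[ParticipantDataset], y=None):
        datasets = list(X)
        if len(datasets) < 2:
            raise ValueError("hierarchical fitting needs at least 2 participants")
        spec = model_spec(self.model)
        config = self._config()
        rng = np.random.default_rng(config.seed)

        mu = config.init_mu + rng.normal(0.0, config.init_mu_noise_sd,
                                         size=spec.n_params)
        prior = GroupPrior(mu=mu,
                           sigma2=np.full(spec.n_params, config.init_sigma2))

        trace: List[float] = []
        fits: List[SubjectFit] = []
        prev_total = None
        converged = False
        for iteration in range(config.max_iterations):
            new_fits = []
            for i, ds in enumerate(datasets):
                warm = (fits[i].eta,) if fits else ()
                # full multi-start only on the first pass; afterwards the
                # previous estimate plus the prior mean suffice
                cfg = config if not fits else EMConfig(
                    tolerance=config.tolerance,
                    max_iterations=config.max_iterations,
                    init_mu=config.init_mu,
                    init_mu_noise_sd=config.init_mu_noise_sd,
                    init_sigma2=config.init_sigma2,
                    n_optimizer_restarts=1, seed=config.seed)
                f = subject_map_estimate(ds, spec, prior, cfg, rng=rng,
                                         extra_starts=warm)
                if not np.isfinite(f.log_posterior):
                    raise RuntimeError(
                        f"posterior diverged for participant "
                        f"{ds.participant_id} at EM iteration {iteration + 1}"
                    )
                new_fits.append(f)
            fits = new_fits
            total = float(sum(f.log_posterior for f in fits))
            if not np.isfinite(total):
                raise RuntimeError("total posterior diverged (NaN)")
            trace.append(total)
            prior = m_step(fits)
            if prev_total is not None and abs(total - prev_total) < config.tolerance:
                converged = True
                break
            prev_total = total
        logger.info("EM for %s finished after %d iterations (converged=%s)",
                    self.model, len(trace), converged)

        self.spec_ = spec
        self.prior_ = prior
        self.subject_fits_ = fits
        self.trace_ = trace
        self.n_iter_ = len(trace)
        self.converged_ = converged
        return self

    def fitted_parameters(self):
        """Long-format DataFrame of natural/transformed estimates."""
        import pandas as pd

        rows = []
        for f in self.subject_fits_:
            nat = f.natural.as_dict(self.spec_)
            for k, name in enumerate(self.spec_.param_names):
                rows.append({
                    "participant_id": f.participant_id,
                    "model_id": self.spec_.model_id,
                    "parameter": name,
                    "natural": nat[name],
                    "transformed": float(f.eta[k]),
                    "hessian_correction": float(f.hessian_diag_inv[k]),
                })
        return pd.DataFrame(rows)


def em_fit(datasets: Sequence[ParticipantDataset],
           spec: Union[ModelSpec, str],
           config: Optional[EMConfig] = None
           ) -> Tuple[GroupPrior, List[SubjectFit], List[float]]:
    """Functional wrapper around :class:`HierarchicalRescorlaWagner`."""
    config = config or EMConfig()
    model_id = spec.model_id if isinstance(spec, ModelSpec) else spec
    est = HierarchicalRescorlaWagner(
        model=model_id, tolerance=config.tolerance,
        max_iterations=config.max_iterations, init_mu=config.init_mu,
        init_mu_noise_sd=config.init_mu_noise_sd,
        init_sigma2=config.init_sigma2,
        n_restarts=config.n_optimizer_restarts,
        random_state=config.seed,
    ).fit(datasets)
    return est.prior_, est.subject_fits_, est.trace_
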