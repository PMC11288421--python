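"""Hot numerical loops, JIT-compiled with numba when available.

The per-trial likelihood recursion is evaluated tens of thousands of
times inside the hierarchical fit, so it lives here as a flat function
over primitive arrays.  Correctness is established in the test suite
against an independent brute-force recursion, never against this code
itself.
"""

from __future__ import annotations

import math

import numpy as np

try:  # pragma: no cover - exercised implicitly on import
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]

        def deco(func):
            return func

        return deco


#: floor applied to per-trial choice probabilities before taking logs
P_FLOOR = 1e-12
#: clip for unconstrained parameters before exponentiation
ETA_CLIP = 40.0


@njit(cache=False)
def trial_log_likelihood(alphas, betas, bias, has_bias,
                         a_slot, b_slot, ingroup, choice, reward, v0):
    """Summed log choice probability over one learning-phase sequence.

    choice: 1 = accept, 0 = punish; reward: 1.0 positive, 0.0 negative.
    v0 = [va_in, vp_in, va_out, vp_out].  Values for the two divider
    groups evolve independently; only the chosen action's value is
    updated, by alpha * (reward - value).
    """
    va0, vp0 = v0[0], v0[1]
    va1, vp1 = v0[2], v0[3]
    total = 0.0
    for t in range(a_slot.shape[0]):
        ing = ingroup[t] == 1
        if ing:
            va, vp = va0, vp0
        else:
            va, vp = va1, vp1
        b = betas[b_slot[t]]
        x = va - vp
        if ing and has_bias:
            x += bias
        x /= b
        if x >= 0.0:
            p_acc = 1.0 / (1.0 + math.exp(-x))
        else:
            e = math.exp(x)
            p_acc = e / (1.0 + e)
        if choice[t] == 1:
            p = p_acc
        else:
            p = 1.0 - p_acc
        if p < P_FLOOR:
            p = P_FLOOR
        total += math.log(p)
        a = alphas[a_slot[t]]
        r = reward[t]
        if choice[t] == 1:
            va += a * (r - va)
        else:
            vp += a * (r - vp)
        if ing:
            va0, vp0 = va, vp
        else:
            va1, vp1 = va, vp
    return total


@njit(cache=False)
def natural_from_eta(eta, n_alpha, n_beta):
    """Map an unconstrained vector to (alphas, betas, bias).

    alpha = logistic(eta), beta = exp(eta), bias = identity.  eta is
    clipped to +/-ETA_CLIP before exponentiation to keep the optimizer's
    exploratory steps finite.
    """
    alphas = np.empty(n_alpha)
    for k in range(n_alpha):
        x = eta[k]
        if x > ETA_CLIP:
            x = ETA_CLIP
        elif x < -ETA_CLIP:
            x = -ETA_CLIP
        alphas[k] = 1.0 / (1.0 + math.exp(-x))
    betas = np.empty(n_beta)
    for k in range(n_beta):
        x = eta[n_alpha + k]
        if x > ETA_CLIP:
            x = ETA_CLIP
        elif x < -ETA_CLIP:
            x = -ETA_CLIP
        betas[k] = math.exp(x)
    bias = 0.0
    if eta.shape[0] > n_alpha + n_beta:
        bias = eta[n_alpha + n_beta]
    return alphas, betas, bias


@njit(cache=False)
def negative_log_posterior(eta, mu, sigma2, n_alpha, n_beta, has_bias,
                           a_slot, b_slot, ingroup, choice, reward, v0):
    """Negative (log likelihood + independent Gaussian log prior on eta)."""
    alphas, betas, bias = natural_from_eta(eta, n_alpha, n_beta)
    ll = trial_log_likelihood(alphas, betas, bias, has_bias,
                              a_slot, b_slot, ingroup, choice, reward, v0)
    lp = 0.0
    for k in range(eta.shape[0]):
        d = eta[k] - mu[k]
        lp += -0.5 * (d * d / sigma2[k] + math.log(2.0 * math.pi * sigma2[k]))
    return -(ll + lp)


@njit(cache=False)
def sample_log_likelihoods(etas, n_alpha, n_beta, has_bias,
                           a_slot, b_slot, ingroup, choice, reward, v0):
    """Log likelihood of one subject's sequence at each row of ``etas``."""
    out = np.empty(etas.shape[0])
    for k in range(etas.shape[0]):
        alphas, betas, bias = natural_from_eta(etas[k], n_alpha, n_beta)
        out[k] = trial_log_likelihood(alphas, betas, bias, has_bias,
                                      a_slot, b_slot, ingroup, choice,
                                      reward, v0)
    return out
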