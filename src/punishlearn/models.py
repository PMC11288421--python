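"""The candidate model family and its parameterization.

Six Rescorla-Wagner variants differ in how learning rates (alpha) and
temperatures (beta) are shared across divider groups (ingroup/outgroup)
and learning blocks (1/2), and in whether an ingroup acceptance bias
term is present:

====== ============================================ =========
id      parameter sharing                            bias
====== ============================================ =========
1a1b    one alpha, one beta                          no
2a1b    alpha per group, one beta                    no
2a2b    alpha per group, beta per group              no
4a1b    alpha per group x block, one beta            no
4a2b    alpha per group x block, beta per group      no
4a2b_bias  as 4a2b plus the ingroup bias term        yes
====== ============================================ =========

Bounded parameters are estimated on an unconstrained scale: alpha via a
logistic link, beta via an exponential link, bias via identity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Optional, Tuple

import numpy as np

from .data import GROUPS

MODEL_IDS = ("1a1b", "2a1b", "2a2b", "4a1b", "4a2b", "4a2b_bias")

#: margin used to clip alpha into (0, 1) and beta away from 0 before linking
_EPS = float(np.finfo(float).eps)


@dataclass(frozen=True)
class ModelSpec:
    """Which parameters are shared across groups/blocks, and bias presence."""

    model_id: str
    alpha_index_map: Dict[Tuple[str, int], int]
    beta_index_map: Dict[str, int]
    has_bias: bool

    def __post_init__(self) -> None:
        keys = {(g, b) for g in GROUPS for b in (1, 2)}
        if set(self.alpha_index_map) != keys:
            raise ValueError("alpha_index_map must cover all (group, block) pairs")
        if set(self.beta_index_map) != set(GROUPS):
            raise ValueError("beta_index_map must cover both divider groups")
        if self.n_alpha not in (1, 2, 4):
            raise ValueError("number of alpha slots must be 1, 2 or 4")
        if self.n_beta not in (1, 2):
            raise ValueError("number of beta slots must be 1 or 2")

    @property
    def n_alpha(self) -> int:
        return len(set(self.alpha_index_map.values()))

    @property
    def n_beta(self) -> int:
        return len(set(self.beta_index_map.values()))

    @property
    def n_params(self) -> int:
        return self.n_alpha + self.n_beta + (1 if self.has_bias else 0)

    @property
    def param_names(self) -> Tuple[str, ...]:
        if self.n_alpha == 1:
            alphas = ("alpha",)
        elif self.n_alpha == 2:
            alphas = ("alpha_in", "alpha_out")
        else:
            alphas = ("alpha_in_b1", "alpha_in_b2", "alpha_out_b1", "alpha_out_b2")
        if self.n_beta == 1:
            betas = ("beta",)
        else:
            betas = ("beta_in", "beta_out")
        return alphas + betas + (("bias",) if self.has_bias else ())


def _alpha_map(n: int) -> Dict[Tuple[str, int], int]:
    if n == 1:
        return {(g, b): 0 for g in GROUPS for b in (1, 2)}
    if n == 2:
        return {(g, b): i for i, g in enumerate(GROUPS) for b in (1, 2)}
    return {
        ("ingroup", 1): 0,
        ("ingroup", 2): 1,
        ("outgroup", 1): 2,
        ("outgroup", 2): 3,
    }


def _beta_map(n: int) -> Dict[str, int]:
    if n == 1:
        return {g: 0 for g in GROUPS}
    return {g: i for i, g in enumerate(GROUPS)}


_STRUCTURE = {
    "1a1b": (1, 1, False),
    "2a1b": (2, 1, False),
    "2a2b": (2, 2, False),
    "4a1b": (4, 1, False),
    "4a2b": (4, 2, False),
    "4a2b_bias": (4, 2, True),
}


def model_spec(model_id: str) -> ModelSpec:
    """Build the :class:`ModelSpec` for one of the six candidate models."""
    try:
        n_a, n_b, bias = _STRUCTURE[model_id]
    except KeyError:
        raise ValueError(
            f"unknown model {model_id!r}; choose from {MODEL_IDS}"
        ) from None
    return ModelSpec(model_id, _alpha_map(n_a), _beta_map(n_b), bias)


def all_model_specs() -> Tuple[ModelSpec, ...]:
    return tuple(model_spec(m) for m in MODEL_IDS)


@dataclass
class ParamVector:
    """Natural-scale parameter values for one agent or subject.

    ``alphas`` has one entry per alpha slot (each in (0, 1)), ``betas``
    one per beta slot (each > 0); ``bias`` is an unbounded real, present
    only for the bias model.
    """

    alphas: np.ndarray
    betas: np.ndarray
    bias: Optional[float] = None

    def __post_init__(self) -> None:
        self.alphas = np.asarray(self.alphas, dtype=float)
        self.betas = np.asarray(self.betas, dtype=float)
        if np.any(self.alphas < 0) or np.any(self.alphas > 1):
            raise ValueError("learning rates must lie in [0, 1]")
        if np.any(self.betas <= 0):
            raise ValueError("temperatures must be strictly positive")

    def validate_for(self, spec: ModelSpec) -> None:
        if len(self.alphas) != spec.n_alpha or len(self.betas) != spec.n_beta:
            raise ValueError(
                f"parameter vector shape ({len(self.alphas)} alphas, "
                f"{len(self.betas)} betas) does not match model {spec.model_id}"
            )
        if spec.has_bias and self.bias is None:
            raise ValueError(f"model {spec.model_id} requires a bias term")
        if not spec.has_bias and self.bias is not None:
            raise ValueError(f"model {spec.model_id} has no bias term")

    def as_dict(self, spec: ModelSpec) -> Dict[str, float]:
        vals = list(self.alphas) + list(self.betas)
        if spec.has_bias:
            vals.append(self.bias)
        return dict(zip(spec.param_names, (float(v) for v in vals)))


def to_transformed(params: ParamVector, spec: ModelSpec) -> np.ndarray:
    """Map natural parameters to the unconstrained estimation scale.

    alpha -> logit(alpha), beta -> log(beta), bias -> bias.  Values at
    the boundary of their domain are clipped inward by a machine-epsilon
    margin (with a warning) so the links stay finite.
    """
    params.validate_for(spec)
    alphas = np.asarray(params.alphas, dtype=float)
    betas = np.asarray(params.betas, dtype=float)
    if np.any(alphas <= 0) or np.any(alphas >= 1):
        warnings.warn("alpha at the boundary of (0, 1); clipping for the link")
        alphas = np.clip(alphas, _EPS, 1.0 - _EPS)
    if np.any(betas <= 0):
        warnings.warn("beta at 0; clipping for the link")
        betas = np.maximum(betas, _EPS)
    eta = np.concatenate(
        [np.log(alphas / (1.0 - alphas)), np.log(betas)]
    )
    if spec.has_bias:
        eta = np.append(eta, params.bias)
    return eta


def to_natural(eta: np.ndarray, spec: ModelSpec) -> ParamVector:
    """Inverse of :func:`to_transformed`."""
    eta = np.asarray(eta, dtype=float)
    if eta.shape != (spec.n_params,):
        raise ValueError(
            f"expected {spec.n_params} transformed values for {spec.model_id}, "
            f"got shape {eta.shape}"
        )
    n_a, n_b = spec.n_alpha, spec.n_beta
    alphas = 1.0 / (1.0 + np.exp(-eta[:n_a]))
    betas = np.exp(eta[n_a:n_a + n_b])
    bias = float(eta[n_a + n_b]) if spec.has_bias else None
    return ParamVector(alphas=alphas, betas=betas, bias=bias)
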