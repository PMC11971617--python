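"""Pattern probabilities, the normalizing constant, and the log-likelihood.

The marginal probability of score pattern ``y`` in the subpopulation
defined by a finite support ``B`` is

    P(Y = y | B) = tau_B * exp{ beta' x~ + K(alpha' y~) },

with dummy coding relative to the reference pattern ``y0`` and the
truncated conditional CGF ``K``.  ``tau_B`` normalizes over ``B``; all
work is done in log space because the raw weights span tens of orders of
magnitude in realistic fits.

For fixed ``alpha`` the model is a log-linear exponential family in
``(beta, shape)``; convexity of K in ``alpha`` makes the full
log-likelihood log-concave, so the maximum found by a gradient method
is global.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy.special import logsumexp, softmax

from .cgf import CGFSpec, Epsilons, cgf_derivative, h_coefficients
from .patterns import PatternCounts, TestDesign, dummy_code, dummy_matrices

__all__ = [
    "ModelParams",
    "NominalParams",
    "linear_predictor",
    "pattern_log_weight",
    "log_normalizer",
    "pattern_probabilities",
    "log_likelihood",
    "score_vector",
    "nominal_log_likelihood",
    "nominal_score_vector",
    "PatternEvaluator",
    "NominalEvaluator",
]


@dataclass(frozen=True)
class ModelParams:
    """Everything the pattern likelihood needs.

    ``beta`` stacks the transformed item-category locations (length
    ``sum m_i``), ``alpha`` the item scaling parameters (length k), and
    ``eps`` the convex-CGF shape coefficients.  ``support`` is the
    finite pattern set B over which probabilities are normalized; the
    reference pattern must belong to it, otherwise the model is
    degenerate.
    """

    design: TestDesign
    beta: np.ndarray
    alpha: np.ndarray
    eps: Epsilons
    y0: tuple[int, ...]
    support: np.ndarray  # (P, k) int

    def __post_init__(self) -> None:
        beta = np.asarray(self.beta, dtype=np.float64)
        alpha = np.asarray(self.alpha, dtype=np.float64)
        if beta.shape != (self.design.n_beta,):
            raise ValueError(f"beta must have length {self.design.n_beta}")
        if alpha.shape != (self.design.k,):
            raise ValueError(f"alpha must have length {self.design.k}")
        support = np.asarray(self.support, dtype=np.int64)
        if support.ndim != 2 or support.shape[1] != self.design.k:
            raise ValueError("support must be a (P, k) pattern array")
        y0 = self.design.validate_pattern(self.y0, where="y0")
        object.__setattr__(self, "beta", beta)
        object.__setattr__(self, "alpha", alpha)
        object.__setattr__(self, "support", support)
        object.__setattr__(self, "y0", y0)
        if not any(tuple(row) == y0 for row in support):
            raise ValueError("reference pattern y0 not in support B: model is degenerate")

    @property
    def spec(self) -> CGFSpec:
        return self.eps.spec

    @property
    def lambdas(self) -> np.ndarray:
        return h_coefficients(self.eps).lambdas

    def free_vector(self) -> np.ndarray:
        """Pack (beta, alpha, free eps) into one optimization vector."""
        return np.concatenate([self.beta, self.alpha, self.eps.free])

    def with_free_vector(self, theta: np.ndarray) -> "ModelParams":
        nb, k = self.design.n_beta, self.design.k
        theta = np.asarray(theta, dtype=np.float64)
        if theta.shape != (nb + k + self.spec.n_free,):
            raise ValueError("free-parameter vector has wrong length")
        return replace(
            self,
            beta=theta[:nb],
            alpha=theta[nb : nb + k],
            eps=self.spec.epsilons(theta[nb + k :]),
        )


@dataclass(frozen=True)
class NominalParams:
    """Nominal-response generalization: unrestricted category scalings.

    The CGF argument ``alpha' y~`` is replaced by ``eta' x~`` with one
    scaling per item-category slot; the partial credit structure is the
    special case ``eta_is = alpha_i * s``.
    """

    design: TestDesign
    beta: np.ndarray
    eta: np.ndarray  # length sum m_i
    eps: Epsilons
    y0: tuple[int, ...]
    support: np.ndarray

    def __post_init__(self) -> None:
        beta = np.asarray(self.beta, dtype=np.float64)
        eta = np.asarray(self.eta, dtype=np.float64)
        if beta.shape != (self.design.n_beta,) or eta.shape != (self.design.n_beta,):
            raise ValueError(f"beta and eta must have length {self.design.n_beta}")
        support = np.asarray(self.support, dtype=np.int64)
        y0 = self.design.validate_pattern(self.y0, where="y0")
        object.__setattr__(self, "beta", beta)
        object.__setattr__(self, "eta", eta)
        object.__setattr__(self, "support", support)
        object.__setattr__(self, "y0", y0)
        if not any(tuple(row) == y0 for row in support):
            raise ValueError("reference pattern y0 not in support B: model is degenerate")

    @property
    def spec(self) -> CGFSpec:
        return self.eps.spec

    @property
    def lambdas(self) -> np.ndarray:
        return h_coefficients(self.eps).lambdas

    def free_vector(self) -> np.ndarray:
        return np.concatenate([self.beta, self.eta, self.eps.free])

    def with_free_vector(self, theta: np.ndarray) -> "NominalParams":
        nb = self.design.n_beta
        theta = np.asarray(theta, dtype=np.float64)
        return replace(
            self,
            beta=theta[:nb],
            eta=theta[nb : 2 * nb],
            eps=self.spec.epsilons(theta[2 * nb :]),
        )

    @classmethod
    def from_gpcm(cls, params: ModelParams) -> "NominalParams":
        """Embed a partial-credit parameterization: eta_is = alpha_i * s."""
        eta = np.concatenate(
            [params.alpha[i] * np.arange(1, mi + 1) for i, mi in enumerate(params.design.m)]
        )
        return cls(
            design=params.design,
            beta=params.beta.copy(),
            eta=eta,
            eps=params.eps,
            y0=params.y0,
            support=params.support,
        )


def linear_predictor(alpha: Sequence[float], y_tilde: Sequence[float]) -> float:
    """The CGF argument ``u = alpha' y~`` for one pattern."""
    alpha = np.asarray(alpha, dtype=np.float64)
    y_tilde = np.asarray(y_tilde, dtype=np.float64)
    if alpha.shape != y_tilde.shape:
        raise ValueError("alpha and y_tilde must have equal length")
    return float(alpha @ y_tilde)


def pattern_log_weight(params: ModelParams, y: Sequence[int]) -> float:
    """Unnormalized log probability ``beta' x~ + K(alpha' y~)`` of one pattern."""
    coding = dummy_code(y, params.y0, params.design)
    u = linear_predictor(params.alpha, coding.y_tilde)
    return float(params.beta @ coding.x_tilde + cgf_derivative(u, 0, params.lambdas))


class PatternEvaluator:
    """Vectorized likelihood/score engine over a fixed support.

    Precomputes the dummy-coding matrices of the support once; the free
    parameter layout is ``[beta (sum m), alpha (k), free eps]``.
    """

    def __init__(self, params: ModelParams):
        self.params = params
        self.design = params.design
        self.X, self.Yt = dummy_matrices(params.support, params.y0, params.design)

    def counts_on_support(self, data: PatternCounts) -> np.ndarray:
        """Observed counts aligned to support rows (0 for unobserved)."""
        counts = np.zeros(len(self.params.support))
        index = {tuple(int(v) for v in row): i for i, row in enumerate(self.params.support)}
        for row, c in zip(data.patterns, data.counts):
            key = tuple(int(v) for v in row)
            if key not in index:
                raise ValueError(f"observed pattern {key} outside support B")
            counts[index[key]] = c
        return counts

    def log_weights(self, params: ModelParams | None = None) -> np.ndarray:
        p = params if params is not None else self.params
        u = self.Yt @ p.alpha
        return self.X @ p.beta + cgf_derivative(u, 0, p.lambdas)

    def log_normalizer(self, params: ModelParams | None = None) -> float:
        return -float(logsumexp(self.log_weights(params)))

    def probabilities(self, params: ModelParams | None = None) -> np.ndarray:
        return softmax(self.log_weights(params))

    def log_likelihood(self, params: ModelParams, counts: np.ndarray) -> float:
        w = self.log_weights(params)
        n = counts.sum()
        return float(counts @ w - n * logsumexp(w))

    def weight_jacobian(self, params: ModelParams) -> np.ndarray:
        """d(log weight)/d(free params), one row per support pattern."""
        u = self.Yt @ params.alpha
        lam = params.lambdas
        kprime = cgf_derivative(u, 1, lam)
        cols = [self.X, kprime[:, None] * self.Yt]
        cols.append(_eps_jacobian(u, params.eps))
        return np.hstack(cols)

    def score(self, params: ModelParams, counts: np.ndarray) -> np.ndarray:
        J = self.weight_jacobian(params)
        P = self.probabilities(params)
        return counts @ J - counts.sum() * (P @ J)


def _eps_jacobian(u: np.ndarray, eps: Epsilons) -> np.ndarray:
    """d K(u) / d(free eps), via dK/dh_c = u^{c+2} / ((c+1)(c+2)).

    ``dh_c/deps1_j = 2 eps1_{c-j}`` (zero out of range), same for eps2.
    """
    spec = eps.spec
    two_q = 2 * spec.q
    # basis_c = u^{c+2}/((c+1)(c+2)) for c = 0..2q
    powers = np.array([c + 2 for c in range(two_q + 1)])
    denom = np.array([(c + 1) * (c + 2) for c in range(two_q + 1)], dtype=np.float64)
    basis = (u[:, None] ** powers[None, :]) / denom[None, :]
    cols = []
    for j in range(1, spec.q + 1):
        dh = np.zeros(two_q + 1)
        for c in range(two_q + 1):
            jj = c - j
            if 0 <= jj <= spec.deg1:
                dh[c] = 2.0 * eps.eps1[jj]
        cols.append(basis @ dh)
    for j in range(1, spec.deg2 + 1):
        dh = np.zeros(two_q + 1)
        for c in range(two_q + 1):
            jj = c - j
            if 0 <= jj <= spec.deg2:
                dh[c] = 2.0 * eps.eps2[jj]
        cols.append(basis @ dh)
    if not cols:
        return np.zeros((len(u), 0))
    return np.column_stack(cols)


class NominalEvaluator:
    """Likelihood/score engine for the nominal-response generalization."""

    def __init__(self, params: NominalParams):
        self.params = params
        self.design = params.design
        self.X, self.Yt = dummy_matrices(params.support, params.y0, params.design)

    counts_on_support = PatternEvaluator.counts_on_support

    def log_weights(self, params: NominalParams | None = None) -> np.ndarray:
        p = params if params is not None else self.params
        u = self.X @ p.eta
        return self.X @ p.beta + cgf_derivative(u, 0, p.lambdas)

    def probabilities(self, params: NominalParams | None = None) -> np.ndarray:
        return softmax(self.log_weights(params))

    def log_likelihood(self, params: NominalParams, counts: np.ndarray) -> float:
        w = self.log_weights(params)
        n = counts.sum()
        return float(counts @ w - n * logsumexp(w))

    def weight_jacobian(self, params: NominalParams) -> np.ndarray:
        u = self.X @ params.eta
        kprime = cgf_derivative(u, 1, params.lambdas)
        return np.hstack(
            [self.X, kprime[:, None] * self.X, _eps_jacobian(u, params.eps)]
        )

    def score(self, params: NominalParams, counts: np.ndarray) -> np.ndarray:
        J = self.weight_jacobian(params)
        P = self.probabilities(params)
        return counts @ J - counts.sum() * (P @ J)


def log_normalizer(params: ModelParams) -> float:
    """``ln tau_B``: minus the log-sum-exp of the support's log weights."""
    return PatternEvaluator(params).log_normalizer()


def pattern_probabilities(params: ModelParams) -> dict[tuple[int, ...], float]:
    """Normalized pattern probabilities over the support B."""
    ev = PatternEvaluator(params)
    probs = ev.probabilities()
    return {tuple(int(v) for v in row): float(p) for row, p in zip(params.support, probs)}


def log_likelihood(params: ModelParams, data: PatternCounts) -> float:
    """Multinomial log-likelihood ``n ln tau_B + beta' n~ + sum n_y K(u_y)``."""
    ev = PatternEvaluator(params)
    return ev.log_likelihood(params, ev.counts_on_support(data))


def score_vector(params: ModelParams, data: PatternCounts) -> np.ndarray:
    """Analytic gradient of the log-likelihood in the free coordinates.

    Exponential-family form: observed minus model-expected sufficient
    statistics for beta, with the chain rule through K' (alpha) and
    through the h-convolutions (free eps).
    """
    ev = PatternEvaluator(params)
    return ev.score(params, ev.counts_on_support(data))


def nominal_log_likelihood(params: NominalParams, data: PatternCounts) -> float:
    ev = NominalEvaluator(params)
    return ev.log_likelihood(params, ev.counts_on_support(data))


def nominal_score_vector(params: NominalParams, data: PatternCounts) -> np.ndarray:
    ev = NominalEvaluator(params)
    return ev.score(params, ev.counts_on_support(data))
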