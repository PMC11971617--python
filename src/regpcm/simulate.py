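"""Synthetic response generation.

Two generators are provided:

* :func:`simulate_latent` draws person-level responses from the
  generative adjacent-category (partial credit) process: a latent trait
  per person from a pluggable density, then conditionally independent
  item scores with category odds
  ``P(Y_i = s | theta) / P(Y_i = s-1 | theta) = exp{alpha_i (theta - delta_is)}``.
  Normal, two-component normal mixture and shifted-gamma latent shapes
  are included because the fitted model is latent-distribution-free and
  must be exercised against non-normal traits.

* :func:`simulate_from_model` samples score patterns directly from a
  fitted discrete pattern distribution (multinomial over the support),
  the natural generator for parameter-recovery experiments.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .likelihood import ModelParams, PatternEvaluator
from .patterns import PatternCounts, TestDesign

__all__ = [
    "GenerativeGPCM",
    "latent_density",
    "category_probs",
    "simulate_latent",
    "simulate_from_model",
    "expected_pattern_frequencies",
]


def latent_density(name: str, **params) -> Callable[[int, np.random.Generator], np.ndarray]:
    """Named latent-trait samplers.

    ``normal(mu, sigma)``; ``mixture(mu1, sigma1, mu2, sigma2, w)`` a
    two-component normal mixture with weight ``w`` on the first
    component; ``shifted_gamma(shape)`` a gamma standardized to mean 0
    and variance 1 (skewness ``2/sqrt(shape)``).
    """
    if name == "normal":
        mu = params.get("mu", 0.0)
        sigma = params.get("sigma", 1.0)
        return lambda n, rng: rng.normal(mu, sigma, size=n)
    if name == "mixture":
        mu1, s1 = params.get("mu1", -1.0), params.get("sigma1", 0.5)
        mu2, s2 = params.get("mu2", 1.0), params.get("sigma2", 0.5)
        w = params.get("w", 0.5)

        def draw(n, rng):
            pick = rng.random(n) < w
            return np.where(pick, rng.normal(mu1, s1, n), rng.normal(mu2, s2, n))

        return draw
    if name == "shifted_gamma":
        shape = params.get("shape", 4.0)
        scale = 1.0 / np.sqrt(shape)  # unit variance
        loc = -shape * scale  # zero mean

        def draw(n, rng):
            return rng.gamma(shape, scale, size=n) + loc

        return draw
    raise ValueError(f"unknown latent density {name!r}")


@dataclass
class GenerativeGPCM:
    """Generative adjacent-category model with an explicit latent density."""

    design: TestDesign
    alpha: np.ndarray
    delta: list[np.ndarray]  # delta[i] has length m_i (thresholds delta_ia)
    theta_dist: Callable[[int, np.random.Generator], np.ndarray] = field(
        default_factory=lambda: latent_density("normal")
    )

    def __post_init__(self) -> None:
        self.alpha = np.asarray(self.alpha, dtype=np.float64)
        if self.alpha.shape != (self.design.k,):
            raise ValueError(f"alpha must have length k={self.design.k}")
        self.delta = [np.asarray(d, dtype=np.float64) for d in self.delta]
        for i, (d, mi) in enumerate(zip(self.delta, self.design.m)):
            if d.shape != (mi,):
                raise ValueError(f"delta[{i}] must have length m_i={mi}")


def category_probs(theta: float, item: int, model: GenerativeGPCM) -> np.ndarray:
    """Conditional category probabilities of one item at a trait value.

    ``P(Y_i = s | theta)`` is proportional to
    ``exp{alpha_i s theta - alpha_i sum_{a<=s} delta_ia}`` (empty sum
    for s = 0), so adjacent categories are equiprobable exactly at
    ``theta = delta_is``.
    """
    mi = model.design.m[item]
    s = np.arange(mi + 1)
    cumdelta = np.concatenate([[0.0], np.cumsum(model.delta[item])])
    logits = model.alpha[item] * (s * theta - cumdelta)
    logits -= logits.max()
    p = np.exp(logits)
    return p / p.sum()


def simulate_latent(
    model: GenerativeGPCM, n: int, seed: int | np.random.Generator
) -> pd.DataFrame:
    """Draw an n-person score table: trait, then items independently.

    A single seeded generator stream is consumed in person-major order,
    so outputs are bitwise reproducible for a given seed.
    """
    if n < 1:
        raise ValueError("need at least one person")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    theta = model.theta_dist(n, rng)
    scores = np.zeros((n, model.design.k), dtype=np.int64)
    # per-item category probabilities vectorized over persons
    for i, mi in enumerate(model.design.m):
        s = np.arange(mi + 1)
        cumdelta = np.concatenate([[0.0], np.cumsum(model.delta[i])])
        logits = model.alpha[i] * (np.outer(theta, s) - cumdelta[None, :])
        logits -= logits.max(axis=1, keepdims=True)
        p = np.exp(logits)
        p /= p.sum(axis=1, keepdims=True)
        cum = np.cumsum(p, axis=1)
        draws = rng.random(n)
        scores[:, i] = (draws[:, None] > cum[:, :-1]).sum(axis=1)
    return pd.DataFrame(scores, columns=[f"item{i + 1}" for i in range(model.design.k)])


def simulate_from_model(
    params: ModelParams, n: int, seed: int | np.random.Generator
) -> PatternCounts:
    """Multinomial pattern sample from a fitted discrete model."""
    if n < 1:
        raise ValueError("need at least one draw")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    probs = PatternEvaluator(params).probabilities()
    counts = rng.multinomial(n, probs)
    keep = counts > 0
    return PatternCounts(params.design, params.support[keep], counts[keep])


def expected_pattern_frequencies(params: ModelParams, n: int) -> pd.DataFrame:
    """Model-implied expected frequencies ``n * P(y | B)`` over the support."""
    from .patterns import format_pattern

    probs = PatternEvaluator(params).probabilities()
    return pd.DataFrame(
        {
            "pattern": [format_pattern(row) for row in params.support],
            "prob": probs,
            "expected": n * probs,
        }
    )
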