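"""Truncated conditional cumulant-generating function under convexity.

The latent variable Theta, conditioned on the reference score pattern,
enters the marginal pattern probabilities only through a degree-``v``
polynomial cumulant-generating function (CGF)

    K(u) = sum_{r=1}^{v} lambda_r u^r / r!,

whose coefficients ``lambda_r`` are the conditional cumulants for
``r <= v - 1``.  Convexity of K (equivalently, non-negativity of K'' on
the whole real line) is what makes the coefficients consistent with an
actual random variable, and it is enforced structurally: K'' is written
as a sum of two squared polynomials,

    K''(u) = p1(u)^2 + p2(u)^2,

with ``deg p1 = q = (v-2)/2`` and ``deg p2 in {q-1, q}``.  Expanding the
squares gives convolution coefficients ``h_c`` with
``lambda_{c+2} = c! * h_c``.  Identification fixes ``lambda_1 = 0`` and
``lambda_2 = 1`` by pinning the constant terms ``(eps1[0], eps2[0])`` to
a point on the unit circle; the free parameters are the remaining
polynomial coefficients.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import factorial
from typing import Sequence

import numpy as np

__all__ = [
    "CGFSpec",
    "Epsilons",
    "CGFCoefficients",
    "h_coefficients",
    "lambdas_from_h",
    "cgf_derivative",
    "second_derivative_sos",
]


@dataclass(frozen=True)
class CGFSpec:
    """Configuration of the convex CGF parameterization.

    Parameters
    ----------
    v:
        Even truncation order >= 2 of the CGF polynomial. ``v = 2`` is
        the normal (linear-homoscedastic) sub-model with no free shape
        parameters; ``v = 6`` admits skewness and kurtosis.
    deg2:
        Degree of the second squared polynomial, ``q - 1`` (parsimonious
        default) or ``q`` where ``q = (v - 2) / 2``. With ``deg2 = q``
        there are ``v - 2`` free shape parameters, with ``q - 1`` one
        fewer.
    eps_fixed:
        The fixed constant terms ``(eps1[0], eps2[0])``; must lie on the
        unit circle so that ``lambda_2 = h_0 = 1``.
    """

    v: int = 6
    deg2: int | None = None
    eps_fixed: tuple[float, float] = (0.6, 0.8)

    def __post_init__(self) -> None:
        if self.v < 2 or self.v % 2 != 0:
            raise ValueError("truncation order v must be an even integer >= 2")
        q = (self.v - 2) // 2
        deg2 = self.deg2
        if deg2 is None:
            deg2 = max(q - 1, 0)
            object.__setattr__(self, "deg2", deg2)
        if deg2 not in {max(q - 1, 0), q}:
            raise ValueError(f"deg2 must be {max(q - 1, 0)} or {q} for v={self.v}")
        e10, e20 = self.eps_fixed
        if abs(e10 * e10 + e20 * e20 - 1.0) > 1e-12:
            raise ValueError("eps_fixed must satisfy eps10^2 + eps20^2 = 1")

    @property
    def q(self) -> int:
        return (self.v - 2) // 2

    @property
    def deg1(self) -> int:
        return self.q

    @property
    def n_free(self) -> int:
        """Free shape-parameter count: coefficients of index >= 1."""
        return self.q + self.deg2

    def epsilons(self, free: Sequence[float] | None = None) -> "Epsilons":
        """Build full epsilon vectors from the free coefficients.

        ``free`` concatenates ``eps1[1:]`` (length q) and ``eps2[1:]``
        (length deg2); ``None`` gives the normal start (all zero).
        """
        if free is None:
            free = np.zeros(self.n_free)
        free = np.asarray(free, dtype=np.float64)
        if free.shape != (self.n_free,):
            raise ValueError(f"expected {self.n_free} free epsilon values")
        eps1 = np.concatenate([[self.eps_fixed[0]], free[: self.q]])
        eps2 = np.concatenate([[self.eps_fixed[1]], free[self.q :]])
        return Epsilons(eps1=eps1, eps2=eps2, spec=self)


@dataclass(frozen=True)
class Epsilons:
    """Coefficient vectors of the two squared polynomials."""

    eps1: np.ndarray  # length q + 1
    eps2: np.ndarray  # length deg2 + 1
    spec: CGFSpec

    def __post_init__(self) -> None:
        eps1 = np.asarray(self.eps1, dtype=np.float64)
        eps2 = np.asarray(self.eps2, dtype=np.float64)
        if eps1.shape != (self.spec.q + 1,):
            raise ValueError(f"eps1 must have length q+1 = {self.spec.q + 1}")
        if eps2.shape != (self.spec.deg2 + 1,):
            raise ValueError(f"eps2 must have length deg2+1 = {self.spec.deg2 + 1}")
        if abs(eps1[0] - self.spec.eps_fixed[0]) > 1e-12 or abs(
            eps2[0] - self.spec.eps_fixed[1]
        ) > 1e-12:
            raise ValueError("constant epsilon terms must match the spec's fixed values")
        object.__setattr__(self, "eps1", eps1)
        object.__setattr__(self, "eps2", eps2)

    @property
    def free(self) -> np.ndarray:
        return np.concatenate([self.eps1[1:], self.eps2[1:]])


@dataclass(frozen=True)
class CGFCoefficients:
    """Expanded polynomial coefficients of K'' and the cumulants."""

    h: np.ndarray  # h_0 .. h_{2q}
    lambdas: np.ndarray  # index r = 0..v; lambdas[0] unused, lambdas[1] = 0

    @property
    def v(self) -> int:
        return len(self.lambdas) - 1


def h_coefficients(eps: Epsilons) -> CGFCoefficients:
    """Expand ``p1^2 + p2^2`` into power-basis coefficients.

    ``h_c = sum_{j + j' = c} (eps1_j eps1_j' + eps2_j eps2_j')`` is the
    self-convolution of each coefficient vector; ``lambda_{c+2} = c! h_c``.
    """
    two_q = 2 * eps.spec.q
    h = np.zeros(two_q + 1)
    c1 = np.convolve(eps.eps1, eps.eps1)
    c2 = np.convolve(eps.eps2, eps.eps2)
    h[: len(c1)] += c1
    h[: len(c2)] += c2
    return CGFCoefficients(h=h, lambdas=lambdas_from_h(h, lambda1=0.0))


def lambdas_from_h(h: np.ndarray, lambda1: float = 0.0) -> np.ndarray:
    """Map K'' coefficients to cumulant-scale coefficients lambda_2..lambda_v."""
    h = np.asarray(h, dtype=np.float64)
    v = len(h) + 1
    lam = np.zeros(v + 1)
    lam[1] = lambda1
    for c, hc in enumerate(h):
        lam[c + 2] = factorial(c) * hc
    return lam


def cgf_derivative(u, j: int, lambdas: np.ndarray):
    """Evaluate the ``j``-th derivative of the truncated CGF.

    ``K^(j)(u) = sum_{r=max(j,1)}^{v} lambda_r u^(r-j) / (r-j)!`` so that
    ``j = 0`` is K itself, ``j = 1`` the conditional-mean polynomial and
    ``j = 2`` the conditional-variance polynomial. Vectorized over ``u``.
    """
    lambdas = np.asarray(lambdas, dtype=np.float64)
    v = len(lambdas) - 1
    if j < 0:
        raise ValueError("derivative order must be non-negative")
    if j > v:
        return np.zeros_like(np.asarray(u, dtype=np.float64))
    # Horner coefficients, highest power first: term r has power r - j.
    coeffs = []
    for r in range(v, max(j, 1) - 1, -1):
        coeffs.append(lambdas[r] / factorial(r - j))
    if j == 0:
        coeffs.append(0.0)  # K(0) = 0: no constant term
    return np.polyval(np.asarray(coeffs), u)


def second_derivative_sos(u, eps: Epsilons):
    """K'' evaluated directly as the sum of squares ``p1(u)^2 + p2(u)^2``."""
    p1 = np.polyval(eps.eps1[::-1], u)
    p2 = np.polyval(eps.eps2[::-1], u)
    return p1 * p1 + p2 * p2
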