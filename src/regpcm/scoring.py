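"""EAP person scoring and population moments of the latent variable.

Given a score pattern ``y``, the latent variable's conditional MGF is a
shift of the reference-pattern MGF, so its conditional cumulants are
polynomial evaluations of the fitted CGF derivatives at
``u = alpha' y~``:

    kappa_j|y = K^(j)(u).

``kappa_1|y`` is the EAP person score and ``kappa_2|y`` the posterior
variance; monotonicity and non-negativity are inherited from convexity
of K.  Population moments in the subpopulation B average per-pattern
non-central moments over the fitted pattern probabilities (law of total
expectation) and convert back to cumulants.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .cgf import cgf_derivative
from .fit import FitResult
from .likelihood import ModelParams, PatternEvaluator, linear_predictor
from .patterns import PatternCounts, dummy_code, format_pattern

__all__ = [
    "ConditionalMoments",
    "PopulationCumulants",
    "conditional_cumulants",
    "conditional_mgf",
    "eap_table",
    "noncentral_from_cumulants",
    "cumulants_from_noncentral",
    "population_moments",
]


@dataclass(frozen=True)
class ConditionalMoments:
    """Conditional cumulants of the latent variable given one pattern."""

    pattern: tuple[int, ...]
    u: float
    kappa: np.ndarray  # kappa[j-1] = j-th conditional cumulant

    @property
    def eap(self) -> float:
        return float(self.kappa[0])

    @property
    def variance(self) -> float:
        return float(self.kappa[1])


@dataclass(frozen=True)
class PopulationCumulants:
    """First four latent moments/cumulants in the subpopulation B."""

    mu_prime: np.ndarray  # non-central moments 1..4
    kappa: np.ndarray  # cumulants 1..4

    @property
    def mean(self) -> float:
        return float(self.kappa[0])

    @property
    def variance(self) -> float:
        return float(self.kappa[1])


def _params_of(fit_or_params) -> ModelParams:
    if isinstance(fit_or_params, FitResult):
        return fit_or_params.params
    return fit_or_params


def conditional_cumulants(fit_or_params, y: Sequence[int], j_max: int | None = None) -> ConditionalMoments:
    """Conditional cumulants ``kappa_j|y = K^(j)(alpha' y~)``, j = 1..j_max.

    The default ``j_max = v - 1`` covers every cumulant the truncated
    CGF can generate; orders beyond v are identically zero under the
    polynomial CGF.
    """
    params = _params_of(fit_or_params)
    v = params.spec.v
    if j_max is None:
        j_max = max(v - 1, 2)
    coding = dummy_code(y, params.y0, params.design)
    u = linear_predictor(params.alpha, coding.y_tilde)
    lam = params.lambdas
    kappa = np.array([float(cgf_derivative(u, j, lam)) for j in range(1, j_max + 1)])
    return ConditionalMoments(pattern=tuple(int(t) for t in y), u=u, kappa=kappa)


def conditional_mgf(fit_or_params, y: Sequence[int], z) -> float:
    """Conditional MGF of the latent variable given pattern ``y``.

    ``M(z) = exp{ sum_r lambda_r [(z + u)^r - u^r] / r! }`` with
    ``u = alpha' y~``; equivalently ``exp{K(z + u) - K(u)}``.
    """
    params = _params_of(fit_or_params)
    coding = dummy_code(y, params.y0, params.design)
    u = linear_predictor(params.alpha, coding.y_tilde)
    lam = params.lambdas
    return np.exp(cgf_derivative(np.asarray(z) + u, 0, lam) - cgf_derivative(u, 0, lam))


def eap_table(fit_result: FitResult, data: PatternCounts | None = None) -> pd.DataFrame:
    """EAP scores and posterior variances for every observed pattern."""
    params = fit_result.params
    if data is None:
        data = fit_result.data
    rows = []
    for row, ny in zip(data.patterns, data.counts):
        cm = conditional_cumulants(params, row, j_max=2)
        rows.append(
            {
                "pattern": format_pattern(row),
                "n": int(ny),
                "u": cm.u,
                "eap": cm.eap,
                "var": cm.variance,
            }
        )
    return pd.DataFrame(rows)


def noncentral_from_cumulants(kappa: Sequence[float]) -> np.ndarray:
    """First four non-central moments from the first four cumulants."""
    k1, k2, k3, k4 = (float(v) for v in kappa)
    return np.array(
        [
            k1,
            k2 + k1**2,
            k3 + 3 * k1 * k2 + k1**3,
            k4 + 4 * k1 * k3 + 3 * k2**2 + 6 * k1**2 * k2 + k1**4,
        ]
    )


def cumulants_from_noncentral(mu_prime: Sequence[float], *, kappa4: str = "standard") -> np.ndarray:
    """First four cumulants from the first four non-central moments.

    ``kappa4="standard"`` uses the usual identity with ``-3 mu2'^2``;
    ``kappa4="cubed"`` substitutes ``-3 mu2'^3``, a variant kept for
    comparability with outputs computed that way (it is not the
    standard cumulant).
    """
    m1, m2, m3, m4 = (float(v) for v in mu_prime)
    k1 = m1
    k2 = m2 - m1**2
    k3 = m3 - 3 * m2 * m1 + 2 * m1**3
    if kappa4 == "standard":
        quad = -3 * m2**2
    elif kappa4 == "cubed":
        quad = -3 * m2**3
    else:
        raise ValueError("kappa4 must be 'standard' or 'cubed'")
    k4 = m4 - 4 * m3 * m1 + quad + 12 * m2 * m1**2 - 6 * m1**4
    return np.array([k1, k2, k3, k4])


def population_moments(
    fit_result: FitResult,
    *,
    weighting: str = "model",
    kappa4: str = "standard",
) -> PopulationCumulants:
    """Latent moments and cumulants in the subpopulation defined by B.

    Per-pattern conditional non-central moments (from the conditional
    cumulants) are averaged over patterns with weights given by the
    fitted model probabilities (``weighting="model"``, the plug-in MLE)
    or by observed relative frequencies (``weighting="observed"``, for
    sensitivity checks).
    """
    params = fit_result.params
    ev = PatternEvaluator(params)
    if weighting == "model":
        w = ev.probabilities()
        support = params.support
    elif weighting == "observed":
        w = fit_result.data.counts / fit_result.data.n
        support = fit_result.data.patterns
    else:
        raise ValueError("weighting must be 'model' or 'observed'")
    mu = np.zeros(4)
    for row, wy in zip(support, w):
        cm = conditional_cumulants(params, row, j_max=4)
        mu += wy * noncentral_from_cumulants(cm.kappa[:4])
    return PopulationCumulants(
        mu_prime=mu, kappa=cumulants_from_noncentral(mu, kappa4=kappa4)
    )
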