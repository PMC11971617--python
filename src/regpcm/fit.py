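"""Maximum likelihood estimation and parameter transformations.

Fits the convexity-constrained pattern model by quasi-Newton (BFGS)
maximization of the multinomial log-likelihood with the analytic
gradient.  The log-likelihood is log-concave in all free parameters, so
any stationary point is the global maximum, up to the latent-direction
sign convention which is normalized post hoc (sum of item scalings
non-negative).

Standard errors come from a fresh central-finite-difference Hessian of
the analytic gradient (not the optimizer's internal approximation,
which accumulates noise), inverted to an observed-information
covariance; interpretable item thresholds and cumulants are transformed
with delta-method standard errors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .cgf import CGFSpec, h_coefficients
from .likelihood import (
    ModelParams,
    NominalEvaluator,
    NominalParams,
    PatternEvaluator,
)
from .patterns import PatternCounts, TestDesign, all_patterns

logger = logging.getLogger(__name__)

__all__ = [
    "FitResult",
    "fit",
    "fit_nominal",
    "count_free_parameters",
    "observed_information",
    "item_thresholds",
    "cumulant_estimates",
]


@dataclass
class FitResult:
    """A converged (or flagged) maximum likelihood fit."""

    params: ModelParams | NominalParams
    loglik: float
    cov: np.ndarray | None
    converged: bool
    iterations: int
    grad_norm: float
    data: PatternCounts

    @property
    def n_free(self) -> int:
        return len(self.params.free_vector())

    def standard_errors(self) -> np.ndarray:
        if self.cov is None:
            raise ValueError("no covariance available (fit not converged?)")
        return np.sqrt(np.clip(np.diag(self.cov), 0.0, None))


def count_free_parameters(design: TestDesign, spec: CGFSpec) -> int:
    """Free-parameter count: sum(m_i) + k + (free CGF shape coefficients).

    With the second polynomial at full degree q this is
    ``sum m_i + k + v - 2``; the parsimonious degree q-1 drops one.
    """
    return design.n_beta + design.k + spec.n_free


def _resolve_support(data: PatternCounts, support) -> np.ndarray:
    if support is None or (isinstance(support, str) and support == "observed"):
        return data.patterns.copy()
    if isinstance(support, str) and support == "full":
        return all_patterns(data.design)
    arr = np.asarray(support, dtype=np.int64)
    if arr.ndim != 2 or arr.shape[1] != data.design.k:
        raise ValueError("explicit support must be a (P, k) pattern array")
    return arr


def _maximize(objective, theta0, *, gtol: float, maxiter: int):
    """BFGS with cold restarts.

    A stalled line search ("precision loss") on an ill-conditioned
    problem is usually cured by restarting with a fresh Hessian
    approximation from the stopping point; iterate until the objective
    stops improving or the gradient tolerance is met.
    """
    res = minimize(
        objective, theta0, jac=True, method="BFGS",
        options={"gtol": gtol, "maxiter": maxiter},
    )
    total_nit = res.nit
    for _ in range(4):
        gnorm = float(np.max(np.abs(res.jac)))
        if res.success or gnorm < gtol:
            break
        retry = minimize(
            objective, res.x, jac=True, method="BFGS",
            options={"gtol": gtol, "maxiter": maxiter},
        )
        total_nit += retry.nit
        improved = retry.fun < res.fun - 1e-12 * max(1.0, abs(res.fun))
        res = retry if retry.fun <= res.fun else res
        if not improved:
            break
    res.nit = total_nit
    return res


def _sign_normalize(params: ModelParams) -> ModelParams:
    """Resolve the latent-direction sign: make sum(alpha) >= 0.

    Flipping theta -> -theta maps alpha -> -alpha and eps_j ->
    (-1)^j eps_j, which negates the odd cumulants and leaves every
    pattern probability unchanged.
    """
    if params.alpha.sum() >= 0:
        return params
    free = params.eps.free.copy()
    spec = params.spec
    for idx, j in enumerate(list(range(1, spec.q + 1)) + list(range(1, spec.deg2 + 1))):
        free[idx] *= (-1.0) ** j
    return ModelParams(
        design=params.design,
        beta=params.beta,
        alpha=-params.alpha,
        eps=spec.epsilons(free),
        y0=params.y0,
        support=params.support,
    )


def fit(
    data: PatternCounts,
    spec: CGFSpec | None = None,
    y0=None,
    support="observed",
    *,
    gtol: float = 1e-6,
    maxiter: int = 2000,
    start: np.ndarray | None = None,
    compute_cov: bool = True,
) -> FitResult:
    """Fit the convexity-constrained partial credit model by marginal ML.

    Parameters
    ----------
    data:
        Observed pattern frequencies.
    spec:
        CGF configuration; defaults to ``CGFSpec()`` (v=6, parsimonious
        second polynomial, fixed constants (3/5, 4/5)).
    y0:
        Reference pattern; ``None`` picks the most frequent observed
        pattern. Must be observed.
    support:
        ``"observed"`` (B = O, the default), ``"full"`` (the whole
        product space; only sensible for small designs), or an explicit
        pattern array.
    start:
        Optional starting free-parameter vector; the default is the
        normal sub-model start (beta = 0, alpha = 1, shape = 0), which
        is always feasible.
    """
    if spec is None:
        spec = CGFSpec()
    if data.n_patterns < 2:
        raise ValueError("need at least two distinct patterns to fit the model")
    if y0 is None:
        y0 = data.most_frequent()
    y0 = data.design.validate_pattern(y0, where="y0")
    if y0 not in data:
        raise ValueError("reference pattern y0 must be an observed pattern")
    B = _resolve_support(data, support)

    template = ModelParams(
        design=data.design,
        beta=np.zeros(data.design.n_beta),
        alpha=np.ones(data.design.k),
        eps=spec.epsilons(),
        y0=y0,
        support=B,
    )
    ev = PatternEvaluator(template)
    counts = ev.counts_on_support(data)

    def objective(theta):
        p = template.with_free_vector(theta)
        return -ev.log_likelihood(p, counts), -ev.score(p, counts)

    theta0 = template.free_vector() if start is None else np.asarray(start, float)
    res = _maximize(objective, theta0, gtol=gtol, maxiter=maxiter)
    params = _sign_normalize(template.with_free_vector(res.x))
    # re-evaluate at the sign-normalized point (likelihood is invariant)
    ev2 = PatternEvaluator(params)
    counts2 = ev2.counts_on_support(data)
    loglik = ev2.log_likelihood(params, counts2)
    grad = ev2.score(params, counts2)
    grad_norm = float(np.max(np.abs(grad)))
    converged = bool(res.success) or grad_norm < 10 * gtol * max(1.0, abs(loglik))
    if not converged:
        logger.warning("fit did not converge: %s (grad norm %.3g)", res.message, grad_norm)
    result = FitResult(
        params=params,
        loglik=loglik,
        cov=None,
        converged=converged,
        iterations=int(res.nit),
        grad_norm=grad_norm,
        data=data,
    )
    if compute_cov and converged:
        result.cov = observed_information(params, data)
    return result


def fit_nominal(
    data: PatternCounts,
    spec: CGFSpec | None = None,
    y0=None,
    support="observed",
    *,
    gtol: float = 1e-6,
    maxiter: int = 2000,
    start: np.ndarray | None = None,
) -> FitResult:
    """Fit the nominal-response generalization (unrestricted scalings).

    Starting from the fitted partial-credit embedding is recommended;
    the default start embeds the normal sub-model (eta_is = s).
    """
    if spec is None:
        spec = CGFSpec()
    if y0 is None:
        y0 = data.most_frequent()
    y0 = data.design.validate_pattern(y0, where="y0")
    B = _resolve_support(data, support)
    eta0 = np.concatenate([np.arange(1, mi + 1, dtype=float) for mi in data.design.m])
    template = NominalParams(
        design=data.design,
        beta=np.zeros(data.design.n_beta),
        eta=eta0,
        eps=spec.epsilons(),
        y0=y0,
        support=B,
    )
    ev = NominalEvaluator(template)
    counts = ev.counts_on_support(data)

    def objective(theta):
        p = template.with_free_vector(theta)
        return -ev.log_likelihood(p, counts), -ev.score(p, counts)

    theta0 = template.free_vector() if start is None else np.asarray(start, float)
    res = _maximize(objective, theta0, gtol=gtol, maxiter=maxiter)
    params = template.with_free_vector(res.x)
    loglik = ev.log_likelihood(params, counts)
    grad_norm = float(np.max(np.abs(ev.score(params, counts))))
    return FitResult(
        params=params,
        loglik=loglik,
        cov=None,
        converged=bool(res.success) or grad_norm < 1e-4,
        iterations=int(res.nit),
        grad_norm=grad_norm,
        data=data,
    )


def observed_information(params, data: PatternCounts, *, step: float = 1e-5) -> np.ndarray:
    """Observed-information covariance of the free parameters.

    The Hessian of the log-likelihood is approximated by central finite
    differences of the analytic gradient with a relative step, then the
    negative Hessian is inverted.
    """
    if isinstance(params, NominalParams):
        ev = NominalEvaluator(params)
    else:
        ev = PatternEvaluator(params)
    counts = ev.counts_on_support(data)
    theta = params.free_vector()
    p = len(theta)
    H = np.zeros((p, p))
    for i in range(p):
        h = step * max(1.0, abs(theta[i]))
        tp, tm = theta.copy(), theta.copy()
        tp[i] += h
        tm[i] -= h
        gp = ev.score(params.with_free_vector(tp), counts)
        gm = ev.score(params.with_free_vector(tm), counts)
        H[i] = (gp - gm) / (2 * h)
    H = 0.5 * (H + H.T)
    info = -H
    eigval, eigvec = np.linalg.eigh(info)
    if eigval.min() <= eigval.max() * 1e-10:
        null = eigvec[:, np.argmin(eigval)]
        raise np.linalg.LinAlgError(
            f"observed information is singular; null direction ~ {np.round(null, 3)}"
        )
    return np.linalg.inv(info)


def _delta_method(transform, fit_result: FitResult, *, step: float = 1e-6) -> np.ndarray:
    """SEs of ``transform(theta)`` by numerical Jacobian against the fit cov."""
    theta = fit_result.params.free_vector()
    base = np.asarray(transform(theta), dtype=np.float64)
    J = np.zeros((len(base), len(theta)))
    for i in range(len(theta)):
        h = step * max(1.0, abs(theta[i]))
        tp, tm = theta.copy(), theta.copy()
        tp[i] += h
        tm[i] -= h
        J[:, i] = (np.asarray(transform(tp)) - np.asarray(transform(tm))) / (2 * h)
    var = np.einsum("ij,jk,ik->i", J, fit_result.cov, J)
    return np.sqrt(np.clip(var, 0.0, None))


def item_thresholds(fit_result: FitResult) -> pd.DataFrame:
    """Back-transform beta to thresholds delta and mean thresholds omega.

    ``delta_i = -alpha_i^{-1} J_i^{-1} beta_i`` with J_i the
    lower-triangular ones matrix, i.e. ``delta_i1 = -beta_i1/alpha_i``
    and ``delta_is = (beta_i,s-1 - beta_is)/alpha_i`` for s > 1;
    ``omega_is = -beta_is / (s alpha_i)``.  Standard errors by the delta
    method against the full free-parameter covariance.
    """
    params = fit_result.params
    if isinstance(params, NominalParams):
        raise TypeError("thresholds are defined for the partial-credit parameterization")
    design = params.design
    if np.any(np.abs(params.alpha) < 1e-10):
        raise ValueError("threshold undefined: an item scaling estimate is zero")
    nb, k = design.n_beta, design.k

    def transform(theta):
        beta, alpha = theta[:nb], theta[nb : nb + k]
        out = []
        offset = 0
        for i, mi in enumerate(design.m):
            b = beta[offset : offset + mi]
            prev = np.concatenate([[0.0], b[:-1]])
            delta = (prev - b) / alpha[i]
            omega = -b / (np.arange(1, mi + 1) * alpha[i])
            out.append(np.column_stack([b, delta, omega]).ravel())
            offset += mi
        return np.concatenate(out)

    values = transform(params.free_vector()).reshape(-1, 3)
    ses = (
        _delta_method(transform, fit_result).reshape(-1, 3)
        if fit_result.cov is not None
        else np.full((len(values), 3), np.nan)
    )
    rows = []
    r = 0
    for i, mi in enumerate(design.m):
        for s in range(1, mi + 1):
            rows.append(
                {
                    "item": i + 1,
                    "category": s,
                    "beta": values[r, 0],
                    "beta_se": ses[r, 0],
                    "delta": values[r, 1],
                    "delta_se": ses[r, 1],
                    "omega": values[r, 2],
                    "omega_se": ses[r, 2],
                }
            )
            r += 1
    return pd.DataFrame(rows)


def cumulant_estimates(fit_result: FitResult) -> pd.DataFrame:
    """Conditional cumulants lambda_2..lambda_v with delta-method SEs.

    ``lambda_r = (r-2)! h_{r-2}``; for r <= v-1 these are the
    conditional cumulants kappa_r of the latent variable given the
    reference pattern, while lambda_v is only a remainder coefficient.
    """
    params = fit_result.params
    spec = params.spec
    nb = params.design.n_beta
    n_loc = 2 * nb if isinstance(params, NominalParams) else nb + params.design.k

    def transform(theta):
        lam = h_coefficients(spec.epsilons(theta[n_loc:])).lambdas
        return lam[2:]

    values = transform(params.free_vector())
    ses = (
        _delta_method(transform, fit_result)
        if fit_result.cov is not None
        else np.full(len(values), np.nan)
    )
    v = spec.v
    rows = []
    for idx, r in enumerate(range(2, v + 1)):
        rows.append(
            {
                "r": r,
                "label": f"kappa_{r}" if r <= v - 1 else f"lambda_{r}",
                "estimate": values[idx],
                "se": ses[idx],
            }
        )
    return pd.DataFrame(rows)
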