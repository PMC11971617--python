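"""JSON round-tripping of model configuration, parameters and fits."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .cgf import CGFSpec
from .fit import FitResult
from .likelihood import ModelParams
from .patterns import PatternCounts, TestDesign, format_pattern, parse_pattern

__all__ = ["spec_to_dict", "spec_from_dict", "params_to_dict", "params_from_dict",
           "save_fit", "load_fit_params"]


def spec_to_dict(spec: CGFSpec) -> dict:
    return {"v": spec.v, "deg2": spec.deg2, "eps_fixed": list(spec.eps_fixed)}


def spec_from_dict(d: dict) -> CGFSpec:
    return CGFSpec(
        v=int(d["v"]),
        deg2=d.get("deg2"),
        eps_fixed=tuple(d.get("eps_fixed", (0.6, 0.8))),
    )


def params_to_dict(params: ModelParams) -> dict:
    return {
        "design": {"m": list(params.design.m)},
        "spec": spec_to_dict(params.spec),
        "beta": params.beta.tolist(),
        "alpha": params.alpha.tolist(),
        "eps1": params.eps.eps1.tolist(),
        "eps2": params.eps.eps2.tolist(),
        "y0": format_pattern(params.y0),
        "support": [format_pattern(row) for row in params.support],
    }


def params_from_dict(d: dict) -> ModelParams:
    design = TestDesign(m=tuple(d["design"]["m"]))
    spec = spec_from_dict(d["spec"])
    eps1 = np.asarray(d["eps1"], dtype=float)
    eps2 = np.asarray(d["eps2"], dtype=float)
    free = np.concatenate([eps1[1:], eps2[1:]])
    return ModelParams(
        design=design,
        beta=np.asarray(d["beta"], dtype=float),
        alpha=np.asarray(d["alpha"], dtype=float),
        eps=spec.epsilons(free),
        y0=parse_pattern(d["y0"]),
        support=np.array([parse_pattern(p) for p in d["support"]], dtype=np.int64),
    )


def save_fit(fit_result: FitResult, path) -> None:
    payload = {
        "params": params_to_dict(fit_result.params),
        "loglik": fit_result.loglik,
        "converged": fit_result.converged,
        "iterations": fit_result.iterations,
        "grad_norm": fit_result.grad_norm,
        "cov": None if fit_result.cov is None else fit_result.cov.tolist(),
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def load_fit_params(path) -> FitResult:
    """Rehydrate a saved fit (parameters + covariance, no data)."""
    d = json.loads(Path(path).read_text())
    params = params_from_dict(d["params"])
    support = params.support
    # reconstruct a minimal PatternCounts carrier: support with unit counts
    data = PatternCounts(params.design, support, np.ones(len(support), dtype=np.int64))
    return FitResult(
        params=params,
        loglik=float(d["loglik"]),
        cov=None if d["cov"] is None else np.asarray(d["cov"], dtype=float),
        converged=bool(d["converged"]),
        iterations=int(d["iterations"]),
        grad_norm=float(d["grad_norm"]),
        data=data,
    )
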