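"""Split-sample likelihood-ratio goodness-of-fit and nested LR tests.

The split test randomly partitions the observed pattern set O into two
disjoint halves O1 and O2, fits the model to the full data and to each
half on its own observed support, and compares

    LR = 2[(l1 + n1 ln(n1/n)) + (l2 + n2 ln(n2/n)) - l],

which is asymptotically chi-squared with degrees of freedom equal to
the model's free-parameter count plus one.  A small LR means the two
halves are described by the one fitted model about as well as by two
independent ones, i.e. the model replicates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.stats import chi2

from .cgf import CGFSpec
from .fit import FitResult, count_free_parameters, fit
from .patterns import PatternCounts

logger = logging.getLogger(__name__)

__all__ = ["SplitLRResult", "split_patterns", "split_lr_test", "lr_compare"]


@dataclass(frozen=True)
class SplitLRResult:
    lr: float
    df: int
    pvalue: float | None
    loglik_full: float
    loglik_1: float
    loglik_2: float
    n1: int
    n2: int
    converged: bool


def split_patterns(
    data: PatternCounts, seed: int | None = None, labels=None
) -> tuple[PatternCounts, PatternCounts]:
    """Partition the observed patterns into two disjoint halves.

    Assignment is at the pattern level (every person with a given
    pattern goes to the same half).  Either pass explicit ``labels``
    (array of 1/2 per pattern, or the string ``"stored"`` to use the
    partition column carried by the data) or a ``seed`` for a random
    equal-probability assignment.
    """
    if data.n_patterns < 2:
        raise ValueError("need at least two patterns to split")
    if labels is not None:
        if isinstance(labels, str) and labels == "stored":
            if data.partition is None:
                raise ValueError("data carries no stored partition labels")
            lab = data.partition
        else:
            lab = np.asarray(labels, dtype=np.int64)
            if lab.shape != (data.n_patterns,):
                raise ValueError("labels must give one 1/2 label per pattern")
    else:
        if seed is None:
            raise ValueError("give either labels or a seed")
        rng = np.random.default_rng(seed)
        lab = rng.integers(1, 3, size=data.n_patterns)
        # a one-sided draw leaves an empty half: redraw one pattern over
        if len(np.unique(lab)) == 1:
            flip = rng.integers(0, data.n_patterns)
            lab[flip] = 3 - lab[flip]
    part1, part2 = data.subset(lab == 1), data.subset(lab == 2)
    return part1, part2


def split_lr_test(
    data: PatternCounts,
    partition="stored",
    spec: CGFSpec | None = None,
    y0=None,
    *,
    seed: int | None = None,
    gtol: float = 1e-6,
) -> SplitLRResult:
    """Split-sample LR goodness-of-fit test.

    ``partition`` may be ``"stored"``, an explicit label array, or
    ``"random"`` (requires ``seed``).  The full fit uses ``y0`` (or the
    overall most frequent pattern); each half is refitted on its own
    observed support with its own most frequent pattern as reference —
    the maximized log-likelihood is invariant to that choice.
    """
    if spec is None:
        spec = CGFSpec()
    if isinstance(partition, str) and partition == "random":
        part1, part2 = split_patterns(data, seed=seed)
    elif isinstance(partition, str) and partition == "stored":
        part1, part2 = split_patterns(data, labels="stored")
    else:
        part1, part2 = split_patterns(data, labels=partition)

    full = fit(data, spec, y0=y0, compute_cov=False, gtol=gtol)
    sub1 = fit(part1, spec, compute_cov=False, gtol=gtol)
    sub2 = fit(part2, spec, compute_cov=False, gtol=gtol)
    n, n1, n2 = data.n, part1.n, part2.n
    lr = 2.0 * (
        (sub1.loglik + n1 * np.log(n1 / n))
        + (sub2.loglik + n2 * np.log(n2 / n))
        - full.loglik
    )
    df = count_free_parameters(data.design, spec) + 1
    converged = full.converged and sub1.converged and sub2.converged
    pvalue = float(chi2.sf(lr, df)) if converged else None
    if not converged:
        logger.warning("a sub-fit did not converge; p-value withheld")
    return SplitLRResult(
        lr=float(lr),
        df=df,
        pvalue=pvalue,
        loglik_full=full.loglik,
        loglik_1=sub1.loglik,
        loglik_2=sub2.loglik,
        n1=n1,
        n2=n2,
        converged=converged,
    )


def lr_compare(fit_null: FitResult, fit_alt: FitResult, *, tol: float = 1e-6):
    """LR test of a null model nested in an alternative on the same data.

    Returns ``(lr, df, pvalue)`` with ``lr = 2(l_alt - l_null)`` and
    ``df`` the difference in free-parameter counts.
    """
    lr = 2.0 * (fit_alt.loglik - fit_null.loglik)
    df = fit_alt.n_free - fit_null.n_free
    if df < 0:
        raise ValueError("alternative model has fewer free parameters than the null")
    if lr < -tol * max(1.0, abs(fit_null.loglik)):
        raise ValueError(
            "alternative log-likelihood below the null's: models not nested "
            "or a fit did not converge"
        )
    lr = max(lr, 0.0)
    pvalue = float(chi2.sf(lr, df)) if df > 0 else (1.0 if lr == 0 else 0.0)
    return float(lr), int(df), pvalue
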