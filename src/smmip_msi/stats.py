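"""Exact small-sample statistics used throughout the assay.

Two-sided Fisher's exact test (point-probability ordering), Clopper-Pearson
exact binomial confidence intervals, and the 95th-percentile threshold
estimator with a fixed interpolation convention.
"""

from __future__ import annotations

from collections.abc import Sequence

import numpy as np
from scipy import stats as sps


def fisher_exact(
    table: Sequence[Sequence[int]], alternative: str = "two-sided"
) -> float:
    """Fisher's exact test p-value for a 2x2 contingency table.

    Rows are SNP ref/alt allele, columns deleted / not-deleted.  The default
    two-sided p-value sums the hypergeometric probabilities of all tables
    with the observed margins whose point probability does not exceed that of
    the observed table.  A zero row or column margin carries no information
    and returns 1.0.

    Parameters
    ----------
    table : 2x2 of non-negative ints
    alternative : {"two-sided", "less", "greater"}
        One-sided options are exposed for sensitivity analysis.
    """
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2):
        raise ValueError(f"expected a 2x2 table, got shape {t.shape}")
    if (t < 0).any():
        raise ValueError("table counts must be non-negative")
    if t.sum() == 0:
        raise ValueError("table total must be positive")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        return 1.0
    return float(sps.fisher_exact(t, alternative=alternative).pvalue)


def fisher_exact_two_sided(table: Sequence[Sequence[int]]) -> float:
    return fisher_exact(table, alternative="two-sided")


def clopper_pearson(
    successes: int, trials: int, confidence: float = 0.95
) -> tuple[float, float]:
    """Exact (Clopper-Pearson) two-sided binomial confidence interval.

    Returns ``(lower, upper)`` as proportions.  For ``successes == trials``
    the lower bound equals ``(alpha/2)**(1/n)`` and the upper bound is 1;
    for zero successes the lower bound is 0.

    >>> round(clopper_pearson(51, 51)[0], 3)
    0.93
    """
    if trials < 1:
        raise ValueError("trials must be >= 1")
    if not 0 <= successes <= trials:
        raise ValueError("successes must lie in [0, trials]")
    if not 0 < confidence < 1:
        raise ValueError("confidence must lie in (0, 1)")
    ci = sps.binomtest(successes, trials).proportion_ci(
        confidence_level=confidence, method="exact"
    )
    return float(ci.low), float(ci.high)


def percentile_95(values: Sequence[float], q: float = 95.0) -> float:
    """Percentile of a set of proportions under linear interpolation.

    Uses the convention that the (1-based, fractional) rank
    ``q/100 * (n - 1) + 1`` linearly interpolates its neighbouring order
    statistics — numpy's default "linear" method.  Used for the per-marker
    deletion-frequency thresholds (95th percentile of training MSS samples).

    >>> percentile_95([round(0.01 * k, 2) for k in range(1, 21)])
    0.1905
    """
    vals = np.asarray(values, dtype=float)
    if vals.ndim != 1 or vals.size < 2:
        raise ValueError("need at least 2 values to estimate a percentile threshold")
    return float(np.percentile(vals, q, method="linear"))
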