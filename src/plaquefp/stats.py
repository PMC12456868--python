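"""Shared statistics used across the photometry and histology pipelines.

A single Spearman implementation backs the flat-fiber, ex vivo and in vivo
profile comparisons so that correlation values are identical no matter which
stage computed them. Group contrasts (two-sample t on correlation
coefficients, paired Wilcoxon on depth-resolved fluorescence changes) live
here as well.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import permutations
from typing import NamedTuple, Sequence

import numpy as np
from scipy import stats as sps


class SpearmanResult(NamedTuple):
    rho: float
    p: float
    n: int


class GroupSummary(NamedTuple):
    """Summary form of one group: mean, standard error of the mean, n."""

    mean: float
    sem: float
    n: int


@dataclass(frozen=True)
class GroupComparison:
    """Result of a two-group contrast."""

    test: str
    statistic: float
    df: float | None
    p: float
    n1: int
    n2: int


class DegenerateInputError(ValueError):
    """Raised when a statistic is undefined for the given input."""


def _rank_pearson(rx: np.ndarray, ry: np.ndarray) -> float:
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = math.sqrt(float(rx @ rx) * float(ry @ ry))
    if denom == 0.0:
        raise DegenerateInputError("constant input: Spearman's rho is undefined")
    return float(rx @ ry) / denom


def spearman(x: Sequence[float], y: Sequence[float], *, exact_n: int = 8) -> SpearmanResult:
    """Spearman rank correlation with average ranks for ties.

    The p-value is two-sided: an exact permutation enumeration for
    ``n <= exact_n``, otherwise the usual t-approximation
    ``t = rho * sqrt((n-2)/(1-rho^2))`` on n-2 degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and of equal length")
    n = x.size
    if n < 3:
        raise ValueError("Spearman correlation requires n >= 3")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite")
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    rho = _rank_pearson(rx, ry)

    if n <= exact_n:
        # Null: all pairings of the observed rank vectors equally likely.
        perms = np.array(list(permutations(range(n))), dtype=np.intp)
        ry_c = ry - ry.mean()
        rx_c = rx - rx.mean()
        denom = math.sqrt(float(rx_c @ rx_c) * float(ry_c @ ry_c))
        null = (rx_c[perms] @ ry_c) / denom
        p = float(np.mean(np.abs(null) >= abs(rho) - 1e-12))
    else:
        if abs(rho) >= 1.0:
            p = 0.0
        else:
            t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
            p = 2.0 * float(sps.t.sf(abs(t), n - 2))
    return SpearmanResult(rho=rho, p=p, n=n)


def _summarize(values) -> tuple[float, float, int]:
    """Return (mean, sd, n) from raw values or a GroupSummary."""
    if isinstance(values, GroupSummary):
        mean, sem, n = values
        if n < 2:
            raise ValueError("group size must be >= 2")
        return float(mean), float(sem) * math.sqrt(n), int(n)
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1 or arr.size < 2:
        raise ValueError("each group needs >= 2 raw values")
    return float(arr.mean()), float(arr.std(ddof=1)), arr.size


def two_sample_t(group_a, group_b) -> GroupComparison:
    """Pooled-variance two-sample Student t-test (two-sided).

    Each group may be given either as raw values or as a
    :class:`GroupSummary` ``(mean, sem, n)``; in the summary form the group
    standard deviation is reconstructed as ``sem * sqrt(n)``.
    """
    m1, s1, n1 = _summarize(group_a)
    m2, s2, n2 = _summarize(group_b)
    df = n1 + n2 - 2
    pooled_var = ((n1 - 1) * s1 * s1 + (n2 - 1) * s2 * s2) / df
    if pooled_var <= 0.0:
        raise DegenerateInputError("zero pooled variance: t statistic undefined")
    se = math.sqrt(pooled_var * (1.0 / n1 + 1.0 / n2))
    t = (m1 - m2) / se
    p = 2.0 * float(sps.t.sf(abs(t), df))
    return GroupComparison(test="two-sample t", statistic=t, df=df, p=p, n1=n1, n2=n2)


def paired_wilcoxon(x, y, *, exact_max_n: int = 25) -> GroupComparison:
    """Two-sided Wilcoxon signed-rank test on paired samples.

    Uses the exact null distribution for ``n <= exact_max_n`` (and no zero
    differences), the normal approximation otherwise. All-zero differences
    yield statistic 0 and p = 1 with a warning rather than an error.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("paired samples must be 1-D and of equal length")
    d = x - y
    n = d.size
    if np.all(d == 0.0):
        warnings.warn("all paired differences are zero; p-value is 1", stacklevel=2)
        return GroupComparison(test="wilcoxon signed-rank", statistic=0.0, df=None,
                               p=1.0, n1=n, n2=n)
    method = "exact" if (n <= exact_max_n and not np.any(d == 0.0)) else "approx"
    res = sps.wilcoxon(x, y, alternative="two-sided", method=method)
    return GroupComparison(test="wilcoxon signed-rank", statistic=float(res.statistic),
                           df=None, p=float(res.pvalue), n1=n, n2=n)
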