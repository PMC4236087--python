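"""Exact null moments of the rank-difference statistic and asymptotic inference.

Under H0 the pooled ranks are a uniform random permutation of 1..N, so the
moments depend on the data only through the composition (n_1..n_k).  The mean
is ``(N+1)/6 * sum_{i<j} n_i n_j``.  The variance decomposes over pairs of
cross-group comparisons by how many observations they share:

* the same comparison twice — variance ``(N+1)(2N-1)/36``;
* one shared observation that is the later (or, symmetrically, the earlier)
  member of both comparisons — covariance ``(N+1)(2N-1)/90``;
* one shared observation that sits in the middle of a group-ordered chain —
  covariance ``-(N+1)(7N+4)/360``;
* no shared observation — covariance ``-(N+1)/180`` (sampling ranks without
  replacement leaves a small negative dependence between disjoint pairs).

Each constant is the exact finite-population moment of pooled ranks drawn
without replacement from {1..N}; the whole closed form is verified against
exhaustive enumeration over every composition with N <= 8 in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from ._batch import batch_statistics
from .core import GroupedSample, assign_ranks, rank_difference_statistic

__all__ = [
    "NullMoments",
    "TestResult",
    "new_mean_null",
    "new_variance_null",
    "null_moments",
    "standardize",
    "asymptotic_pvalue",
    "asymptotic_test",
    "cdf_diagnostic",
    "CdfDiagnostic",
]


@dataclass(frozen=True)
class NullMoments:
    """Exact null mean and variance of the rank-difference statistic."""

    mean: float
    variance: float
    sizes: tuple


@dataclass(frozen=True)
class TestResult:
    """Outcome of one trend test on one dataset."""

    test_name: str
    statistic: float
    p_value: float
    method: str  # "asymptotic" | "permutation" | "exact"
    side: str = "increasing"
    z: Optional[float] = None
    replicates: Optional[int] = None
    seed: Optional[int] = None

    def to_dict(self) -> dict:
        return {
            "test": self.test_name,
            "statistic": self.statistic,
            "z": self.z,
            "p_value": self.p_value,
            "method": self.method,
            "side": self.side,
            "replicates": self.replicates,
            "seed": self.seed,
        }


def _validate_sizes(sizes: Sequence[int]) -> tuple:
    sizes = tuple(int(n) for n in sizes)
    if len(sizes) < 2:
        raise ValueError("need at least 2 groups")
    if any(n < 1 for n in sizes):
        raise ValueError("every group size must be >= 1")
    return sizes


def _exact_moments(sizes: Sequence[int]) -> tuple[Fraction, Fraction]:
    """Closed-form null mean and variance as exact rationals."""
    sizes = _validate_sizes(sizes)
    N = sum(sizes)
    k = len(sizes)
    before = np.concatenate(([0], np.cumsum(sizes)[:-1])).astype(int)
    after = (N - np.asarray(sizes) - before).astype(int)

    pairs = sum(sizes[i] * sizes[j] for i in range(k) for j in range(i + 1, k))
    shared_later = sum(n * b * (b - 1) for n, b in zip(sizes, before))
    shared_earlier = sum(n * a * (a - 1) for n, a in zip(sizes, after))
    shared_middle = 2 * sum(n * b * a for n, b, a in zip(sizes, before, after))
    disjoint = pairs * pairs - pairs - shared_later - shared_earlier - shared_middle

    mean = Fraction(N + 1, 6) * pairs
    var_same = Fraction((N + 1) * (2 * N - 1), 36)
    cov_end = Fraction((N + 1) * (2 * N - 1), 90)
    cov_middle = Fraction(-(N + 1) * (7 * N + 4), 360)
    cov_disjoint = Fraction(-(N + 1), 180)
    variance = (
        pairs * var_same
        + (shared_later + shared_earlier) * cov_end
        + shared_middle * cov_middle
        + disjoint * cov_disjoint
    )
    return mean, variance


def new_mean_null(sizes: Sequence[int]) -> float:
    """Exact null mean of the rank-difference statistic for composition ``sizes``."""
    return float(_exact_moments(sizes)[0])


def new_variance_null(sizes: Sequence[int]) -> float:
    """Exact null variance of the rank-difference statistic for ``sizes``."""
    return float(_exact_moments(sizes)[1])


def null_moments(sizes: Sequence[int]) -> NullMoments:
    mean, variance = _exact_moments(sizes)
    return NullMoments(float(mean), float(variance), _validate_sizes(sizes))


def standardize(s: float, sizes: Sequence[int]) -> float:
    """Standardized statistic ``(s - E0[S]) / sqrt(Var0[S])``."""
    mean, variance = _exact_moments(sizes)
    if variance <= 0:
        raise ValueError(f"degenerate composition {tuple(sizes)}: null variance is zero")
    return (s - float(mean)) / float(variance) ** 0.5


def asymptotic_pvalue(z: float, side: str = "increasing") -> float:
    """One-sided upper-tail standard normal p-value.

    ``side`` only labels the direction the caller standardized for; the tail
    is always the upper one because a decreasing alternative is handled by
    reversing the group order before computing the statistic.
    """
    if side not in ("increasing", "decreasing"):
        raise ValueError("side must be 'increasing' or 'decreasing'")
    return float(norm.sf(z))


def asymptotic_test(sample: GroupedSample, side: str = "increasing") -> TestResult:
    """Normal-approximation test of the rank-difference statistic.

    Refuses tied data: the closed-form variance assumes a continuous response,
    so tied samples must use permutation inference instead.
    """
    if side == "decreasing":
        sample = sample.reversed()
    elif side != "increasing":
        raise ValueError("side must be 'increasing' or 'decreasing'")
    ranked = assign_ranks(sample)
    if ranked.tie_flag:
        raise ValueError(
            "tied observations: the closed-form null variance assumes continuous "
            "data; use permutation inference (method='permutation') instead"
        )
    s = rank_difference_statistic(ranked)
    z = standardize(s, sample.sizes)
    return TestResult(
        test_name="new",
        statistic=s,
        z=z,
        p_value=asymptotic_pvalue(z),
        method="asymptotic",
        side=side,
    )


@dataclass(frozen=True)
class CdfDiagnostic:
    """Empirical-vs-normal CDF comparison for the standardized statistic."""

    table: pd.DataFrame  # columns: z, empirical_cdf, normal_cdf
    ks_distance: float
    sizes: tuple
    replicates: int
    seed: Optional[int]


def cdf_diagnostic(sizes: Sequence[int], replicates: int = 20_000,
                   seed: Optional[int] = None) -> CdfDiagnostic:
    """Simulate the null distribution of Z and compare its CDF with the normal.

    Draws ``replicates`` null datasets of standard normal groups with the given
    composition, standardizes the rank-difference statistic for each, and
    reports the empirical CDF alongside the standard normal CDF together with
    the Kolmogorov-Smirnov distance between the two.
    """
    sizes = _validate_sizes(sizes)
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    rng = np.random.default_rng(seed)
    values = rng.standard_normal((int(replicates), sum(sizes)))
    stats = batch_statistics(values, sizes, tests=("new",))["new"]
    mean, variance = _exact_moments(sizes)
    z = np.sort((stats - float(mean)) / float(variance) ** 0.5)
    n = z.size
    ecdf_right = np.arange(1, n + 1) / n
    phi = norm.cdf(z)
    ks = float(np.max(np.maximum(np.abs(ecdf_right - phi),
                                 np.abs(ecdf_right - 1.0 / n - phi))))
    table = pd.DataFrame({"z": z, "empirical_cdf": ecdf_right, "normal_cdf": phi})
    return CdfDiagnostic(table, ks, sizes, int(replicates), seed)
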