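"""Exact-enumeration and Monte-Carlo null distributions, permutation p-values,
and the shared-draw cutpoint calibration used by the power-study engine.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Callable, Optional, Sequence, Union

import numpy as np

from ._batch import TEST_NAMES, batch_statistics
from .core import STATISTICS, GroupedSample, RankedSample, assign_ranks
from .inference import TestResult

__all__ = [
    "NullDistribution",
    "exact_null_distribution",
    "exact_pvalue",
    "permutation_pvalue",
    "calibrate_cutpoints",
]

DEFAULT_ENUMERATION_CAP = 200_000

StatisticSpec = Union[str, Callable[[RankedSample], float]]


def _resolve_statistic(statistic: StatisticSpec):
    """Return (name, callable); named statistics get the vectorized fast path."""
    if callable(statistic):
        return getattr(statistic, "__name__", "custom"), statistic, None
    if statistic not in STATISTICS:
        raise ValueError(f"unknown statistic {statistic!r}; choose from {sorted(STATISTICS)}")
    return statistic, STATISTICS[statistic], statistic


@dataclass(frozen=True)
class NullDistribution:
    """Null distribution of a trend statistic for one composition (n_1..n_k).

    Exact mode stores the full support with probabilities; simulated mode
    stores raw Monte-Carlo draws together with the seed that produced them.
    """

    statistic_name: str
    sizes: tuple
    provenance: str  # "exact" | "simulated"
    values: np.ndarray
    probabilities: Optional[np.ndarray] = None
    replicates: Optional[int] = None
    seed: Optional[int] = None

    def mean(self) -> float:
        if self.provenance == "exact":
            return float(np.dot(self.values, self.probabilities))
        return float(np.mean(self.values))

    def variance(self) -> float:
        if self.provenance == "exact":
            m = self.mean()
            return float(np.dot((self.values - m) ** 2, self.probabilities))
        return float(np.var(self.values))

    def sf(self, x: float, atol: float = 1e-9) -> float:
        """P(statistic >= x) under the null."""
        mask = self.values >= x - atol
        if self.provenance == "exact":
            return float(self.probabilities[mask].sum())
        return float(np.mean(mask))


def _iter_rank_splits(sizes: Sequence[int]):
    """All unordered assignments of ranks 1..N to groups of the given sizes.

    Within-group order never matters for the statistics, so each split of the
    rank set is a single equally-likely outcome under permutation.
    """
    N = int(sum(sizes))

    def rec(avail: tuple, idx: int):
        if idx == len(sizes) - 1:
            yield (avail,)
            return
        for chosen in combinations(avail, sizes[idx]):
            chosen_set = set(chosen)
            rest = tuple(r for r in avail if r not in chosen_set)
            for tail in rec(rest, idx + 1):
                yield (chosen,) + tail

    yield from rec(tuple(range(1, N + 1)), 0)


def n_arrangements(sizes: Sequence[int]) -> int:
    """Multinomial count of distinct rank splits for a composition."""
    N = int(sum(sizes))
    total = math.factorial(N)
    for n in sizes:
        total //= math.factorial(int(n))
    return total


def exact_null_distribution(sizes: Sequence[int], statistic: StatisticSpec,
                            cap: int = DEFAULT_ENUMERATION_CAP) -> NullDistribution:
    """Full null distribution of a statistic by exhaustive enumeration.

    Enumerates every equally-likely assignment of ranks 1..N to the groups and
    tallies the statistic.  Raises when the arrangement count exceeds ``cap``
    (use Monte-Carlo permutation inference instead).
    """
    sizes = tuple(int(n) for n in sizes)
    if len(sizes) < 2 or any(n < 1 for n in sizes):
        raise ValueError("need k >= 2 groups with every n_i >= 1")
    total = n_arrangements(sizes)
    if total > cap:
        raise ValueError(
            f"{total} arrangements exceed the enumeration cap ({cap}); "
            "use permutation_pvalue for Monte-Carlo inference"
        )
    name, fn, _ = _resolve_statistic(statistic)
    groups = tuple(range(len(sizes)))
    counts: dict[float, int] = {}
    for split in _iter_rank_splits(sizes):
        s = fn(RankedSample(groups, [np.asarray(g, dtype=float) for g in split]))
        counts[s] = counts.get(s, 0) + 1
    support = np.array(sorted(counts))
    probs = np.array([counts[v] for v in support], dtype=float) / total
    return NullDistribution(name, sizes, "exact", support, probs)


def exact_pvalue(sample: GroupedSample, statistic: StatisticSpec,
                 side: str = "increasing",
                 cap: int = DEFAULT_ENUMERATION_CAP) -> TestResult:
    """Exact permutation p-value from full enumeration (small samples, no ties)."""
    if side == "decreasing":
        sample = sample.reversed()
    elif side != "increasing":
        raise ValueError("side must be 'increasing' or 'decreasing'")
    ranked = assign_ranks(sample)
    if ranked.tie_flag:
        raise ValueError(
            "tied observations: the rank-enumeration null assumes distinct ranks; "
            "use permutation_pvalue instead"
        )
    name, fn, _ = _resolve_statistic(statistic)
    observed = fn(ranked)
    dist = exact_null_distribution(sample.sizes, statistic, cap=cap)
    return TestResult(
        test_name=name,
        statistic=observed,
        p_value=dist.sf(observed),
        method="exact",
        side=side,
    )


def permutation_pvalue(sample: GroupedSample, statistic: StatisticSpec,
                       replicates: int = 10_000, seed: Optional[int] = None,
                       side: str = "increasing") -> TestResult:
    """Monte-Carlo permutation p-value with the add-one convention.

    Group labels are permuted over the pooled sample; p = (1 + b) / (B + 1)
    where b counts permuted statistics >= the observed one, so the p-value is
    never zero and remains valid for any B.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    if side == "decreasing":
        sample = sample.reversed()
    elif side != "increasing":
        raise ValueError("side must be 'increasing' or 'decreasing'")
    name, fn, batch_name = _resolve_statistic(statistic)
    ranked = assign_ranks(sample)
    observed = fn(ranked)
    rng = np.random.default_rng(seed)
    pooled = sample.pooled()
    B = int(replicates)
    perms = rng.permuted(np.broadcast_to(pooled, (B, pooled.size)), axis=1)
    if batch_name is not None:
        draws = batch_statistics(perms, sample.sizes, tests=(batch_name,))[batch_name]
    else:
        splits = np.cumsum(sample.sizes)[:-1]
        groups = tuple(range(len(sample.sizes)))
        draws = np.array([
            fn(assign_ranks(GroupedSample(groups, np.split(row, splits))))
            for row in perms
        ])
    exceed = int(np.count_nonzero(draws >= observed - 1e-9))
    return TestResult(
        test_name=name,
        statistic=observed,
        p_value=(1 + exceed) / (B + 1),
        method="permutation",
        side=side,
        replicates=B,
        seed=seed,
    )


def empirical_cutpoint(draws: np.ndarray, alpha: float = 0.05) -> float:
    """ceil((1-alpha)*B)-th order statistic; rejection is strictly above it."""
    B = draws.shape[0]
    idx = math.ceil((1.0 - alpha) * B) - 1
    return float(np.sort(draws)[idx])


def calibrate_cutpoints(scenario_null, tests: Sequence[str] = TEST_NAMES,
                        replicates: int = 20_000,
                        seed=None) -> dict[str, float]:
    """Per-test rejection cutpoints from one shared set of simulated null draws.

    Simulates ``replicates`` datasets from ``scenario_null`` once, evaluates
    every requested statistic on the same draws (common random numbers), and
    returns each test's empirical ``1 - alpha`` cutpoint, with alpha taken from
    the scenario.  Downstream rejection rule: statistic > cutpoint.
    """
    from .simulate import generate_matrix  # deferred: simulate imports this module

    if replicates < 100:
        raise ValueError("replicates must be >= 100 for cutpoint calibration")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    values = generate_matrix(scenario_null, int(replicates), rng)
    stats = batch_statistics(values, scenario_null.sizes, tests=tuple(tests))
    alpha = scenario_null.alpha
    return {name: empirical_cutpoint(stats[name], alpha) for name in tests}
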