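"""Grouped samples, pooled ranks, and the five k-sample trend statistics.

All statistics are functions of the pooled-sample ranks only, so a single
:func:`assign_ranks` call serves every test on a given dataset.  The group
order carried by :class:`GroupedSample` defines the direction of the ordered
alternative and is never inferred from the labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.stats import rankdata

__all__ = [
    "GroupedSample",
    "RankedSample",
    "assign_ranks",
    "jt_statistic",
    "mjt_statistic",
    "tm_statistic",
    "cu_statistic",
    "rank_difference_statistic",
    "STATISTICS",
]


@dataclass(frozen=True)
class GroupedSample:
    """k independent samples with an explicit, scientifically-meaningful group order.

    Parameters
    ----------
    groups
        Ordered group identifiers; position in this tuple is the hypothesized
        ordering ``1..k`` of the monotone alternative.
    values
        One 1-d float array of observations per group, aligned with ``groups``.
    """

    groups: tuple
    values: tuple = field(repr=False)

    def __init__(self, groups: Sequence, values: Sequence[Sequence[float]]):
        groups = tuple(groups)
        arrays = tuple(np.asarray(v, dtype=float) for v in values)
        if len(groups) != len(arrays):
            raise ValueError("groups and values must have the same length")
        if len(groups) < 2:
            raise ValueError("need at least 2 groups (k >= 2)")
        if len(set(groups)) != len(groups):
            raise ValueError("group identifiers must be unique")
        for g, a in zip(groups, arrays):
            if a.ndim != 1 or a.size == 0:
                raise ValueError(f"group {g!r} must hold a non-empty 1-d sample")
            if not np.all(np.isfinite(a)):
                raise ValueError(f"group {g!r} contains non-finite values")
        object.__setattr__(self, "groups", groups)
        object.__setattr__(self, "values", arrays)

    @property
    def k(self) -> int:
        return len(self.groups)

    @property
    def sizes(self) -> tuple:
        return tuple(a.size for a in self.values)

    @property
    def total_n(self) -> int:
        return int(sum(self.sizes))

    def pooled(self) -> np.ndarray:
        """All observations concatenated in group order."""
        return np.concatenate(self.values)

    def reversed(self) -> "GroupedSample":
        """Same data with the group order flipped (decreasing alternative)."""
        return GroupedSample(self.groups[::-1], self.values[::-1])


@dataclass(frozen=True)
class RankedSample:
    """Pooled-sample (mid)ranks aligned to a :class:`GroupedSample`.

    ``tie_flag`` is True when midranks were required.  Without ties the ranks
    of the N pooled observations are exactly ``{1, ..., N}``; midranks always
    preserve the total ``N(N+1)/2``.
    """

    groups: tuple
    ranks: tuple = field(repr=False)
    tie_flag: bool = False

    def __init__(self, groups: Sequence, ranks: Sequence[Sequence[float]],
                 tie_flag: bool = False):
        groups = tuple(groups)
        arrays = tuple(np.asarray(r, dtype=float) for r in ranks)
        if len(groups) < 2:
            raise ValueError("need at least 2 groups (k >= 2)")
        if any(a.size == 0 for a in arrays):
            raise ValueError("every group must be non-empty")
        object.__setattr__(self, "groups", groups)
        object.__setattr__(self, "ranks", arrays)
        object.__setattr__(self, "tie_flag", bool(tie_flag))

    @property
    def k(self) -> int:
        return len(self.groups)

    @property
    def sizes(self) -> tuple:
        return tuple(a.size for a in self.ranks)

    @property
    def total_n(self) -> int:
        return int(sum(self.sizes))

    def reversed(self) -> "RankedSample":
        return RankedSample(self.groups[::-1], self.ranks[::-1], self.tie_flag)


def assign_ranks(sample: GroupedSample) -> RankedSample:
    """Rank the pooled sample (midranks for ties) and split back by group."""
    pooled = sample.pooled()
    ranks = rankdata(pooled, method="average")
    tie_flag = bool(np.unique(pooled).size < pooled.size)
    split = np.split(ranks, np.cumsum(sample.sizes)[:-1])
    return RankedSample(sample.groups, split, tie_flag)


def _pairwise_u(ri: np.ndarray, rj: np.ndarray) -> float:
    """Mann-Whitney count for groups i<j: later-group value larger; ties count 1/2."""
    diff = rj[None, :] - ri[:, None]
    return float(np.count_nonzero(diff > 0) + 0.5 * np.count_nonzero(diff == 0))


def jt_statistic(ranked: RankedSample) -> float:
    """Jonckheere-Terpstra: sum of Mann-Whitney counts over all group pairs i<j."""
    total = 0.0
    for i in range(ranked.k):
        for j in range(i + 1, ranked.k):
            total += _pairwise_u(ranked.ranks[i], ranked.ranks[j])
    return total


def mjt_statistic(ranked: RankedSample) -> float:
    """Modified JT: Mann-Whitney counts weighted by the group distance (j - i)."""
    total = 0.0
    for i in range(ranked.k):
        for j in range(i + 1, ranked.k):
            total += (j - i) * _pairwise_u(ranked.ranks[i], ranked.ranks[j])
    return total


def tm_statistic(ranked: RankedSample) -> float:
    """Count of strictly increasing k-tuplets, one observation per group.

    Chain-counting dynamic program: walking groups left to right, ``counts[v]``
    is the number of strictly increasing chains through groups ``1..i`` ending
    at observation ``v`` of group ``i``; prefix sums over the sorted previous
    group advance it in O(k N log N).  Tied values never extend a chain.
    """
    order = np.sort(ranked.ranks[0])
    counts = np.ones_like(order)
    for i in range(1, ranked.k):
        nxt = np.sort(ranked.ranks[i])
        cum = np.concatenate(([0.0], np.cumsum(counts)))
        # chains ending strictly below each next-group value
        counts = cum[np.searchsorted(order, nxt, side="left")]
        order = nxt
    return float(counts.sum())


def cu_statistic(ranked: RankedSample) -> float:
    """Cuzick trend statistic: group rank-sums weighted by the group number 1..k."""
    return float(sum((l + 1) * r.sum() for l, r in enumerate(ranked.ranks)))


def rank_difference_statistic(ranked: RankedSample) -> float:
    """Positive rank-difference trend statistic.

    Over every cross-group pair (u in group i, v in group j, i < j) accumulate
    the positive part of the pooled-rank difference ``max(R_jv - R_iu, 0)`` —
    the magnitude of the concordant comparisons, not just their count.
    """
    total = 0.0
    for i in range(ranked.k):
        for j in range(i + 1, ranked.k):
            diff = ranked.ranks[j][None, :] - ranked.ranks[i][:, None]
            total += diff[diff > 0].sum()
    return float(total)


#: Registry of statistic callables keyed by their CLI names.
STATISTICS: dict[str, Callable[[RankedSample], float]] = {
    "jt": jt_statistic,
    "mjt": mjt_statistic,
    "tm": tm_statistic,
    "cu": cu_statistic,
    "new": rank_difference_statistic,
}
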