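"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately avoid the package's own algorithms: statistics
are computed with naive nested loops / full tuplet enumeration, and the null
distribution is enumerated with a stand-alone recursion, so they can arbitrate
the closed forms and dynamic programs they check.
"""

from fractions import Fraction
from itertools import combinations, product

import numpy as np
import pytest

from ranktrend import GroupedSample, RankedSample, assign_ranks


# ---------------------------------------------------------------------------
# brute-force statistic oracles (operate on plain lists of per-group ranks)

def brute_jt(groups):
    total = 0.0
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            for a in groups[i]:
                for b in groups[j]:
                    if b > a:
                        total += 1
                    elif b == a:
                        total += 0.5
    return total


def brute_mjt(groups):
    total = 0.0
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            for a in groups[i]:
                for b in groups[j]:
                    if b > a:
                        total += j - i
                    elif b == a:
                        total += 0.5 * (j - i)
    return total


def brute_tm(groups):
    count = 0
    for tup in product(*groups):
        if all(tup[i] < tup[i + 1] for i in range(len(tup) - 1)):
            count += 1
    return float(count)


def brute_cu(groups):
    return float(sum((l + 1) * sum(g) for l, g in enumerate(groups)))


def brute_new(groups):
    total = 0.0
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            for a in groups[i]:
                for b in groups[j]:
                    if b > a:
                        total += b - a
    return total


def brute_abs_rank_diff(groups):
    """Sum of |rank difference| over every cross-group pair."""
    total = 0.0
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            for a in groups[i]:
                for b in groups[j]:
                    total += abs(b - a)
    return total


# ---------------------------------------------------------------------------
# independent null-distribution enumerator

def iter_splits(sizes):
    """Every unordered assignment of ranks 1..N to groups of the given sizes."""
    N = sum(sizes)

    def rec(remaining, idx):
        if idx == len(sizes) - 1:
            yield [list(remaining)]
            return
        for chosen in combinations(remaining, sizes[idx]):
            rest = [r for r in remaining if r not in set(chosen)]
            for tail in rec(rest, idx + 1):
                yield [list(chosen)] + tail

    yield from rec(list(range(1, N + 1)), 0)


def enumerated_moments(sizes, stat=brute_new):
    """Exact (Fraction) null mean and variance of a statistic by enumeration."""
    total = 0
    s_sum = Fraction(0)
    s2_sum = Fraction(0)
    for split in iter_splits(sizes):
        s = Fraction(stat(split)).limit_denominator(2)
        total += 1
        s_sum += s
        s2_sum += s * s
    mean = s_sum / total
    return mean, s2_sum / total - mean * mean


def all_compositions(max_n=8, ks=(2, 3, 4)):
    out = []
    for k in ks:
        for N in range(k, max_n + 1):
            for cuts in combinations(range(1, N), k - 1):
                edges = (0,) + cuts + (N,)
                out.append(tuple(b - a for a, b in zip(edges[:-1], edges[1:])))
    return out


# ---------------------------------------------------------------------------
# fixtures

@pytest.fixture
def rng():
    return np.random.default_rng(20140918)


def random_tiefree_sample(rng, k=None, max_size=8):
    k = k or int(rng.integers(2, 5))
    sizes = rng.integers(1, max_size + 1, size=k)
    values = []
    while True:
        values = [rng.standard_normal(n) for n in sizes]
        if np.unique(np.concatenate(values)).size == sum(sizes):
            return GroupedSample([f"g{i}" for i in range(k)], values)


def ranked_from_lists(groups):
    return RankedSample(tuple(range(len(groups))),
                       [np.asarray(g, dtype=float) for g in groups])


@pytest.fixture
def four_group_csv(tmp_path, rng):
    """Synthetic long-format file with the 17/17/18/16 dose-group layout."""
    sizes = {"0": 17, "10": 17, "20": 18, "40": 16}
    rows = ["group,value"]
    for shift, (label, n) in enumerate(sizes.items()):
        for v in rng.normal(loc=0.5 * shift, size=n):
            rows.append(f"{label},{v:.6f}")
    path = tmp_path / "doses.csv"
    path.write_text("\n".join(rows) + "\n")
    return path, list(sizes), tuple(sizes.values())
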