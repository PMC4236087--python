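import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ranktrend import (
    GroupedSample,
    RankedSample,
    assign_ranks,
    cu_statistic,
    jt_statistic,
    mjt_statistic,
    rank_difference_statistic,
    tm_statistic,
)
from ranktrend._batch import batch_statistics

from .conftest import (
    brute_abs_rank_diff,
    brute_cu,
    brute_jt,
    brute_mjt,
    brute_new,
    brute_tm,
    random_tiefree_sample,
    ranked_from_lists,
)


class TestGroupedSample:
    def test_basic_properties(self):
        s = GroupedSample(["a", "b", "c"], [[1.0], [2.0, 3.0], [4.0]])
        assert s.k == 3
        assert s.sizes == (1, 2, 1)
        assert s.total_n == 4

    def test_rejects_single_group(self):
        with pytest.raises(ValueError, match="at least 2 groups"):
            GroupedSample(["a"], [[1.0, 2.0]])

    def test_rejects_empty_group(self):
        with pytest.raises(ValueError, match="non-empty"):
            GroupedSample(["a", "b"], [[1.0], []])

    def test_rejects_nonfinite(self):
        with pytest.raises(ValueError, match="non-finite"):
            GroupedSample(["a", "b"], [[1.0], [np.nan]])

    def test_rejects_duplicate_labels(self):
        with pytest.raises(ValueError, match="unique"):
            GroupedSample(["a", "a"], [[1.0], [2.0]])

    def test_reversed_flips_order(self):
        s = GroupedSample(["a", "b"], [[1.0], [2.0, 3.0]])
        assert s.reversed().groups == ("b", "a")
        assert s.reversed().sizes == (2, 1)


class TestAssignRanks:
    def test_distinct_values(self):
        rs = assign_ranks(GroupedSample(["A", "B"], [[1.2, 3.4], [2.2, 4.1]]))
        assert list(rs.ranks[0]) == [1, 3]
        assert list(rs.ranks[1]) == [2, 4]
        assert not rs.tie_flag

    def test_midranks_and_tie_flag(self):
        rs = assign_ranks(GroupedSample(["A", "B"], [[5.0, 5.0], [7.0]]))
        assert list(rs.ranks[0]) == [1.5, 1.5]
        assert list(rs.ranks[1]) == [3]
        assert rs.tie_flag

    def test_monotone_transform_gives_identical_ranks(self, rng):
        s = random_tiefree_sample(rng)
        transformed = GroupedSample(s.groups, [np.exp(v) for v in s.values])
        a, b = assign_ranks(s), assign_ranks(transformed)
        for ra, rb in zip(a.ranks, b.ranks):
            np.testing.assert_array_equal(ra, rb)

    def test_rank_sum_conserved_with_ties(self, rng):
        values = rng.integers(0, 4, size=12).astype(float)
        s = GroupedSample(["a", "b", "c"], np.split(values, [4, 8]))
        rs = assign_ranks(s)
        total = sum(r.sum() for r in rs.ranks)
        assert total == 12 * 13 / 2

    def test_tiefree_ranks_are_permutation(self, rng):
        s = random_tiefree_sample(rng)
        rs = assign_ranks(s)
        pooled = np.sort(np.concatenate(rs.ranks))
        np.testing.assert_array_equal(pooled, np.arange(1, s.total_n + 1))


class TestHandExamples:
    """Small cases whose values were enumerated by hand."""

    def test_jt_two_groups(self):
        assert jt_statistic(ranked_from_lists([[1, 3], [2, 4]])) == 3

    def test_jt_reversed_is_zero(self):
        assert jt_statistic(ranked_from_lists([[3, 4], [1, 2]])) == 0

    def test_jt_three_singletons(self):
        assert jt_statistic(ranked_from_lists([[1], [2], [3]])) == 3

    def test_mjt_three_singletons(self):
        assert mjt_statistic(ranked_from_lists([[1], [2], [3]])) == 4

    def test_mjt_reversed_singletons(self):
        assert mjt_statistic(ranked_from_lists([[3], [2], [1]])) == 0

    def test_tm_mw_special_case(self):
        assert tm_statistic(ranked_from_lists([[1, 3], [2, 4]])) == 3

    def test_tm_three_singletons(self):
        assert tm_statistic(ranked_from_lists([[1], [2], [3]])) == 1
        assert tm_statistic(ranked_from_lists([[3], [2], [1]])) == 0

    def test_cu_three_singletons(self):
        assert cu_statistic(ranked_from_lists([[1], [2], [3]])) == 14
        assert cu_statistic(ranked_from_lists([[3], [2], [1]])) == 10

    def test_rank_difference_two_groups(self):
        # (2-1) + (4-1) + 0 + (4-3)
        assert rank_difference_statistic(ranked_from_lists([[1, 3], [2, 4]])) == 5

    def test_rank_difference_three_singletons(self):
        assert rank_difference_statistic(ranked_from_lists([[1], [2], [3]])) == 4
        assert rank_difference_statistic(ranked_from_lists([[3], [2], [1]])) == 0

    def test_jt_ties_count_half(self):
        rs = assign_ranks(GroupedSample(["A", "B"], [[5.0, 5.0], [5.0, 7.0]]))
        # cross pairs: two tied (1/2 each) plus two concordant
        assert jt_statistic(rs) == pytest.approx(3.0)


class TestAgainstBruteForce:
    @pytest.mark.parametrize("trial", range(25))
    def test_all_statistics_match_naive_loops(self, trial):
        rng = np.random.default_rng(1000 + trial)
        s = random_tiefree_sample(rng, max_size=6)
        ranked = assign_ranks(s)
        groups = [list(r) for r in ranked.ranks]
        assert jt_statistic(ranked) == pytest.approx(brute_jt(groups))
        assert mjt_statistic(ranked) == pytest.approx(brute_mjt(groups))
        assert tm_statistic(ranked) == pytest.approx(brute_tm(groups))
        assert cu_statistic(ranked) == pytest.approx(brute_cu(groups))
        assert rank_difference_statistic(ranked) == pytest.approx(brute_new(groups))

    def test_tm_dp_with_ties_strict_only(self):
        rs = assign_ranks(GroupedSample(["a", "b", "c"], [[1.0, 2.0], [2.0], [3.0]]))
        groups = [list(r) for r in rs.ranks]
        assert tm_statistic(rs) == brute_tm(groups)


class TestInvariants:
    @pytest.mark.parametrize("trial", range(30))
    def test_reversal_identities(self, trial):
        rng = np.random.default_rng(2000 + trial)
        s = random_tiefree_sample(rng, max_size=6)
        ranked = assign_ranks(s)
        groups = [list(r) for r in ranked.ranks]
        cross_pairs = sum(
            len(groups[i]) * len(groups[j])
            for i in range(len(groups)) for j in range(i + 1, len(groups))
        )
        assert (jt_statistic(ranked) + jt_statistic(ranked.reversed())
                == pytest.approx(cross_pairs))
        assert (rank_difference_statistic(ranked)
                + rank_difference_statistic(ranked.reversed())
                == pytest.approx(brute_abs_rank_diff(groups)))

    def test_k2_collapse_tm_jt_mjt(self, rng):
        for _ in range(10):
            s = random_tiefree_sample(rng, k=2)
            ranked = assign_ranks(s)
            assert tm_statistic(ranked) == jt_statistic(ranked)
            assert mjt_statistic(ranked) == jt_statistic(ranked)

    @given(st.integers(0, 2 ** 32 - 1))
    @settings(max_examples=25, deadline=None)
    def test_monotone_transform_invariance(self, seed):
        rng = np.random.default_rng(seed)
        s = random_tiefree_sample(rng, max_size=5)
        t = GroupedSample(s.groups, [np.expm1(v) + 3 * v for v in s.values])
        a, b = assign_ranks(s), assign_ranks(t)
        for fn in (jt_statistic, mjt_statistic, tm_statistic, cu_statistic,
                   rank_difference_statistic):
            assert fn(a) == pytest.approx(fn(b))


class TestBatchAgreement:
    """The vectorized engine must reproduce the scalar statistics exactly."""

    @pytest.mark.parametrize("sizes", [(3, 4), (2, 3, 4), (5, 1, 3, 2)])
    def test_batch_matches_scalar(self, rng, sizes):
        B, N = 40, sum(sizes)
        values = rng.standard_normal((B, N))
        batch = batch_statistics(values, sizes)
        splits = np.cumsum(sizes)[:-1]
        for b in range(B):
            sample = GroupedSample(
                [f"g{i}" for i in range(len(sizes))], np.split(values[b], splits))
            ranked = assign_ranks(sample)
            assert batch["jt"][b] == pytest.approx(jt_statistic(ranked))
            assert batch["mjt"][b] == pytest.approx(mjt_statistic(ranked))
            assert batch["tm"][b] == pytest.approx(tm_statistic(ranked))
            assert batch["cu"][b] == pytest.approx(cu_statistic(ranked))
            assert batch["new"][b] == pytest.approx(
                rank_difference_statistic(ranked))

    def test_batch_handles_ties(self, rng):
        sizes = (3, 3, 2)
        values = rng.integers(0, 3, size=(20, 8)).astype(float)
        batch = batch_statistics(values, sizes)
        splits = np.cumsum(sizes)[:-1]
        for b in range(20):
            ranked = assign_ranks(GroupedSample(
                ["a", "b", "c"], np.split(values[b], splits)))
            assert batch["jt"][b] == pytest.approx(jt_statistic(ranked))
            assert batch["new"][b] == pytest.approx(
                rank_difference_statistic(ranked))

    def test_batch_rejects_bad_shapes(self, rng):
        with pytest.raises(ValueError, match="row length"):
            batch_statistics(rng.standard_normal((5, 7)), (3, 3))
        with pytest.raises(ValueError, match="unknown tests"):
            batch_statistics(rng.standard_normal((5, 6)), (3, 3), tests=("zz",))
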