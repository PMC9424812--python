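"""Subset scoring (D, R, contribution) and the greedy searches against
independent step-wise exhaustive oracles."""

import numpy as np
import pytest

from imrmr import (
    CandidateSubset,
    FeatureTable,
    PairwiseStats,
    classic_mrmr_rank,
    make_plan,
    rank_subsets,
    relevance_profile,
    subset_contribution,
    subset_redundancy,
    subset_relevance,
)
from tests.conftest import random_table
from tests.oracles import mrmr_oracle, subset_rank_oracle


@pytest.fixture(scope="module")
def stats_and_profile():
    t = random_table(seed=21, n=60, m=8, k=2)
    stats = PairwiseStats(t)
    prof = relevance_profile(t, alpha=0.5, codes=stats.codes)
    return t, stats, prof


class TestSubsetScores:
    def test_contribution_is_sum_of_ic(self, stats_and_profile):
        _, _, prof = stats_and_profile
        s = CandidateSubset(1, (0, 3))
        assert subset_contribution(s, prof) == pytest.approx(prof.ic[0] + prof.ic[3])
        single = CandidateSubset(2, (5,))
        assert subset_contribution(single, prof) == pytest.approx(prof.ic[5])

    def test_contribution_out_of_profile_is_error(self, stats_and_profile):
        _, _, prof = stats_and_profile
        with pytest.raises(ValueError):
            subset_contribution(CandidateSubset(1, (99,)), prof)

    def test_relevance_is_weighted_sum(self, stats_and_profile):
        _, stats, _ = stats_and_profile
        s = CandidateSubset(1, (1, 4))
        d = subset_relevance(s, stats, beta=0.5)
        expected = 0.5 * (stats.class_mi[1] + stats.class_mi[4]) + 0.5 * (
            stats.class_corr_mag[1] + stats.class_corr_mag[4]
        )
        assert d == pytest.approx(expected, abs=1e-12)
        # beta = 1 reduces to the pure MI sum
        assert subset_relevance(s, stats, beta=1.0) == pytest.approx(
            stats.class_mi[1] + stats.class_mi[4], abs=1e-12
        )

    def test_beta_contract(self, stats_and_profile):
        _, stats, _ = stats_and_profile
        with pytest.raises(ValueError):
            subset_relevance(CandidateSubset(1, (0,)), stats, beta=0.0)

    def test_redundancy_mean_of_equal_terms(self, stats_and_profile):
        _, stats, _ = stats_and_profile
        fx = CandidateSubset(1, (0, 1))
        fy = CandidateSubset(2, (2, 3))
        one = subset_redundancy(fx, [fy], stats, beta=0.5)
        two = subset_redundancy(fx, [fy, fy], stats, beta=0.5)
        assert two == pytest.approx(one, abs=1e-12)

    def test_redundancy_higher_against_duplicates(self):
        t = random_table(seed=22, n=80, m=6, k=2, n_informative=2)
        X = t.X.copy()
        X[:, 4] = X[:, 0]  # subset (4,5) duplicates part of (0,1)
        X[:, 5] = X[:, 1]
        t = FeatureTable(X, t.y, t.feature_names, t.class_labels)
        stats = PairwiseStats(t)
        target = CandidateSubset(1, (0, 1))
        dup = subset_redundancy(CandidateSubset(2, (4, 5)), [target], stats, beta=0.5)
        indep = subset_redundancy(CandidateSubset(3, (2, 3)), [target], stats, beta=0.5)
        assert dup > indep

    def test_redundancy_requires_selected(self, stats_and_profile):
        _, stats, _ = stats_and_profile
        with pytest.raises(ValueError):
            subset_redundancy(CandidateSubset(1, (0,)), [], stats, beta=0.5)

    def test_self_pairs_excluded_for_overlapping_subsets(self, stats_and_profile):
        _, stats, _ = stats_and_profile
        fx = CandidateSubset(1, (0, 1))
        r_overlap = subset_redundancy(fx, [fx], stats, beta=1.0)
        # only the two cross pairs (0,1) and (1,0) remain
        expected = 2 * stats.feature_mi[0, 1]
        assert r_overlap == pytest.approx(expected, abs=1e-12)


class TestRankSubsets:
    def test_single_subset_degenerate(self):
        t = random_table(seed=23, n=40, m=4, k=2)
        plan = make_plan(range(4))
        # collapse to one group
        from imrmr import egm_partition
        plan = egm_partition(range(4), 1)
        seq = rank_subsets(plan, t, alpha=0.5, beta=0.5)
        assert len(seq) == 1 and seq.ordered[0].R is None

    def test_matches_exhaustive_oracle(self):
        for seed in range(5):
            t = random_table(seed=100 + seed, n=50, m=12, k=2)
            stats = PairwiseStats(t)
            prof = relevance_profile(t, alpha=0.5, codes=stats.codes)
            plan = make_plan(prof.ranking)
            seq = rank_subsets(plan, t, alpha=0.5, beta=0.4, stats=stats, profile=prof)
            subsets = [(s.index, s.members) for s in plan.subsets]
            expected = subset_rank_oracle(subsets, stats.codes, t.X, t.class_codes, 0.5, 0.4)
            assert [s.subset.index for s in seq.ordered] == expected

    def test_duplicated_signal_subset_ranked_last(self):
        rng = np.random.default_rng(30)
        n = 120
        codes = rng.integers(0, 2, size=n)
        sig = codes * 3.0 + rng.standard_normal((2, n))          # 2 signal features
        noise = rng.standard_normal((2, n))
        X = np.column_stack([sig[0], sig[1], sig[0], sig[1], noise[0], noise[1]])
        t = FeatureTable(X, np.array(["a", "b"], dtype=object)[codes],
                         tuple(f"f{j}" for j in range(6)), ("a", "b"))
        a = CandidateSubset(1, (0, 1))   # the originals
        b = CandidateSubset(2, (2, 3))   # exact duplicates of subset 1
        c = CandidateSubset(3, (4, 5))   # independent noise
        from imrmr.grouping import GroupingPlan
        plan = GroupingPlan(fc=2, r=3, subsets=(a, b, c))
        seq = rank_subsets(plan, t, alpha=0.5, beta=0.5)
        order = [s.subset.index for s in seq.ordered]
        assert order[0] == 1          # richest in originals first (tie-break by index)
        assert order.index(2) == 2    # the duplicate subset is pushed behind noise

    def test_every_subset_appears_once(self, small_table):
        plan = make_plan(range(small_table.n_features))
        seq = rank_subsets(plan, small_table, alpha=0.7, beta=0.7)
        assert sorted(s.subset.index for s in seq.ordered) == [s.index for s in plan.subsets]


class TestClassicMrmr:
    def test_single_feature(self):
        t = random_table(seed=24, n=30, m=1, k=2)
        assert list(classic_mrmr_rank(t)) == [0]

    def test_matches_exhaustive_oracle(self):
        for seed in range(5):
            t = random_table(seed=200 + seed, n=50, m=10, k=2)
            stats = PairwiseStats(t)
            assert list(classic_mrmr_rank(t, stats=stats)) == mrmr_oracle(
                stats.codes, t.class_codes
            )

    def test_duplicate_of_top_feature_deferred(self):
        rng = np.random.default_rng(31)
        n = 150
        codes = rng.integers(0, 2, size=n)
        f0 = codes * 3.0 + 0.3 * rng.standard_normal(n)   # strongest feature
        f1 = f0.copy()                                    # exact duplicate
        f2 = codes * 2.0 + rng.standard_normal(n)         # weaker but informative
        f3 = rng.standard_normal(n)
        X = np.column_stack([f0, f1, f2, f3])
        t = FeatureTable(X, np.array(["a", "b"], dtype=object)[codes],
                         ("f0", "f1", "f2", "f3"), ("a", "b"))
        order = list(classic_mrmr_rank(t))
        assert order[0] == 0
        assert order.index(2) < order.index(1)  # duplicate behind the other informative feature
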