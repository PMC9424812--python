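"""Sequence flattening, the SFS / SFSFs wrappers and the α/β grid search."""

import numpy as np
import pytest
from sklearn.dummy import DummyClassifier

from imrmr import (
    CandidateSubset,
    SubsetSequence,
    default_classifier,
    flatten_sequence,
    grid_select,
    make_evaluator,
    rank_subsets,
    sfs_select,
    sfsfs_select,
    stratified_split,
)
from imrmr.ranking import SubsetScore
from tests.conftest import random_table


def make_sequence(member_lists):
    scores = tuple(
        SubsetScore(subset=CandidateSubset(i + 1, tuple(m)), D=0.0, R=None,
                    criterion=None, contribution=0.0)
        for i, m in enumerate(member_lists)
    )
    return SubsetSequence(ordered=scores, alpha=0.5, beta=0.5)


class TestFlatten:
    def test_concatenation(self):
        seq = make_sequence([(3, 1), (2,)])
        assert flatten_sequence(seq) == [3, 1, 2]

    def test_single_subset_keeps_member_order(self):
        assert flatten_sequence(make_sequence([(5, 0, 2)])) == [5, 0, 2]


class TestSfs:
    def test_single_feature(self):
        feats, acc, path = sfs_select([0], lambda fs: 80.0)
        assert feats == (0,) and acc == 80.0 and path == [80.0]

    def test_best_prefix_from_known_accuracy_function(self):
        # features 0-2 carry signal, the rest only hurt
        def evaluate(fs):
            good = len(set(fs) & {0, 1, 2})
            return 60.0 + 10.0 * good - 1.0 * (len(fs) - good)

        order = list(range(10))
        feats, acc, path = sfs_select(order, evaluate)
        assert feats == (0, 1, 2)
        assert acc == 90.0
        # exhaustive check: the returned accuracy is the max over all prefixes
        assert acc == max(evaluate(tuple(order[:k])) for k in range(1, 11))

    def test_constant_accuracy_ties_to_shortest(self):
        feats, acc, _ = sfs_select(list(range(6)), lambda fs: 50.0)
        assert feats == (0,)

    def test_duplicate_order_rejected(self):
        with pytest.raises(ValueError):
            sfs_select([0, 1, 1], lambda fs: 1.0)


class TestSfsfs:
    def test_immediate_stop_on_first_subset(self):
        seq = make_sequence([(0, 1), (2, 3)])
        calls = []

        def evaluate(fs):
            calls.append(fs)
            return 90.0

        feats, acc, path, converged = sfsfs_select(seq, evaluate, raw_accuracy=85.0)
        assert feats == (0, 1) and converged and len(calls) == 1

    def test_two_subsets_needed(self):
        seq = make_sequence([(0, 1), (2, 3), (4, 5)])
        table = {(0, 1): 70.0, (0, 1, 2, 3): 88.0, (0, 1, 2, 3, 4, 5): 95.0}
        feats, acc, path, converged = sfsfs_select(seq, table.__getitem__, raw_accuracy=85.0)
        assert feats == (0, 1, 2, 3) and acc == 88.0 and converged

    def test_never_converges_returns_best_cumulative(self):
        seq = make_sequence([(0,), (1,), (2,)])
        table = {(0,): 60.0, (0, 1): 72.0, (0, 1, 2): 65.0}
        feats, acc, path, converged = sfsfs_select(seq, table.__getitem__, raw_accuracy=99.0)
        assert not converged
        assert feats == (0, 1) and acc == 72.0


class TestEvaluator:
    def test_cv_never_sees_test_data(self, small_table):
        split = stratified_split(small_table, 0.7, seed=0)
        # corrupt the test labels: a train-only CV score must not change
        corrupted = type(split)(
            train=split.train,
            test=type(split.test)(
                split.test.X,
                np.array([split.test.class_labels[0]] * split.test.n_samples, dtype=object),
                split.test.feature_names,
                split.test.class_labels,
            ),
            seed=split.seed,
            train_fraction=split.train_fraction,
        )
        clf = default_classifier(0, 20)
        a = make_evaluator(split, clf, protocol="cv", seed=0)((0, 1, 2))
        b = make_evaluator(corrupted, clf, protocol="cv", seed=0)((0, 1, 2))
        assert a == b

    def test_protocols_are_deterministic(self, small_table):
        split = stratified_split(small_table, 0.7, seed=1)
        clf = default_classifier(0, 20)
        for protocol in ("cv", "paper_faithful"):
            e1 = make_evaluator(split, clf, protocol=protocol, seed=3)
            e2 = make_evaluator(split, clf, protocol=protocol, seed=3)
            assert e1((0, 1)) == e2((0, 1))
            assert 0.0 <= e1((0, 1)) <= 100.0


class TestGridSelect:
    def test_single_cell_equals_single_wrapper_run(self, small_table):
        res = grid_select(
            small_table, alphas=[0.5], betas=[0.5],
            estimator=default_classifier(0, 20), seed=2,
        )
        assert len(res.grid) == 1
        assert res.alpha == 0.5 and res.beta == 0.5
        assert res.features == res.grid[0].features

    def test_constant_classifier_ties_break_low_lexicographic(self, small_table):
        # DummyClassifier gives identical accuracy for every feature set,
        # so every cell ties: expect the shortest subset at the first cell
        res = grid_select(
            small_table, alphas=[0.3, 0.7], betas=[0.4, 0.8],
            estimator=DummyClassifier(strategy="most_frequent"), seed=0,
        )
        assert len(res.features) == 1
        assert (res.alpha, res.beta) == (0.3, 0.4)

    def test_selected_features_valid_and_duplicate_free(self, multiclass_table):
        res = grid_select(
            multiclass_table, alphas=[0.5], betas=[0.3, 0.9],
            estimator=default_classifier(0, 20), seed=4,
        )
        assert len(res.features) == len(set(res.features))
        assert set(res.features) <= set(range(multiclass_table.n_features))
        assert 0.5 in res.b_max_per_alpha

    def test_sfsfs_mode_runs_and_flags_convergence(self, small_table):
        res = grid_select(
            small_table, alphas=[0.5], betas=[0.5],
            estimator=default_classifier(0, 20), seed=5, mode="sfsfs",
        )
        assert res.mode == "sfsfs"
        assert isinstance(res.converged, bool)

    def test_wrappers_match_exhaustive_oracle_with_stub(self, small_table):
        """With a deterministic stub accuracy, SFS equals brute-force max
        over prefixes and SFSFs equals the first qualifying cumulative set."""
        split = stratified_split(small_table, 0.7, seed=0)
        from imrmr import PairwiseStats, make_plan, relevance_profile
        stats = PairwiseStats(split.train)
        prof = relevance_profile(split.train, 0.5, codes=stats.codes)
        plan = make_plan(prof.ranking)
        seq = rank_subsets(plan, split.train, 0.5, 0.5, stats=stats, profile=prof)

        def stub(fs):
            return 50.0 + sum((hash(("acc", f)) % 97) / 10 for f in fs) - 2.0 * len(fs)

        order = flatten_sequence(seq)
        feats, acc, _ = sfs_select(order, stub)
        best_k = max(range(1, len(order) + 1), key=lambda k: (stub(tuple(order[:k])), -k))
        assert feats == tuple(order[:best_k])

        raw = stub(tuple(order))
        feats2, acc2, _, conv = sfsfs_select(seq, stub, raw)
        cum = []
        expected = None
        for s in seq.ordered:
            cum.extend(s.subset.members)
            if stub(tuple(cum)) >= raw:
                expected = tuple(cum)
                break
        if expected is not None:
            assert conv and feats2 == expected
        else:
            assert not conv
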