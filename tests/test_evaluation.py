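import numpy as np
import pandas as pd
import pytest

from mmclassify.evaluation import (
    accuracy_at_specificity,
    auc,
    kfold_roc,
    loo_optimal_cutoff,
    optimal_cutoff,
)
from mmclassify.lefse import DiscriminationConfig


def pair_counting_auc(scores, labels):
    """O(n^2) oracle: fraction of (pos, neg) pairs ranked correctly, ties 1/2."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    pos = scores[labels]
    neg = scores[~labels]
    wins = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
    return wins / (len(pos) * len(neg))


def exhaustive_best_accuracy(scores, labels):
    """Oracle: best achievable accuracy over a dense cutoff grid."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    grid = np.concatenate([[scores.min() - 1], np.unique(scores), [scores.max() + 1],
                           np.linspace(scores.min() - 1, scores.max() + 1, 2001)])
    return max(((scores >= c) == labels).mean() for c in grid)


class TestAuc:
    def test_matches_pair_counting_oracle(self, rng):
        for _ in range(20):
            scores = np.round(rng.normal(size=12), 1)  # rounding forces ties
            labels = rng.random(12) < 0.5
            if labels.all() or not labels.any():
                continue
            assert auc(scores, labels) == pytest.approx(pair_counting_auc(scores, labels), abs=1e-9)

    def test_perfect_and_reversed(self):
        labels = [0, 0, 1, 1]
        assert auc([1, 2, 3, 4], labels) == 1.0
        assert auc([4, 3, 2, 1], labels) == 0.0

    def test_complement_identity(self, rng):
        scores = rng.normal(size=30)
        labels = rng.random(30) < 0.4
        assert auc(scores, labels) + auc(-scores, labels) == pytest.approx(1.0, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            auc([1, 2], [1, 1])


class TestOptimalCutoff:
    def test_matches_exhaustive_grid(self, rng):
        for _ in range(20):
            scores = rng.normal(size=15)
            labels = rng.random(15) < 0.5
            if labels.all() or not labels.any():
                continue
            c = optimal_cutoff(scores, labels)
            achieved = ((scores >= c) == labels).mean()
            assert achieved == pytest.approx(exhaustive_best_accuracy(scores, labels), abs=1e-9)

    def test_separable_case(self):
        c = optimal_cutoff([1.0, 2.0, 5.0, 6.0], [0, 0, 1, 1])
        assert 2.0 < c < 5.0


class TestAccuracyAtSpecificity:
    def test_reaches_requested_specificity(self, rng):
        scores = rng.normal(size=40)
        labels = rng.random(40) < 0.5
        labels[0], labels[1] = True, False
        res = accuracy_at_specificity(scores, labels, spec=0.8)
        assert res.specificity >= 0.8
        assert res.attained

    def test_smallest_qualifying_cutoff(self):
        scores = np.array([1.0, 2.0, 3.0, 4.0])
        labels = np.array([0, 0, 1, 1])
        res = accuracy_at_specificity(scores, labels, spec=1.0)
        assert res.specificity == 1.0 and res.sensitivity == 1.0 and res.accuracy == 1.0


class TestKfoldRoc:
    def test_planted_data_high_auc(self, planted_rel, planted_labels):
        roc = kfold_roc(planted_rel, planted_labels, k=10, config=DiscriminationConfig(seed=0), random_state=0)
        assert roc.auc > 0.8
        assert roc.mean_fpr.shape == roc.mean_tpr.shape == (101,)
        assert roc.mean_tpr[-1] == 1.0
        assert np.all(np.diff(roc.mean_tpr) >= -1e-12)
        assert len(roc.fold_curves) == 10
        assert set(roc.fold_assignments) == set(range(10))

    def test_deterministic_given_seeds(self, planted_rel, planted_labels):
        a = kfold_roc(planted_rel, planted_labels, k=5, config=DiscriminationConfig(seed=1), random_state=1)
        b = kfold_roc(planted_rel, planted_labels, k=5, config=DiscriminationConfig(seed=1), random_state=1)
        assert a.auc == b.auc
        np.testing.assert_array_equal(a.mean_tpr, b.mean_tpr)

    def test_too_many_folds_for_stratification(self, planted_rel, planted_labels):
        with pytest.raises(ValueError, match="stratify"):
            kfold_roc(planted_rel, planted_labels, k=30, config=DiscriminationConfig(seed=0))

    def test_loo_mode_single_pooled_curve(self, planted_rel, planted_labels):
        roc = kfold_roc(planted_rel, planted_labels, k=len(planted_labels), config=DiscriminationConfig(seed=0))
        assert len(roc.fold_curves) == 1


class TestLooOptimalCutoff:
    def test_separable_scores(self):
        scores = np.concatenate([np.arange(10), np.arange(20, 30)]).astype(float)
        labels = np.array([0] * 10 + [1] * 10)
        res = loo_optimal_cutoff(scores, labels)
        assert res.accuracy == 1.0 and 10 < res.cutoff < 20

    def test_nan_scores_excluded(self):
        scores = np.array([np.nan, 1.0, 2.0, 5.0, 6.0, np.nan])
        labels = np.array([1, 0, 0, 1, 1, 0])
        res = loo_optimal_cutoff(scores, labels)
        assert res.accuracy == 1.0
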