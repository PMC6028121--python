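import numpy as np
import pandas as pd
import pytest
from sklearn.base import clone

from mmclassify.abundance import AbundanceTable
from mmclassify.lefse import DiscriminationConfig
from mmclassify.risk import (
    RiskIndexClassifier,
    RiskModel,
    apply_model,
    arcsine_sqrt,
    fdr_adjust,
    loo_risk_indices,
    permutation_test,
    risk_index,
)


class TestArcsineSqrt:
    def test_closed_forms(self):
        assert arcsine_sqrt(0.0) == 0.0
        assert arcsine_sqrt(1.0) == pytest.approx(np.pi / 2)
        assert arcsine_sqrt(0.25) == pytest.approx(np.pi / 6)

    def test_vectorized_and_monotone(self):
        p = np.linspace(0, 1, 50)
        out = arcsine_sqrt(p)
        assert np.all(np.diff(out) > 0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            arcsine_sqrt(1.5)
        with pytest.raises(ValueError):
            arcsine_sqrt(-0.2)

    def test_tiny_negative_noise_clipped(self):
        assert arcsine_sqrt(-1e-15) == 0.0


class TestRiskModel:
    def test_overlapping_sets_rejected(self):
        with pytest.raises(ValueError, match="disjoint"):
            RiskModel({"A"}, {"A"})

    def test_empty_model_rejected(self):
        with pytest.raises(ValueError, match="at least one"):
            RiskModel(set(), set())

    def test_worked_example(self):
        model = RiskModel({"A"}, {"B"})
        ri = risk_index({"A": 0.04, "B": 0.01}, model)
        assert ri == pytest.approx(0.101190, abs=1e-6)

    def test_missing_taxa_contribute_zero(self):
        model = RiskModel({"A"}, {"B"})
        assert risk_index({"A": 0.04}, model) == pytest.approx(arcsine_sqrt(0.04))


class TestFdrAdjust:
    def test_bh_arithmetic(self):
        np.testing.assert_allclose(fdr_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_monotone_after_sorting(self, rng):
        q = fdr_adjust(np.sort(rng.random(30)))
        assert np.all(np.diff(q) >= -1e-15)

    def test_empty_input(self):
        assert fdr_adjust([]).size == 0


class TestRiskIndexClassifier:
    def test_fit_predict_on_planted_data(self, planted_rel, planted_labels):
        X = planted_rel.to_feature_frame()
        y = planted_labels.to_numpy()
        clf = RiskIndexClassifier(random_state=0).fit(X, y)
        assert set(np.unique(clf.predict(X))) <= {0, 1}
        assert (clf.predict(X) == y).mean() > 0.8
        assert clf.model_.n_taxa == clf.support_.sum()

    def test_decision_function_is_risk_index(self, planted_rel, planted_labels):
        X = planted_rel.to_feature_frame()
        clf = RiskIndexClassifier(random_state=0).fit(X, planted_labels.to_numpy())
        scores = clf.decision_function(X)
        manual = [
            risk_index(dict(zip(X.columns, row)), clf.model_) for row in X.to_numpy()
        ]
        np.testing.assert_allclose(scores, manual, atol=1e-12)

    def test_clone_and_params_round_trip(self):
        clf = RiskIndexClassifier(kw_alpha=0.01, random_state=4)
        assert clone(clf).get_params() == clf.get_params()

    def test_no_signal_raises(self, rng):
        X = rng.random((20, 10))
        X /= X.sum(axis=1, keepdims=True)
        y = np.arange(20) < 10
        with pytest.raises(ValueError, match="no discriminant taxa"):
            RiskIndexClassifier(kw_alpha=1e-6, random_state=0).fit(X, y)


class TestLooRiskIndices:
    def test_planted_signal_significant(self, planted_rel, planted_labels):
        res = loo_risk_indices(planted_rel, planted_labels, DiscriminationConfig(seed=0))
        assert res.mwu_p < 0.05
        assert res.observed_diff > 0
        assert res.risk_index.index.tolist() == planted_rel.sample_ids
        assert res.n_missing_folds == 0

    def test_label_swap_negates_scores_bit_exactly(self, planted_rel, planted_labels):
        cfg = DiscriminationConfig(seed=1)
        res1 = loo_risk_indices(planted_rel, planted_labels, cfg)
        res2 = loo_risk_indices(planted_rel, 1 - planted_labels, cfg)
        np.testing.assert_array_equal(res1.risk_index.to_numpy(), -res2.risk_index.to_numpy())
        assert res1.observed_diff == res2.observed_diff  # target class flips with the labels
        assert res1.mwu_p == res2.mwu_p

    def test_tiny_class_rejected(self, planted_rel):
        y = pd.Series(0, index=planted_rel.sample_ids)
        y.iloc[:2] = 1
        with pytest.raises(ValueError, match=">= 2"):
            loo_risk_indices(planted_rel, y, DiscriminationConfig(seed=0))


class TestPermutationTest:
    def test_planted_signal_small_p_and_floor(self, planted_rel, planted_labels):
        cfg = DiscriminationConfig(seed=0)
        observed = loo_risk_indices(planted_rel, planted_labels, cfg)
        p, res = permutation_test(planted_rel, planted_labels, cfg, B=19, observed=observed)
        assert p >= 1 / 20  # pseudocount floor
        assert p < 0.2
        assert res.perm_p == p

    def test_deterministic_given_seed(self, planted_rel, planted_labels):
        cfg = DiscriminationConfig(seed=42)
        obs = loo_risk_indices(planted_rel, planted_labels, cfg)
        p1, _ = permutation_test(planted_rel, planted_labels, cfg, B=9, observed=obs, fast=True)
        p2, _ = permutation_test(planted_rel, planted_labels, cfg, B=9, observed=obs, fast=True)
        assert p1 == p2

    def test_invalid_B_rejected(self, planted_rel, planted_labels):
        with pytest.raises(ValueError, match="B"):
            permutation_test(planted_rel, planted_labels, B=0)


class TestApplyModel:
    def test_cross_dialect_matching_and_unmatched_report(self):
        model = RiskModel({"k__Bacteria; p__Firmicutes"}, {"k__Bacteria; p__Lost"})
        data = pd.DataFrame(
            {"S1": [0.25, 0.75]},
            index=["k__Bacteria;p__Firmicutes", "k__Bacteria;p__Other"],
        )
        table = AbundanceTable(data, normalized=True)
        scores, unmatched = apply_model(model, table)
        assert scores.loc["S1"] == pytest.approx(np.pi / 6)
        assert unmatched == ["k__Bacteria; p__Lost"]

    def test_requires_normalized_table(self, tiny_counts):
        with pytest.raises(ValueError, match="normalized"):
            apply_model(RiskModel({"x"}, set()), tiny_counts)

    def test_no_match_raises(self):
        table = AbundanceTable(pd.DataFrame({"S1": [1.0]}, index=["g__A"]), normalized=True)
        with pytest.raises(ValueError, match="no model taxa"):
            apply_model(RiskModel({"g__Z"}, set()), table)
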