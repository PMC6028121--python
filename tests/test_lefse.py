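import numpy as np
import pandas as pd
import pytest
from scipy import stats
from sklearn.base import clone

from mmclassify.lefse import (
    DiscriminantTaxaSelector,
    DiscriminationConfig,
    discriminant_taxa,
    kruskal_wallis_2group,
    kruskal_wallis_screen,
    lda_effect_sizes,
    select_discriminant,
)


class TestKruskalWallis:
    def test_matches_scipy_with_ties(self, rng):
        X = np.round(rng.random((20, 15)), 1)  # rounding forces ties
        y = np.arange(20) < 9
        H, p = kruskal_wallis_2group(X, y)
        for j in range(15):
            ref = stats.kruskal(X[y, j], X[~y, j])
            assert H[j] == pytest.approx(ref.statistic, abs=1e-12)
            assert p[j] == pytest.approx(ref.pvalue, abs=1e-12)

    def test_constant_column_p_one(self):
        X = np.column_stack([np.ones(10), np.arange(10.0)])
        _, p = kruskal_wallis_2group(X, np.arange(10) < 5)
        assert p[0] == 1.0
        assert p[1] < 0.05

    def test_closed_form_separated_groups(self):
        X = np.array([[1.0], [2.0], [3.0], [4.0], [5.0], [6.0]])
        H, p = kruskal_wallis_2group(X, np.array([0, 0, 0, 1, 1, 1], dtype=bool))
        ref = stats.kruskal([1, 2, 3], [4, 5, 6])
        assert H[0] == pytest.approx(ref.statistic)
        assert p[0] == pytest.approx(ref.pvalue)

    def test_small_class_rejected(self):
        with pytest.raises(ValueError, match=">= 2"):
            kruskal_wallis_2group(np.zeros((5, 2)), np.array([1, 0, 0, 0, 0], dtype=bool))


class TestLdaEffectSizes:
    def test_stronger_shift_larger_score(self, rng):
        n = 30
        y = np.arange(n) < 15
        X = rng.normal(0.0, 1.0, (n, 3))
        X[y, 1] += 1.0
        X[y, 2] += 4.0
        scores = lda_effect_sizes(X, y, 30, 2 / 3, 1e6, np.random.default_rng(0))
        assert scores[2] > scores[1] > scores[0]

    def test_deterministic_given_rng_seed(self, rng):
        X = rng.random((20, 4))
        y = np.arange(20) < 10
        a = lda_effect_sizes(X, y, 30, 2 / 3, 1e6, np.random.default_rng(5))
        b = lda_effect_sizes(X, y, 30, 2 / 3, 1e6, np.random.default_rng(5))
        np.testing.assert_array_equal(a, b)


class TestSelectDiscriminant:
    def test_label_swap_leaves_support_invariant(self, rng):
        X = rng.random((24, 40))
        y = np.arange(24) < 12
        X[y, :5] *= 3
        X /= X.sum(axis=1, keepdims=True)
        s1, e1, _, l1 = select_discriminant(X, y, DiscriminationConfig(seed=3), np.random.default_rng(3))
        s2, e2, _, l2 = select_discriminant(X, ~y, DiscriminationConfig(seed=3), np.random.default_rng(3))
        np.testing.assert_array_equal(s1, s2)
        np.testing.assert_array_equal(e1, ~e2)
        np.testing.assert_array_equal(l1, l2)

    def test_planted_taxa_selected_and_signed(self, planted_rel, planted_labels, planted_dataset):
        taxa = discriminant_taxa(planted_rel, planted_labels, DiscriminationConfig(seed=0))
        selected = {t.taxon_id for t in taxa}
        planted = {t for t, _, _ in planted_dataset.truth["feature00"]}
        assert len(planted & selected) >= 4  # >= 80% of 5 planted taxa
        by_id = {t.taxon_id: t for t in taxa}
        for t in planted & selected:
            assert by_id[t].enriched_class == 1


class TestSelectorEstimator:
    def test_sklearn_api(self, planted_rel, planted_labels):
        X = planted_rel.to_feature_frame()
        sel = DiscriminantTaxaSelector(random_state=0).fit(X, planted_labels.to_numpy())
        assert sel.support_.shape == (X.shape[1],)
        assert sel.transform(X).shape == (X.shape[0], sel.support_.sum())
        assert len(sel.get_support(indices=True)) == sel.support_.sum()
        assert set(clone(sel).get_params()) == set(sel.get_params())

    def test_deterministic_given_random_state(self, planted_rel, planted_labels):
        X = planted_rel.to_feature_frame()
        a = DiscriminantTaxaSelector(random_state=9).fit(X, planted_labels.to_numpy())
        b = DiscriminantTaxaSelector(random_state=9).fit(X, planted_labels.to_numpy())
        np.testing.assert_array_equal(a.support_, b.support_)
        np.testing.assert_array_equal(a.lda_log10_, b.lda_log10_)

    def test_more_than_two_classes_rejected(self):
        with pytest.raises(ValueError, match="two classes"):
            DiscriminantTaxaSelector().fit(np.random.default_rng(0).random((6, 3)), [0, 1, 2, 0, 1, 2])

    def test_results_records_only_selected(self, planted_rel, planted_labels):
        X = planted_rel.to_feature_frame()
        sel = DiscriminantTaxaSelector(random_state=0).fit(X, planted_labels.to_numpy())
        recs = sel.results_()
        assert len(recs) == sel.support_.sum()
        for r in recs:
            assert r.kw_p < sel.kw_alpha
            assert r.lda_log10 >= sel.lda_threshold


class TestScreenWrapper:
    def test_kw_screen_returns_taxon_ids(self, planted_rel, planted_labels, planted_dataset):
        hits = kruskal_wallis_screen(planted_rel, planted_labels)
        planted = {t for t, _, _ in planted_dataset.truth["feature00"]}
        assert len(planted & hits) >= 4

    def test_invalid_alpha_rejected(self):
        with pytest.raises(ValueError, match="kw_alpha"):
            DiscriminationConfig(kw_alpha=1.5)
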