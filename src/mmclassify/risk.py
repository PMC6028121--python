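"""Arcsine-root risk-index classification with leave-one-out and permutation testing.

A risk model is two disjoint taxon sets: taxa enriched in the target
class (e.g. tumors carrying a LoF mutation) and taxa enriched in the
reference class.  A sample's risk index is the difference of the summed
arcsine-square-root-transformed relative abundances of the two sets:

    RI = sum_{t in positive} asin(sqrt(a_t)) - sum_{t in negative} asin(sqrt(a_t))

The sum is deliberately unweighted: with tens of taxa and ~44 samples,
re-using LDA regression coefficients would overfit, whereas the
variance-stabilized unweighted sum keeps model flexibility low.

Significance of the observed between-class difference in held-out risk
indices is assessed by a two-sided Mann-Whitney U test and by an
empirical permutation null (labels shuffled, the full leave-one-out
pipeline — taxon selection inside every fold — re-run each time).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted
from statsmodels.stats.multitest import multipletests

from .abundance import AbundanceTable, canonical_lineage
from .lefse import DiscriminationConfig, select_discriminant

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# the index itself
# ---------------------------------------------------------------------------

def arcsine_sqrt(p):
    """Variance-stabilizing arcsin(sqrt(p)) for proportions, in [0, pi/2].

    Values outside [0,1] by more than 1e-12 raise; within tolerance they
    are clipped.
    """
    arr = np.asarray(p, dtype=float)
    if np.any(arr < -1e-12) or np.any(arr > 1 + 1e-12):
        raise ValueError("proportions must lie in [0, 1]")
    out = np.arcsin(np.sqrt(np.clip(arr, 0.0, 1.0)))
    return float(out) if np.isscalar(p) or arr.ndim == 0 else out


@dataclass
class RiskModel:
    """Taxon sets defining a risk-index classifier."""

    positive_taxa: set
    negative_taxa: set
    target_class: object = 1

    def __post_init__(self) -> None:
        self.positive_taxa = set(self.positive_taxa)
        self.negative_taxa = set(self.negative_taxa)
        if self.positive_taxa & self.negative_taxa:
            raise ValueError("positive and negative taxon sets must be disjoint")
        if not (self.positive_taxa | self.negative_taxa):
            raise ValueError("risk model must contain at least one taxon")

    @property
    def n_taxa(self) -> int:
        return len(self.positive_taxa) + len(self.negative_taxa)


def risk_index(sample_abundances, model: RiskModel) -> float:
    """Score one sample: sum of transformed positive taxa minus negative taxa.

    ``sample_abundances`` maps taxon id -> relative abundance; model taxa
    absent from the mapping contribute 0 (logged).
    """
    abund = dict(sample_abundances)
    missing = (model.positive_taxa | model.negative_taxa) - set(abund)
    if missing:
        logger.info("%d model taxa absent from sample; contributing 0", len(missing))
    pos = sum(arcsine_sqrt(abund[t]) for t in model.positive_taxa if t in abund)
    neg = sum(arcsine_sqrt(abund[t]) for t in model.negative_taxa if t in abund)
    return float(pos - neg)


def fdr_adjust(p_values):
    """Benjamini-Hochberg step-up q-values."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([])
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# estimator
# ---------------------------------------------------------------------------

class RiskIndexClassifier(ClassifierMixin, BaseEstimator):
    """Discriminant-taxon risk-index classifier (samples x taxa proportions).

    ``fit`` screens taxa with the two-stage KW + bootstrap-LDA procedure,
    splits the selected taxa by enriched class into positive/negative
    sets, and picks the training-accuracy-optimal decision cutoff.
    ``decision_function`` returns the per-sample risk index.

    Fitted attributes: ``classes_``, ``model_`` (:class:`RiskModel`),
    ``support_``, ``signs_``, ``cutoff_``, ``selector_kw_p_``.
    """

    def __init__(
        self,
        kw_alpha: float = 0.05,
        lda_threshold: float = 2.0,
        n_bootstrap: int = 30,
        bootstrap_fraction: float = 2.0 / 3.0,
        scale: float = 1e6,
        random_state: int | None = None,
    ):
        self.kw_alpha = kw_alpha
        self.lda_threshold = lda_threshold
        self.n_bootstrap = n_bootstrap
        self.bootstrap_fraction = bootstrap_fraction
        self.scale = scale
        self.random_state = random_state

    def _config(self) -> DiscriminationConfig:
        return DiscriminationConfig(
            kw_alpha=self.kw_alpha,
            lda_threshold=self.lda_threshold,
            n_bootstrap=self.n_bootstrap,
            bootstrap_fraction=self.bootstrap_fraction,
            scale=self.scale,
            seed=self.random_state,
        )

    def fit(self, X, y):
        from .evaluation import optimal_cutoff

        if isinstance(X, pd.DataFrame):
            self.feature_names_in_ = np.asarray(X.columns, dtype=object)
            X = X.to_numpy(dtype=float)
        else:
            X = np.asarray(X, dtype=float)
            self.feature_names_in_ = np.asarray([str(i) for i in range(X.shape[1])], dtype=object)
        y = np.asarray(y)
        classes = np.unique(y)
        if len(classes) != 2:
            raise ValueError("exactly two classes required")
        self.classes_ = classes
        ypos = y == classes[1]
        rng = np.random.default_rng(self.random_state)
        support, enriched_pos, kw_p, _ = select_discriminant(X, ypos, self._config(), rng)
        if not support.any():
            raise ValueError("no discriminant taxa selected; cannot build a risk model")
        self.support_ = support
        self.signs_ = np.where(enriched_pos, 1.0, -1.0)
        self.selector_kw_p_ = kw_p
        names = self.feature_names_in_
        self.model_ = RiskModel(
            positive_taxa={str(names[i]) for i in np.flatnonzero(support & enriched_pos)},
            negative_taxa={str(names[i]) for i in np.flatnonzero(support & ~enriched_pos)},
            target_class=classes[1],
        )
        scores = self._decision(X)
        self.cutoff_ = optimal_cutoff(scores, ypos)
        self.n_features_in_ = X.shape[1]
        return self

    def _decision(self, X: np.ndarray) -> np.ndarray:
        T = np.arcsin(np.sqrt(np.clip(np.asarray(X, dtype=float), 0.0, 1.0)))
        return (T[:, self.support_] * self.signs_[self.support_]).sum(axis=1)

    def decision_function(self, X):
        check_is_fitted(self, "support_")
        if isinstance(X, pd.DataFrame):
            X = X.to_numpy(dtype=float)
        return self._decision(np.asarray(X, dtype=float))

    def predict(self, X):
        scores = self.decision_function(X)
        return np.where(scores >= self.cutoff_, self.classes_[1], self.classes_[0])


# ---------------------------------------------------------------------------
# leave-one-out and permutation machinery
# ---------------------------------------------------------------------------

@dataclass
class RiskIndexResult:
    """Held-out risk indices and the significance of their class difference."""

    risk_index: pd.Series
    labels: pd.Series
    observed_diff: float
    mwu_p: float
    n_taxa_used: int
    perm_p: float | None = None
    q: float | None = None
    fold_n_taxa: np.ndarray | None = None
    n_missing_folds: int = 0


def _loo_scores(
    X: np.ndarray, ypos: np.ndarray, config: DiscriminationConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Held-out risk index per sample; taxon selection re-run in every fold.

    Returns ``(scores, fold_n_taxa)``; a fold with an empty model records
    NaN for its held-out sample.
    """
    X = np.asarray(X, dtype=float)
    ypos = np.asarray(ypos, dtype=bool)
    n = len(ypos)
    T = np.arcsin(np.sqrt(np.clip(X, 0.0, 1.0)))
    scores = np.full(n, np.nan)
    n_taxa = np.zeros(n, dtype=int)
    mask = np.ones(n, dtype=bool)
    for i in range(n):
        mask[i] = False
        ytr = ypos[mask]
        if ytr.sum() < 2 or (~ytr).sum() < 2:
            mask[i] = True
            raise ValueError("both classes need >= 2 samples after removing any one sample")
        support, enriched_pos, _, _ = select_discriminant(X[mask], ytr, config, rng)
        if support.any():
            signs = np.where(enriched_pos, 1.0, -1.0)
            scores[i] = (T[i, support] * signs[support]).sum()
            n_taxa[i] = int(support.sum())
        mask[i] = True
    return scores, n_taxa


def _diff_and_mwu(scores: np.ndarray, ypos: np.ndarray) -> tuple[float, float]:
    ok = ~np.isnan(scores)
    a = scores[ok & ypos]
    b = scores[ok & ~ypos]
    if len(a) == 0 or len(b) == 0:
        return np.nan, np.nan
    diff = float(a.mean() - b.mean())
    mwu_p = float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
    return diff, mwu_p


def loo_risk_indices(
    table: AbundanceTable | pd.DataFrame,
    labels,
    config: DiscriminationConfig | None = None,
) -> RiskIndexResult:
    """Leave-one-out held-out risk indices plus Mann-Whitney significance.

    For each sample, taxa are re-selected and the risk model rebuilt on
    the other n-1 samples before the held-out sample is scored — the
    held-out sample never informs its own model.  Aborts if more than 20%
    of folds yield an empty model.
    """
    config = config or DiscriminationConfig()
    Xdf = table.to_feature_frame() if isinstance(table, AbundanceTable) else pd.DataFrame(table)
    labels = pd.Series(labels, index=Xdf.index) if not isinstance(labels, pd.Series) else labels.loc[Xdf.index]
    classes = np.unique(labels)
    if len(classes) != 2:
        raise ValueError("exactly two classes required")
    ypos = (labels.to_numpy() == classes[1])
    rng = np.random.default_rng(config.seed)
    scores, fold_n_taxa = _loo_scores(Xdf.to_numpy(dtype=float), ypos, config, rng)
    n_missing = int(np.isnan(scores).sum())
    if n_missing > 0.2 * len(scores):
        raise RuntimeError(
            f"{n_missing}/{len(scores)} leave-one-out folds produced an empty risk model; "
            "the screen finds no signal at these thresholds"
        )
    diff, mwu_p = _diff_and_mwu(scores, ypos)
    # reference model on the full data, for reporting n_taxa_used
    support, _, _, _ = select_discriminant(
        Xdf.to_numpy(dtype=float), ypos, config, np.random.default_rng(config.seed)
    )
    return RiskIndexResult(
        risk_index=pd.Series(scores, index=Xdf.index, name="risk_index"),
        labels=labels,
        observed_diff=diff,
        mwu_p=mwu_p,
        n_taxa_used=int(support.sum()),
        fold_n_taxa=fold_n_taxa,
        n_missing_folds=n_missing,
    )


def permutation_test(
    table: AbundanceTable | pd.DataFrame,
    labels,
    config: DiscriminationConfig | None = None,
    B: int = 999,
    observed: RiskIndexResult | None = None,
    fast: bool = False,
) -> tuple[float, RiskIndexResult]:
    """Empirical p for the observed mean risk-index difference.

    Labels are permuted ``B`` times; each permutation re-runs the full
    leave-one-out pipeline (taxon selection inside every fold), and the
    permuted mean differences form the null.  The +1 pseudocount makes
    the p-value valid:  p = (1 + #{|diff_perm| >= |diff_obs|}) / (B + 1).

    ``fast=True`` skips the inner LOO during permutations (selection once
    per permutation) — a smoke-test mode only, not used for inference.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    config = config or DiscriminationConfig()
    Xdf = table.to_feature_frame() if isinstance(table, AbundanceTable) else pd.DataFrame(table)
    labels = pd.Series(labels, index=Xdf.index) if not isinstance(labels, pd.Series) else labels.loc[Xdf.index]
    classes = np.unique(labels)
    ypos = (labels.to_numpy() == classes[1])
    X = Xdf.to_numpy(dtype=float)
    if observed is None:
        observed = loo_risk_indices(Xdf, labels, config)
    ss = np.random.SeedSequence(config.seed if config.seed is not None else 0)
    perm_ss, *child_ss = ss.spawn(B + 1)
    perm_rng = np.random.default_rng(perm_ss)
    T = np.arcsin(np.sqrt(np.clip(X, 0.0, 1.0)))
    null_diffs = np.full(B, np.nan)
    for b in range(B):
        yb = perm_rng.permutation(ypos)
        rng_b = np.random.default_rng(child_ss[b])
        if fast:
            support, enriched_pos, _, _ = select_discriminant(X, yb, config, rng_b)
            if not support.any():
                continue
            signs = np.where(enriched_pos, 1.0, -1.0)
            scores = (T[:, support] * signs[support]).sum(axis=1)
        else:
            scores, _ = _loo_scores(X, yb, config, rng_b)
            if np.isnan(scores).sum() > 0.2 * len(scores):
                continue  # degenerate permutation: excluded from the null
        d, _ = _diff_and_mwu(scores, yb)
        null_diffs[b] = d
    valid = ~np.isnan(null_diffs)
    n_valid = int(valid.sum())
    perm_p = float((1 + np.sum(np.abs(null_diffs[valid]) >= abs(observed.observed_diff))) / (n_valid + 1))
    observed.perm_p = perm_p
    return perm_p, observed


def apply_model(model: RiskModel, external_table: AbundanceTable) -> tuple[pd.Series, list[str]]:
    """Score an external cohort with a fixed trained model.

    Taxa are matched by canonicalized lineage string (tolerant of spaced
    vs unspaced dialects); model taxa unmatched in the external table are
    returned for reporting.  Errors if nothing matches.
    """
    if not external_table.normalized:
        raise ValueError("external table must be normalized (relative abundances)")
    canon = {canonical_lineage(t): t for t in external_table.taxon_ids}
    matched_pos = {canon[canonical_lineage(t)] for t in model.positive_taxa if canonical_lineage(t) in canon}
    matched_neg = {canon[canonical_lineage(t)] for t in model.negative_taxa if canonical_lineage(t) in canon}
    unmatched = [
        t
        for t in (model.positive_taxa | model.negative_taxa)
        if canonical_lineage(t) not in canon
    ]
    if not (matched_pos | matched_neg):
        raise ValueError("no model taxa matched the external table")
    T = external_table.data.apply(lambda col: np.arcsin(np.sqrt(np.clip(col, 0, 1))))
    pos = T.loc[sorted(matched_pos)].sum(axis=0) if matched_pos else 0.0
    neg = T.loc[sorted(matched_neg)].sum(axis=0) if matched_neg else 0.0
    out = pd.Series(pos - neg, index=external_table.sample_ids, name="risk_index")
    return out, unmatched
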