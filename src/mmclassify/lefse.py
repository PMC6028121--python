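"""Two-class discriminant-taxon screening (LEfSe-style).

Stage 1: per-taxon Kruskal-Wallis rank test at ``kw_alpha``.
Stage 2: bootstrapped one-dimensional Fisher LDA over the screened taxa;
per-taxon effect size is the mean of (a) the absolute between-class
difference of the taxon's contribution to the LDA projection and (b) the
absolute raw class-mean difference, averaged over bootstrap subsamples,
reported as log10(effect * scale + 1) on the conventional per-million
scale.  Taxa with log10 score >= ``lda_threshold`` are returned, signed
by the class with the larger raw mean.

The hot path is vectorized numpy: the Kruskal-Wallis screen runs over all
taxa at once and the LDA bootstraps are batched, because the leave-one-out
and permutation schemes upstream re-run this screen tens of thousands of
times.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted


@dataclass
class DiscriminantTaxon:
    """A taxon selected by the KW+LDA screen."""

    taxon_id: str
    enriched_class: object
    kw_p: float
    lda_log10: float


@dataclass
class DiscriminationConfig:
    """Knobs of the two-stage screen (LEfSe defaults)."""

    kw_alpha: float = 0.05
    lda_threshold: float = 2.0
    n_bootstrap: int = 30
    bootstrap_fraction: float = 2.0 / 3.0
    scale: float = 1e6  # maps proportion-scale effects onto the per-million convention
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0 < self.kw_alpha < 1:
            raise ValueError("kw_alpha must be in (0,1)")
        if self.n_bootstrap < 1:
            raise ValueError("n_bootstrap must be >= 1")


# ---------------------------------------------------------------------------
# stage 1: vectorized two-group Kruskal-Wallis
# ---------------------------------------------------------------------------

def _tie_terms(X: np.ndarray) -> np.ndarray:
    """sum(t^3 - t) over tied runs, per column, fully vectorized."""
    n = X.shape[0]
    Xs = np.sort(X, axis=0)
    new_run = np.ones_like(Xs, dtype=bool)
    new_run[1:] = Xs[1:] != Xs[:-1]
    # position within run: index minus index of run start
    idx = np.arange(n)[:, None]
    start = np.where(new_run, idx, 0)
    start = np.maximum.accumulate(start, axis=0)
    pos = idx - start + 1
    # extending a run from length j-1 to j adds 3j^2-3j to t^3-t
    return (3 * pos * (pos - 1)).sum(axis=0).astype(float)


def kruskal_wallis_2group(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Tie-corrected Kruskal-Wallis H and chi2(1) p per column of ``X``.

    Columns with all values equal get H = 0, p = 1.
    """
    y = np.asarray(y).astype(bool)
    n = len(y)
    n1 = int(y.sum())
    n0 = n - n1
    if n1 < 2 or n0 < 2:
        raise ValueError("each class needs >= 2 samples")
    ranks = stats.rankdata(X, axis=0)
    R1 = ranks[y].sum(axis=0)
    R0 = ranks[~y].sum(axis=0)
    H = 12.0 / (n * (n + 1)) * (R1**2 / n1 + R0**2 / n0) - 3 * (n + 1)
    ties = _tie_terms(np.asarray(X, dtype=float))
    denom = 1.0 - ties / (n**3 - n)
    constant = denom <= 0
    with np.errstate(divide="ignore", invalid="ignore"):
        H = np.where(constant, 0.0, H / np.where(constant, 1.0, denom))
    H = np.maximum(H, 0.0)  # guard tiny negative rounding
    p = stats.chi2.sf(H, df=1)
    p = np.where(constant, 1.0, p)
    return H, p


# ---------------------------------------------------------------------------
# stage 2: batched bootstrap LDA effect sizes
# ---------------------------------------------------------------------------

def lda_effect_sizes(
    X: np.ndarray,
    y: np.ndarray,
    n_bootstrap: int,
    bootstrap_fraction: float,
    scale: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """log10 LDA effect-size score per column of ``X`` (screened taxa only).

    Bootstraps subsample ``bootstrap_fraction`` of each class without
    replacement.  Degenerate within-class covariance is handled with a
    small relative ridge on the pooled scatter.
    """
    y = np.asarray(y).astype(bool)
    X = np.asarray(X, dtype=float)
    n, k = X.shape
    idx1 = np.flatnonzero(y)
    idx0 = np.flatnonzero(~y)
    m1 = max(2, int(np.ceil(bootstrap_fraction * len(idx1))))
    m0 = max(2, int(np.ceil(bootstrap_fraction * len(idx0))))
    m1, m0 = min(m1, len(idx1)), min(m0, len(idx0))
    B = n_bootstrap
    # subsample membership keyed to original sample positions so that the
    # draw is invariant to which class is labeled "positive"
    r = rng.random((B, n))
    take1 = np.argsort(r[:, idx1], axis=1)[:, :m1]
    take0 = np.argsort(r[:, idx0], axis=1)[:, :m0]
    X1 = X[idx1][take1]  # (B, m1, k)
    X0 = X[idx0][take0]
    mu1 = X1.mean(axis=1)
    mu0 = X0.mean(axis=1)
    d = mu1 - mu0  # (B, k)
    C1 = X1 - mu1[:, None, :]
    C0 = X0 - mu0[:, None, :]
    Sw = np.einsum("bik,bil->bkl", C1, C1) + np.einsum("bik,bil->bkl", C0, C0)
    Sw /= max(m1 + m0 - 2, 1)
    tr = np.einsum("bkk->b", Sw) / k
    lam = 1e-6 * np.maximum(tr, 0.0) + 1e-15
    Sw += lam[:, None, None] * np.eye(k)
    w = np.linalg.solve(Sw, d[..., None])[..., 0]  # (B, k)
    norms = np.linalg.norm(w, axis=1, keepdims=True)
    w = np.where(norms > 0, w / np.where(norms == 0, 1.0, norms), 0.0)
    eff = 0.5 * (np.abs(w * d) + np.abs(d))  # (B, k)
    mean_eff = eff.mean(axis=0)
    return np.log10(mean_eff * scale + 1.0)


def select_discriminant(
    X: np.ndarray,
    ypos: np.ndarray,
    config: DiscriminationConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Numpy-level two-stage screen shared by the estimator and the LOO loops.

    Returns ``(support, enriched_pos, kw_p, lda_log10)`` where
    ``enriched_pos[i]`` is True when taxon i has the larger raw mean in
    the positive class.
    """
    X = np.asarray(X, dtype=float)
    ypos = np.asarray(ypos, dtype=bool)
    _, kw_p = kruskal_wallis_2group(X, ypos)
    screened = kw_p < config.kw_alpha
    lda = np.full(X.shape[1], np.nan)
    if screened.any():
        lda[screened] = lda_effect_sizes(
            X[:, screened], ypos, config.n_bootstrap, config.bootstrap_fraction, config.scale, rng
        )
    support = screened & (np.nan_to_num(lda, nan=-np.inf) >= config.lda_threshold)
    enriched_pos = X[ypos].mean(axis=0) > X[~ypos].mean(axis=0)
    return support, enriched_pos, kw_p, lda


# ---------------------------------------------------------------------------
# estimator
# ---------------------------------------------------------------------------

class DiscriminantTaxaSelector(TransformerMixin, BaseEstimator):
    """Select taxa discriminating two classes (KW screen + bootstrap LDA).

    scikit-learn transformer over a samples x taxa matrix of relative
    abundances.  Fitted attributes:

    - ``support_`` : boolean mask of selected taxa
    - ``kw_p_`` : Kruskal-Wallis p per taxon
    - ``lda_log10_`` : log10 LDA score per taxon (NaN where not screened)
    - ``enriched_class_`` : per taxon, the class with the larger raw mean
    - ``classes_`` : the two class labels, sorted
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

    def fit(self, X, y):
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
        if ypos.sum() < 2 or (~ypos).sum() < 2:
            raise ValueError("each class needs >= 2 samples")
        config = DiscriminationConfig(
            kw_alpha=self.kw_alpha,
            lda_threshold=self.lda_threshold,
            n_bootstrap=self.n_bootstrap,
            bootstrap_fraction=self.bootstrap_fraction,
            scale=self.scale,
            seed=self.random_state,
        )
        rng = np.random.default_rng(self.random_state)
        support, enriched_pos, kw_p, lda = select_discriminant(X, ypos, config, rng)
        self.kw_p_ = kw_p
        self.lda_log10_ = lda
        self.support_ = support
        self.enriched_class_ = np.where(enriched_pos, classes[1], classes[0])
        self.n_features_in_ = X.shape[1]
        return self

    def get_support(self, indices: bool = False):
        check_is_fitted(self, "support_")
        return np.flatnonzero(self.support_) if indices else self.support_

    def transform(self, X):
        check_is_fitted(self, "support_")
        if isinstance(X, pd.DataFrame):
            return X.loc[:, self.support_]
        return np.asarray(X)[:, self.support_]

    def results_(self) -> list[DiscriminantTaxon]:
        """Selected taxa as :class:`DiscriminantTaxon` records."""
        check_is_fitted(self, "support_")
        return [
            DiscriminantTaxon(
                taxon_id=str(self.feature_names_in_[i]),
                enriched_class=self.enriched_class_[i],
                kw_p=float(self.kw_p_[i]),
                lda_log10=float(self.lda_log10_[i]),
            )
            for i in np.flatnonzero(self.support_)
        ]


# ---------------------------------------------------------------------------
# functional wrappers over the estimator
# ---------------------------------------------------------------------------

def kruskal_wallis_screen(table, labels, alpha: float = 0.05) -> set[str]:
    """Taxa of an :class:`AbundanceTable` with tie-corrected KW p < alpha."""
    X = table.to_feature_frame()
    labels = pd.Series(labels, index=X.index) if not isinstance(labels, pd.Series) else labels.loc[X.index]
    classes = np.unique(labels)
    if len(classes) != 2:
        raise ValueError("exactly two classes required")
    _, p = kruskal_wallis_2group(X.to_numpy(dtype=float), labels.to_numpy() == classes[1])
    return {t for t, pv in zip(X.columns, p) if pv < alpha}


def discriminant_taxa(table, labels, config: DiscriminationConfig | None = None) -> list[DiscriminantTaxon]:
    """Full KW -> LDA screen on an :class:`AbundanceTable`; deterministic given seed."""
    config = config or DiscriminationConfig()
    X = table.to_feature_frame()
    labels = pd.Series(labels, index=X.index) if not isinstance(labels, pd.Series) else labels.loc[X.index]
    sel = DiscriminantTaxaSelector(
        kw_alpha=config.kw_alpha,
        lda_threshold=config.lda_threshold,
        n_bootstrap=config.n_bootstrap,
        bootstrap_fraction=config.bootstrap_fraction,
        scale=config.scale,
        random_state=config.seed,
    ).fit(X, labels.to_numpy())
    return sel.results_()
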