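"""Classifier evaluation: cross-validated ROC/AUC and risk-index cutoffs.

AUC is computed with the rank (Mann-Whitney) formulation, U/(n1*n2) with
ties counted 1/2, which equals the area under the empirical ROC curve.
The 10-fold curves are averaged vertically (at a fixed false-positive-rate
grid), mirroring how per-fold ROC curves plus an average curve are
conventionally plotted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import clone
from sklearn.metrics import roc_curve
from sklearn.model_selection import KFold, StratifiedKFold


# ---------------------------------------------------------------------------
# scalar metrics
# ---------------------------------------------------------------------------

def auc(scores, labels) -> float:
    """Rank-based AUC: U/(n1*n2), ties counted 1/2."""
    scores = np.asarray(scores, dtype=float)
    ypos = np.asarray(labels).astype(bool)
    n1 = int(ypos.sum())
    n0 = int((~ypos).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be non-empty")
    ranks = stats.rankdata(scores)
    u = ranks[ypos].sum() - n1 * (n1 + 1) / 2
    return float(u / (n1 * n0))


def _cutoff_candidates(scores: np.ndarray) -> np.ndarray:
    """Midpoints between adjacent distinct scores, plus flanking cutoffs."""
    s = np.unique(scores)
    mids = (s[:-1] + s[1:]) / 2 if len(s) > 1 else np.array([])
    return np.concatenate(([s[0] - 1.0], mids, [s[-1] + 1.0]))


def optimal_cutoff(scores, labels) -> float:
    """Cutoff maximizing accuracy of ``score >= cutoff -> positive``.

    Ties in accuracy resolve to the midpoint of the first contiguous run
    of tied candidates, making the choice deterministic.  (Ties across
    non-adjacent candidate regions are not an interval: a midpoint
    spanning them could fall in a sub-optimal region between.)
    """
    scores = np.asarray(scores, dtype=float)
    ypos = np.asarray(labels).astype(bool)
    cands = _cutoff_candidates(scores)
    acc = np.array([((scores >= c) == ypos).mean() for c in cands])
    best = np.flatnonzero(acc == acc.max())
    run_end = best[0]
    while run_end + 1 in best:
        run_end += 1
    return float((cands[best[0]] + cands[run_end]) / 2)


@dataclass
class CutoffResult:
    cutoff: float
    sensitivity: float
    specificity: float
    accuracy: float
    attained: bool = True  # False when the requested specificity was unreachable


def _confusion_at(scores: np.ndarray, ypos: np.ndarray, cutoff: float) -> tuple[float, float, float]:
    pred = scores >= cutoff
    tp = (pred & ypos).sum()
    tn = (~pred & ~ypos).sum()
    sens = tp / max(ypos.sum(), 1)
    spec = tn / max((~ypos).sum(), 1)
    acc = (tp + tn) / len(ypos)
    return float(sens), float(spec), float(acc)


def accuracy_at_specificity(scores, labels, spec: float = 0.80) -> CutoffResult:
    """Smallest cutoff with specificity >= ``spec``; accuracy/sensitivity there.

    With degenerate scores the requested specificity may only be reached
    by classifying everything negative; the result is flagged via
    ``attained=False`` when even that fails (impossible for spec <= 1).
    """
    scores = np.asarray(scores, dtype=float)
    ypos = np.asarray(labels).astype(bool)
    if ypos.all() or not ypos.any():
        raise ValueError("both classes must be non-empty")
    for c in _cutoff_candidates(scores):
        sens, sp, acc = _confusion_at(scores, ypos, c)
        if sp >= spec:
            return CutoffResult(float(c), sens, sp, acc, attained=True)
    sens, sp, acc = _confusion_at(scores, ypos, np.inf)  # pragma: no cover
    return CutoffResult(np.inf, sens, sp, acc, attained=False)


# ---------------------------------------------------------------------------
# cross-validated ROC
# ---------------------------------------------------------------------------

@dataclass
class ROCResult:
    fold_curves: list  # (fpr, tpr) per fold
    mean_fpr: np.ndarray
    mean_tpr: np.ndarray
    auc: float
    fold_assignments: np.ndarray
    fold_aucs: list = field(default_factory=list)


def kfold_roc(table, labels, k: int = 10, config=None, random_state: int | None = None, pooled: bool = False) -> ROCResult:
    """Stratified k-fold ROC with per-fold retraining of the risk model.

    Each fold's model (taxon screen + risk model) is trained on the other
    k-1 folds and scores its held-out samples; per-fold ROC curves use
    fold-local scores (``pooled=True`` instead pools all held-out scores
    into a single curve repeated per fold).  The mean curve averages
    fold TPRs on a fixed FPR grid; ``auc`` is its trapezoidal area.
    ``k = n`` degenerates to leave-one-out (unstratified, pooled scores).
    """
    from .abundance import AbundanceTable
    from .lefse import DiscriminationConfig
    from .risk import RiskIndexClassifier

    config = config or DiscriminationConfig()
    Xdf = table.to_feature_frame() if isinstance(table, AbundanceTable) else pd.DataFrame(table)
    labels = pd.Series(labels, index=Xdf.index) if not isinstance(labels, pd.Series) else labels.loc[Xdf.index]
    y = labels.to_numpy()
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError("exactly two classes required")
    ypos = y == classes[1]
    X = Xdf.to_numpy(dtype=float)
    n = len(y)

    loo = k >= n
    if loo:
        splitter = KFold(n_splits=n)
        splits = splitter.split(X)
    else:
        if min(ypos.sum(), (~ypos).sum()) < k:
            raise ValueError(f"cannot stratify {k} folds: smallest class has {min(ypos.sum(), (~ypos).sum())} samples")
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=random_state)
        splits = splitter.split(X, ypos)

    clf = RiskIndexClassifier(
        kw_alpha=config.kw_alpha,
        lda_threshold=config.lda_threshold,
        n_bootstrap=config.n_bootstrap,
        bootstrap_fraction=config.bootstrap_fraction,
        scale=config.scale,
        random_state=config.seed,
    )
    assignments = np.full(n, -1)
    held_scores = np.full(n, np.nan)
    fold_tests: list[np.ndarray] = []
    for f, (train, test) in enumerate(splits):
        assignments[test] = f
        est = clone(clf).fit(X[train], ypos[train])
        held_scores[test] = est.decision_function(X[test])
        fold_tests.append(test)

    grid = np.linspace(0.0, 1.0, 101)
    curves, tprs, fold_aucs = [], [], []
    for test in fold_tests:
        idx = np.arange(n) if (pooled or loo) else test
        yt, st = ypos[idx], held_scores[idx]
        if len(np.unique(yt)) < 2:
            continue
        fpr, tpr, _ = roc_curve(yt, st)
        curves.append((fpr, tpr))
        # the empirical ROC is a right-continuous step function; evaluate it
        # on the grid directly (linear interpolation would inflate tiny folds)
        ufpr, inverse = np.unique(fpr, return_inverse=True)
        utpr = np.zeros_like(ufpr)
        np.maximum.at(utpr, inverse, tpr)
        tprs.append(utpr[np.searchsorted(ufpr, grid, side="right") - 1])
        fold_aucs.append(auc(st, yt))
        if loo:
            break  # one pooled curve describes LOO
    if not curves:
        raise ValueError("no fold contained both classes; re-stratification impossible")
    mean_tpr = np.mean(tprs, axis=0)
    mean_tpr[-1] = 1.0
    return ROCResult(
        fold_curves=curves,
        mean_fpr=grid,
        mean_tpr=mean_tpr,
        auc=float(np.trapezoid(mean_tpr, grid)),
        fold_assignments=assignments,
        fold_aucs=fold_aucs,
    )


def loo_optimal_cutoff(scores, labels) -> CutoffResult:
    """Held-out performance of the accuracy-optimal cutoff, refined per sample.

    Each sample is treated as a new patient: the optimal cutoff is chosen
    on the other samples' (held-out) risk indices, the new sample is
    classified, and the cutoff refined for the next.  Reports aggregate
    held-out sensitivity/specificity/accuracy plus the final full-data
    cutoff.
    """
    scores = np.asarray(scores, dtype=float)
    ypos = np.asarray(labels).astype(bool)
    ok = ~np.isnan(scores)
    scores, ypos = scores[ok], ypos[ok]
    n = len(scores)
    pred = np.zeros(n, dtype=bool)
    mask = np.ones(n, dtype=bool)
    for i in range(n):
        mask[i] = False
        c = optimal_cutoff(scores[mask], ypos[mask])
        pred[i] = scores[i] >= c
        mask[i] = True
    tp = (pred & ypos).sum()
    tn = (~pred & ~ypos).sum()
    return CutoffResult(
        cutoff=optimal_cutoff(scores, ypos),
        sensitivity=float(tp / max(ypos.sum(), 1)),
        specificity=float(tn / max((~ypos).sum(), 1)),
        accuracy=float((tp + tn) / n),
    )
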