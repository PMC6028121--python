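"""Covariate-adjusted per-taxon linear models (robustness check).

A deliberately simple analogue of multivariate association testing:
after prevalence and abundance filtering, each taxon's arcsine-root
relative abundance is regressed on mutation status plus age and sex by
ordinary least squares, with a two-sided t-test on the status coefficient
and Benjamini-Hochberg correction across taxa.  No boosting-based feature
selection is performed; this module is a robustness analogue of such
tools, not a clone.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.base import BaseEstimator

from .abundance import AbundanceTable
from .risk import arcsine_sqrt, fdr_adjust


@dataclass
class LmResult:
    taxon: str
    coefficient: float
    p: float
    q: float
    n_samples_used: int


def maaslin_filter(table: AbundanceTable, min_prevalence: int = 5, min_abundance: float = 0.001) -> AbundanceTable:
    """Keep taxa present (>0) in >= ``min_prevalence`` samples with mean
    relative abundance >= ``min_abundance``.  Idempotent."""
    if table.data.to_numpy().max(initial=0.0) > 1 + 1e-9:
        raise ValueError("maaslin_filter expects relative abundances")
    present = (table.data > 0).sum(axis=1)
    mean_ab = table.data.mean(axis=1)
    keep = table.data.index[(present >= min_prevalence) & (mean_ab >= min_abundance)]
    return AbundanceTable(table.data.loc[keep], normalized=False, rank=table.rank)


def _design(status: np.ndarray, covariates: pd.DataFrame | None) -> pd.DataFrame:
    X = pd.DataFrame({"status": status.astype(float)})
    if covariates is not None:
        cov = covariates.reset_index(drop=True)
        if "age" in cov.columns:
            X["age"] = pd.to_numeric(cov["age"], errors="coerce")
        if "sex" in cov.columns:
            X["sex_M"] = (cov["sex"].astype(str).str.upper() == "M").astype(float)
            X.loc[cov["sex"].isna(), "sex_M"] = np.nan
    return sm.add_constant(X)


def fit_per_taxon_lm(
    table: AbundanceTable,
    feature_labels,
    covariates: pd.DataFrame | None = None,
    transform=arcsine_sqrt,
) -> list[LmResult]:
    """OLS of transformed abundance on mutation status (+ age, sex) per taxon.

    Rows with missing covariates are dropped per taxon (count reported in
    ``n_samples_used``).  Constant-abundance taxa get coefficient 0 and
    p = 1 by convention; rank-deficient designs are skipped.
    """
    labels = pd.Series(feature_labels)
    samples = [s for s in table.sample_ids if s in labels.index]
    sub = table.data[samples]
    status = labels.loc[samples].to_numpy()
    cov = covariates.loc[samples] if covariates is not None else None
    design = _design(status, cov)
    results = []
    for taxon in sub.index:
        yvals = transform(sub.loc[taxon].to_numpy())
        frame = design.copy()
        frame["y"] = yvals
        frame = frame.dropna()
        n_used = len(frame)
        if np.ptp(yvals) == 0:
            results.append(LmResult(taxon, 0.0, 1.0, np.nan, n_used))
            continue
        exog = frame.drop(columns="y")
        if np.linalg.matrix_rank(exog.to_numpy()) < exog.shape[1]:
            continue  # rank-deficient design; diagnostic via absence
        fit = sm.OLS(frame["y"], exog).fit()
        results.append(LmResult(taxon, float(fit.params["status"]), float(fit.pvalues["status"]), np.nan, n_used))
    ps = [r.p for r in results]
    qs = fdr_adjust(ps)
    for r, q in zip(results, qs):
        r.q = float(q)
    return results


class PerTaxonLinearModel(BaseEstimator):
    """Estimator facade over :func:`fit_per_taxon_lm`.

    ``fit(X, y)`` takes samples x taxa relative abundances (DataFrame)
    and binary status; fitted attribute ``results_`` is the per-taxon
    coefficient/p/q table.
    """

    def __init__(self, min_prevalence: int = 5, min_abundance: float = 0.001):
        self.min_prevalence = min_prevalence
        self.min_abundance = min_abundance

    def fit(self, X, y, covariates: pd.DataFrame | None = None):
        X = pd.DataFrame(X)
        table = AbundanceTable(X.T, normalized=True)  # caller provides proportions
        filtered = maaslin_filter(table, self.min_prevalence, self.min_abundance)
        labels = pd.Series(np.asarray(y), index=X.index)
        self.results_ = fit_per_taxon_lm(filtered, labels, covariates)
        self.n_features_in_ = X.shape[1]
        return self

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(r.taxon, r.coefficient, r.p, r.q, r.n_samples_used) for r in self.results_],
            columns=["taxon", "coefficient", "p", "q", "n_samples_used"],
        ).set_index("taxon")


def concordance(ri_summary: pd.DataFrame, lm_summary: pd.DataFrame, alpha: float = 0.05) -> tuple[int, int, float]:
    """Of the features significant under the risk-index pipeline, how many
    are also significant under the linear-model check.

    Both summaries must cover the same feature list and carry a ``q``
    column.  Returns (k, n, k/n); n counts risk-index-significant
    features.
    """
    if set(ri_summary.index) != set(lm_summary.index):
        raise ValueError("feature lists differ between summaries")
    ri_sig = ri_summary["q"] <= alpha
    lm_sig = lm_summary["q"].loc[ri_summary.index] <= alpha
    n = int(ri_sig.sum())
    k = int((ri_sig & lm_sig).sum())
    return k, n, (k / n if n else np.nan)
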