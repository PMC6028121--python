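"""Compositional correlation inference (SparCC) and mutation-conditioned networks.

Relative-abundance data are compositional: closure to a constant sum
induces spurious negative correlation between taxa.  SparCC estimates
correlations between the unobserved *basis* abundances from log-ratio
variances t_ij = Var[log(x_i/x_j)].  Under the approximation that the
average correlation is small, the basis variances w_i solve the linear
system

    (ones + diag(D-2)) w = rowsums(T),

and r_ij = (w_i + w_j - t_ij) / (2 sqrt(w_i w_j)), clipped to [-1, 1].
Strongly correlated pairs violate the approximation, so the pair with the
largest |r| above an exclusion threshold is iteratively removed from the
system and the variances re-solved.  Counts are resampled from a
Dirichlet posterior (counts + 1 prior) to propagate sampling noise; the
reported matrix is the element-wise median over resamples.  Significance
uses shuffle-based pseudo p-values: each taxon's counts are permuted
independently across samples, destroying correlation while preserving
marginals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .abundance import AbundanceTable

logger = logging.getLogger(__name__)


@dataclass
class SparccConfig:
    n_dirichlet_resamples: int = 20
    n_exclusion_iterations: int = 10
    exclusion_threshold: float = 0.1
    n_shuffles: int = 100
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0 < self.exclusion_threshold < 1:
            raise ValueError("exclusion_threshold must be in (0,1)")
        if self.n_shuffles < 1:
            raise ValueError("n_shuffles must be >= 1")


def _basis_correlations(fracs: np.ndarray, config: SparccConfig) -> np.ndarray:
    """One SparCC estimate from a single fraction matrix (samples x taxa)."""
    D = fracs.shape[1]
    logf = np.log(fracs)
    cov = np.cov(logf, rowvar=False)
    v = np.diag(cov).copy()
    t = v[:, None] + v[None, :] - 2 * cov  # t_ij = Var[log(x_i/x_j)]
    np.fill_diagonal(t, 0.0)

    M = np.ones((D, D)) + np.diag(np.full(D, D - 2.0))
    t_rowsums = t.sum(axis=1)
    excluded = np.zeros((D, D), dtype=bool)

    def solve():
        w = np.linalg.solve(M, t_rowsums)
        if np.any(w <= 0):
            logger.warning("negative basis variance clipped")
            w = np.maximum(w, 1e-12)
        denom = 2 * np.sqrt(np.outer(w, w))
        r = (w[:, None] + w[None, :] - t) / denom
        r = np.clip(r, -1.0, 1.0)
        np.fill_diagonal(r, 1.0)
        return r

    r = solve()
    for _ in range(config.n_exclusion_iterations):
        absr = np.abs(r.copy())
        absr[np.triu_indices(D)] = 0.0
        absr[excluded] = 0.0
        i, j = np.unravel_index(np.argmax(absr), absr.shape)
        if absr[i, j] <= config.exclusion_threshold:
            break
        excluded[i, j] = excluded[j, i] = True
        M[i, i] -= 1
        M[j, j] -= 1
        M[i, j] = M[j, i] = 0.0
        t_rowsums[i] -= t[i, j]
        t_rowsums[j] -= t[i, j]
        try:
            r = solve()
        except np.linalg.LinAlgError:  # over-excluded system; keep last estimate
            break
    return r


def _dirichlet_fractions(counts: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Posterior fractions per sample, Dirichlet(counts + 1)."""
    g = rng.standard_gamma(counts + 1.0)
    return g / g.sum(axis=1, keepdims=True)


def sparcc_correlations(counts, config: SparccConfig | None = None, rng: np.random.Generator | None = None) -> np.ndarray:
    """Median SparCC correlation matrix over Dirichlet resamples.

    ``counts`` is samples x taxa (or an :class:`AbundanceTable` in counts
    mode).  At least 4 taxa and 4 samples are required — the basis-variance
    system is underdetermined below that.
    """
    config = config or SparccConfig()
    if isinstance(counts, AbundanceTable):
        counts = counts.to_feature_frame()
    counts = np.asarray(counts, dtype=float)
    n, D = counts.shape
    if D < 4:
        raise ValueError(f"SparCC needs >= 4 taxa for an identifiable basis-variance system (got {D})")
    if n < 4:
        raise ValueError(f"SparCC needs >= 4 samples (got {n})")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    estimates = np.empty((config.n_dirichlet_resamples, D, D))
    for b in range(config.n_dirichlet_resamples):
        fracs = _dirichlet_fractions(counts, rng)
        estimates[b] = _basis_correlations(fracs, config)
    r = np.median(estimates, axis=0)
    r = np.clip((r + r.T) / 2, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return r


def pseudo_pvalues(counts, observed_r: np.ndarray, config: SparccConfig | None = None) -> np.ndarray:
    """Two-sided shuffle pseudo p-values for a SparCC correlation matrix.

    p_ij = (1 + #{|r_shuffled| >= |r_observed|}) / (n_shuffles + 1).
    """
    config = config or SparccConfig()
    if isinstance(counts, AbundanceTable):
        counts = counts.to_feature_frame()
    counts = np.asarray(counts, dtype=float)
    n, D = counts.shape
    rng = np.random.default_rng(config.seed)
    exceed = np.zeros((D, D))
    for _ in range(config.n_shuffles):
        shuffled = np.empty_like(counts)
        for j in range(D):  # each taxon permuted independently across samples
            shuffled[:, j] = counts[rng.permutation(n), j]
        r_null = sparcc_correlations(shuffled, config, rng=rng)
        exceed += np.abs(r_null) >= np.abs(observed_r)
    p = (1.0 + exceed) / (config.n_shuffles + 1.0)
    np.fill_diagonal(p, 0.0)
    return p


class SparCC(BaseEstimator):
    """Estimator wrapper: fit on a samples x taxa count matrix.

    Fitted attributes: ``correlation_`` (D x D), and after
    :meth:`compute_pvalues`, ``pvalues_``.
    """

    def __init__(
        self,
        n_dirichlet_resamples: int = 20,
        n_exclusion_iterations: int = 10,
        exclusion_threshold: float = 0.1,
        n_shuffles: int = 100,
        random_state: int | None = None,
    ):
        self.n_dirichlet_resamples = n_dirichlet_resamples
        self.n_exclusion_iterations = n_exclusion_iterations
        self.exclusion_threshold = exclusion_threshold
        self.n_shuffles = n_shuffles
        self.random_state = random_state

    def _config(self) -> SparccConfig:
        return SparccConfig(
            n_dirichlet_resamples=self.n_dirichlet_resamples,
            n_exclusion_iterations=self.n_exclusion_iterations,
            exclusion_threshold=self.exclusion_threshold,
            n_shuffles=self.n_shuffles,
            seed=self.random_state,
        )

    def fit(self, X, y=None):
        if isinstance(X, pd.DataFrame):
            self.feature_names_in_ = np.asarray(X.columns, dtype=object)
            X = X.to_numpy(dtype=float)
        else:
            X = np.asarray(X, dtype=float)
            self.feature_names_in_ = np.asarray([str(i) for i in range(X.shape[1])], dtype=object)
        self._counts = X
        self.correlation_ = sparcc_correlations(X, self._config())
        self.n_features_in_ = X.shape[1]
        return self

    def compute_pvalues(self) -> np.ndarray:
        check_is_fitted(self, "correlation_")
        self.pvalues_ = pseudo_pvalues(self._counts, self.correlation_, self._config())
        return self.pvalues_


# ---------------------------------------------------------------------------
# networks
# ---------------------------------------------------------------------------

def build_network(
    r: np.ndarray,
    p: np.ndarray,
    nodes,
    node_abundance=None,
    r_min: float = 0.25,
    p_max: float = 0.05,
    stratum: str = "pooled",
    exclude: set | None = None,
) -> nx.Graph:
    """Edge-filtered correlation network: keep |r| >= r_min and p <= p_max.

    ``exclude`` drops listed taxa up front (e.g. families prone to
    miscalls).  Node attribute ``mean_abundance`` carries the stratum
    mean relative abundance; edges carry r, pseudo_p, and sign.
    """
    nodes = list(nodes)
    r = np.asarray(r)
    p = np.asarray(p)
    if r.shape != p.shape or r.shape[0] != len(nodes):
        raise ValueError("correlation/p matrices must align with the node list")
    exclude = exclude or set()
    keep = [i for i, t in enumerate(nodes) if t not in exclude]
    g = nx.Graph(stratum=stratum)
    for i in keep:
        attrs = {}
        if node_abundance is not None:
            attrs["mean_abundance"] = float(np.asarray(node_abundance)[i])
        g.add_node(nodes[i], **attrs)
    for ii, i in enumerate(keep):
        for j in keep[ii + 1:]:
            if abs(r[i, j]) >= r_min and p[i, j] <= p_max:
                g.add_edge(
                    nodes[i],
                    nodes[j],
                    r=float(r[i, j]),
                    pseudo_p=float(p[i, j]),
                    sign="direct" if r[i, j] > 0 else "inverse",
                )
    return g


def differential_networks(
    counts: AbundanceTable,
    feature_labels,
    taxa,
    config: SparccConfig | None = None,
    r_min: float = 0.25,
    p_max: float = 0.05,
    feature_name: str = "feature",
) -> tuple[nx.Graph, nx.Graph, set]:
    """Independent SparCC networks for mutated vs wildtype strata.

    ``taxa`` is the discriminant set for the feature (the reduced table);
    both strata need >= 4 samples.  Returns (mutated network, wildtype
    network, symmetric difference of their edge sets).
    """
    config = config or SparccConfig()
    labels = pd.Series(feature_labels)
    reduced = counts.select_taxa(taxa)
    nets = {}
    for name, mask in (("mutated", labels == 1), ("wildtype", labels == 0)):
        samples = labels.index[mask]
        if len(samples) < 4:
            raise ValueError(f"stratum {name!r} for {feature_name} has {len(samples)} samples; >= 4 required")
        sub = reduced.select_samples(samples)
        counts_st = sub.to_feature_frame().to_numpy(dtype=float)
        r = sparcc_correlations(counts_st, config)
        p = pseudo_pvalues(counts_st, r, config)
        totals = sub.data.sum(axis=0).to_numpy()
        mean_ab = (sub.data.to_numpy() / totals).mean(axis=1)
        nets[name] = build_network(
            r, p, sub.taxon_ids, node_abundance=mean_ab, r_min=r_min, p_max=p_max,
            stratum=f"{feature_name}:{name}",
        )
    e_mut = {frozenset(e) for e in nets["mutated"].edges}
    e_wt = {frozenset(e) for e in nets["wildtype"].edges}
    return nets["mutated"], nets["wildtype"], e_mut ^ e_wt
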