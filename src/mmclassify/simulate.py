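"""Synthetic data with the statistical structure the analysis assumes.

The generator emulates a genus-level tumor microbiome survey jointly
with binary mutation features:

- a sparse compositional base drawn once from a log-normal (a few taxa
  dominate, a long tail is rare), shared across samples;
- per-feature binary mutation labels at controlled prevalence;
- planted taxon-label associations as *multiplicative* shifts of chosen
  taxa in labeled samples, applied before renormalization so that
  boosting one taxon depresses the rest (compositional realism);
- counts drawn Dirichlet-multinomial around each sample's expected
  composition, emulating 16S overdispersion, at Poisson-distributed
  sequencing depth.

Defaults mirror the study conditions: 44 tumor samples, 300 genus-level
taxa, ~120,000 reads per sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .abundance import AbundanceTable, RANK_PREFIXES
from .mutations import MutationMatrix


@dataclass
class SyntheticConfig:
    n_samples: int = 44
    n_taxa: int = 300
    depth: float = 120_000.0  # mean reads per sample
    base_logmean_sd: float = 2.5  # log-normal spread of the base composition
    planted: list[tuple[int, float, int]] = field(default_factory=list)  # (taxon index, fold, direction +-1)
    label_prevalence: float = 0.5
    n_features: int = 1
    overdispersion: float = 500.0  # total Dirichlet concentration; larger = closer to multinomial
    overlap: float | None = None  # optional Jaccard overlap between feature columns
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if not 0 < self.label_prevalence < 1:
            raise ValueError("label_prevalence must be in (0,1)")
        for idx, fold, _ in self.planted:
            if fold <= 0:
                raise ValueError("fold_change must be > 0")
            if not 0 <= idx < self.n_taxa:
                raise ValueError(f"planted taxon index {idx} out of range")
        if self.n_features < 1:
            raise ValueError("n_features must be >= 1")


@dataclass
class SyntheticDataset:
    abundance: AbundanceTable  # counts
    labels: MutationMatrix
    truth: dict  # feature -> list of (taxon id, fold, direction)
    pathway_map: dict[str, set[str]]
    metadata: pd.DataFrame | None = None


def _taxon_ids(n_taxa: int) -> list[str]:
    pad = len(str(n_taxa))
    return [
        ";".join(f"{p}__sim{str(i).zfill(pad)}" for p in RANK_PREFIXES[:6])
        for i in range(n_taxa)
    ]


def simulate_base_composition(config: SyntheticConfig, rng: np.random.Generator) -> np.ndarray:
    """Sparse log-normal base proportions, drawn once and normalized."""
    base = rng.lognormal(mean=0.0, sigma=config.base_logmean_sd, size=config.n_taxa)
    return base / base.sum()


def simulate_composition(config: SyntheticConfig, labels: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Expected per-sample proportions (samples x taxa).

    Positive-label samples have each planted taxon multiplied by its fold
    change (direction -1 divides) before renormalization.
    """
    base = simulate_base_composition(config, rng)
    expected = np.tile(base, (config.n_samples, 1))
    pos = np.asarray(labels, dtype=bool)
    for idx, fold, direction in config.planted:
        factor = fold if direction >= 0 else 1.0 / fold
        expected[pos, idx] *= factor
    expected /= expected.sum(axis=1, keepdims=True)
    return expected


def simulate_counts(expected: np.ndarray, config: SyntheticConfig, rng: np.random.Generator) -> np.ndarray:
    """Dirichlet-multinomial counts at Poisson depth around ``config.depth``.

    The Dirichlet concentration vector is ``overdispersion * expected``,
    so ``overdispersion`` is the total concentration: small values give
    the heavy between-sample compositional noise typical of 16S data,
    and the multinomial limit is recovered as it grows.
    """
    n, k = expected.shape
    depths = rng.poisson(config.depth, size=n)
    depths = np.maximum(depths, 1)
    counts = np.empty((n, k), dtype=np.int64)
    for i in range(n):
        g = rng.standard_gamma(config.overdispersion * expected[i])
        total = g.sum()
        p = g / total if total > 0 else expected[i]
        counts[i] = rng.multinomial(depths[i], p)
    return counts


def simulate_mutations(config: SyntheticConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Binary feature x sample labels, each feature Bernoulli(prevalence).

    Features resample (up to 100 tries) until both classes are non-empty.
    With ``overlap`` set, later features are constrained toward the
    requested Jaccard overlap with the first feature (1.0 duplicates it;
    0.0 forces disjoint mutated sets, infeasible at high prevalence).
    """
    n = config.n_samples
    features = {}
    first = None
    for f in range(config.n_features):
        name = f"feature{f:02d}"
        if config.overlap is not None and first is not None and config.overlap >= 1.0:
            features[name] = first.copy()
            continue
        if config.overlap is not None and first is not None and config.overlap <= 0.0:
            pool = np.flatnonzero(~first.astype(bool))
            m = int(round(config.label_prevalence * n))
            if m > len(pool):
                raise ValueError("disjoint features infeasible at this prevalence")
            col = np.zeros(n, dtype=int)
            col[rng.choice(pool, size=m, replace=False)] = 1
            features[name] = col
            continue
        for _ in range(100):
            col = (rng.random(n) < config.label_prevalence).astype(int)
            if 0 < col.sum() < n:
                break
        else:
            raise ValueError(f"could not draw non-degenerate labels for {name}")
        features[name] = col
        if first is None:
            first = col
    samples = [f"S{str(i).zfill(len(str(n)))}" for i in range(n)]
    return pd.DataFrame(features, index=samples).T


def toy_pathway_map(feature_names, genes_per_pathway: int = 3) -> dict[str, set[str]]:
    """Assign synthetic genes to synthetic pathways (for pipeline plumbing)."""
    out = {}
    for i, f in enumerate(feature_names):
        out[f"pathway_{i:02d}"] = {f} | {f"{f}_partner{j}" for j in range(genes_per_pathway - 1)}
    return out


def _streams(seed: int | None, n: int = 4) -> list[np.random.Generator]:
    """Independent child generators so each stage has its own stream."""
    ss = np.random.SeedSequence(seed if seed is not None else 0)
    return [np.random.default_rng(c) for c in ss.spawn(n)]


def planted_indices_by_rank(config: SyntheticConfig, ranks) -> list[int]:
    """Taxon indices at the given base-abundance ranks (0 = most abundant).

    Reproduces the base-composition draw of :func:`generate_dataset` for
    the same seed, letting callers plant effects in taxa of known
    abundance tier before generating the dataset.
    """
    _, rng_base, _, _ = _streams(config.seed)
    base = simulate_base_composition(config, rng_base)
    order = np.argsort(base)[::-1]
    return [int(order[r]) for r in ranks]


def generate_dataset(config: SyntheticConfig | None = None) -> SyntheticDataset:
    """composition -> counts -> labels -> toy pathway map, fully seeded.

    The planted shifts are tied to the *first* feature's labels; the
    ``truth`` ledger records them for recovery tests.  Each stage draws
    from its own child stream of the seed, so e.g. the base composition
    is the same whether or not extra mutation features are requested.
    """
    config = config or SyntheticConfig()
    rng_labels, rng_base, rng_comp, rng_counts = _streams(config.seed)
    label_df = simulate_mutations(config, rng_labels)
    first_labels = label_df.iloc[0].to_numpy()
    base = simulate_base_composition(config, rng_base)
    expected = np.tile(base, (config.n_samples, 1))
    pos = first_labels.astype(bool)
    for idx, fold, direction in config.planted:
        factor = fold if direction >= 0 else 1.0 / fold
        expected[pos, idx] *= factor
    expected /= expected.sum(axis=1, keepdims=True)
    counts = simulate_counts(expected, config, rng_counts)
    rng = rng_comp  # metadata draws
    taxa = _taxon_ids(config.n_taxa)
    table = AbundanceTable(
        pd.DataFrame(counts.T, index=taxa, columns=label_df.columns), normalized=False, rank="genus"
    )
    truth = {
        label_df.index[0]: [(taxa[idx], fold, direction) for idx, fold, direction in config.planted]
    }
    meta = pd.DataFrame(
        {
            "patient_id": [f"P{i}" for i in range(config.n_samples)],
            "tissue": "tumor",
            "stage": pd.array(
                rng.choice([1, 2, 3, 4], size=config.n_samples), dtype="Int64"
            ),
            "age": rng.normal(65, 10, size=config.n_samples).round(1),
            "sex": rng.choice(["M", "F"], size=config.n_samples),
        },
        index=label_df.columns,
    )
    return SyntheticDataset(
        abundance=table,
        labels=MutationMatrix(label_df, feature_kind="gene", effect_scope="lof"),
        truth=truth,
        pathway_map=toy_pathway_map(label_df.index),
        metadata=meta,
    )
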