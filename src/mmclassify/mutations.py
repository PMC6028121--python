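"""Binary gene- and pathway-level loss-of-function mutation profiles.

Somatic mutation calls are classified by predicted effect, binarized per
gene and sample, optionally collapsed onto curated pathways (KEGG / PID;
a pathway is "mutated" when any member gene carries a qualifying
mutation), prevalence-filtered, and checked for confounding with tumor
stage by Fisher's exact test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

# SnpEff-style annotation vocabulary, matched case-insensitively.  A
# loss-of-function call is a premature stop, a lost stop, or a frameshift.
DEFAULT_EFFECT_ALIASES: dict[str, tuple[str, ...]] = {
    "lof": (
        "stop_gained",
        "stop gained",
        "stop_lost",
        "stop lost",
        "frameshift_variant",
        "frameshift",
        "start_lost",
    ),
    "synonymous": (
        "synonymous_variant",
        "synonymous",
        "silent",
        "stop_retained_variant",
    ),
    "missense": (
        "missense_variant",
        "missense",
        "nonsynonymous snv",
        "non_synonymous_codon",
    ),
}

_SEVERITY = ("lof", "missense", "synonymous")  # most to least severe

EFFECT_SCOPES = {
    "total": ("synonymous", "missense", "lof", "other"),
    "nonsynonymous": ("missense", "lof"),
    "missense": ("missense",),
    "lof": ("lof",),
}


def classify_effect(raw_effect: str, aliases: dict | None = None) -> str:
    """Map a raw annotation string to {lof, missense, synonymous, other}.

    Composite SnpEff annotations joined by '&' are resolved to the most
    severe component.  Unknown strings become ``other``.
    """
    table = aliases or DEFAULT_EFFECT_ALIASES
    parts = [p.strip().lower() for p in str(raw_effect).split("&")]
    found = set()
    for cls, names in table.items():
        lowered = tuple(n.lower() for n in names)
        if any(p in lowered for p in parts):
            found.add(cls)
    for cls in _SEVERITY:
        if cls in found:
            return cls
    return "other"


@dataclass
class MutationMatrix:
    """Binary feature (gene or pathway) x sample indicator matrix."""

    data: pd.DataFrame  # features x samples, values in {0, 1}
    feature_kind: str = "gene"  # gene | kegg_pathway | pid_pathway
    effect_scope: str = "lof"

    def __post_init__(self) -> None:
        vals = self.data.to_numpy()
        if vals.size and not np.isin(vals, (0, 1)).all():
            raise ValueError("mutation matrix values must be binary")
        self.data = self.data.astype(int)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    def prevalence(self) -> pd.Series:
        """Number of mutated samples per feature."""
        return self.data.sum(axis=1)


def build_matrix(records, samples, effect_scope: str = "lof") -> MutationMatrix:
    """Binarize mutation records into a gene x sample indicator matrix.

    An entry is 1 iff the sample carries at least one record of a
    qualifying effect class in that gene (duplicates are idempotent).
    """
    if effect_scope not in EFFECT_SCOPES:
        raise ValueError(f"effect_scope must be one of {sorted(EFFECT_SCOPES)}")
    qualifying = EFFECT_SCOPES[effect_scope]
    samples = list(samples)
    hits = [(r.gene_symbol, r.sample_id) for r in records if r.effect_class in qualifying and r.sample_id in samples]
    if not records:
        logger.warning("empty record list: all-zero mutation matrix")
    genes = sorted({g for g, _ in hits})
    data = pd.DataFrame(0, index=genes, columns=samples, dtype=int)
    for g, s in hits:
        data.loc[g, s] = 1
    return MutationMatrix(data, feature_kind="gene", effect_scope=effect_scope)


def gene_id_map(records) -> dict[str, set[str]]:
    """Gene symbol -> known identifiers (symbol plus ENSEMBL id if any)."""
    out: dict[str, set[str]] = {}
    for r in records:
        ids = out.setdefault(r.gene_symbol, {r.gene_symbol})
        if r.ensembl_gene_id:
            ids.add(r.ensembl_gene_id)
    return out


def collapse_to_pathways(
    m: MutationMatrix,
    pathway_map: dict[str, set[str]],
    feature_kind: str = "kegg_pathway",
    gene_ids: dict[str, set[str]] | None = None,
) -> MutationMatrix:
    """OR gene indicators over pathway memberships.

    Pathway membership is matched on ENSEMBL ids when ``gene_ids``
    provides them, falling back to gene symbols; mapping misses are
    logged, never fatal.  Pathways with no member gene present in ``m``
    are dropped.
    """
    if m.feature_kind != "gene":
        raise ValueError("collapse_to_pathways requires a gene-level matrix")
    ids = gene_ids or {}
    rows = {}
    for pathway, members in pathway_map.items():
        member_genes = [
            g for g in m.feature_ids if g in members or (ids.get(g, set()) & members)
        ]
        if not member_genes:
            logger.info("pathway %s has no member gene in the matrix; dropped", pathway)
            continue
        rows[pathway] = (m.data.loc[member_genes].sum(axis=0) > 0).astype(int)
    data = pd.DataFrame(rows).T if rows else pd.DataFrame(columns=m.sample_ids, dtype=int)
    data = data.reindex(columns=m.sample_ids, fill_value=0)
    return MutationMatrix(data, feature_kind=feature_kind, effect_scope=m.effect_scope)


@dataclass
class PrevalenceReport:
    min_patients: int
    n_kept: int
    n_dropped: int
    kept: list[str] = field(default_factory=list)
    dropped: list[str] = field(default_factory=list)


def prevalence_filter(m: MutationMatrix, min_patients: int) -> tuple[MutationMatrix, PrevalenceReport]:
    """Keep features mutated in at least ``min_patients`` samples."""
    if min_patients < 1:
        raise ValueError("min_patients must be >= 1")
    prev = m.prevalence()
    kept = prev[prev >= min_patients].index.tolist()
    dropped = prev[prev < min_patients].index.tolist()
    out = MutationMatrix(m.data.loc[kept], feature_kind=m.feature_kind, effect_scope=m.effect_scope)
    return out, PrevalenceReport(min_patients, len(kept), len(dropped), kept, dropped)


def stage_groups(metadata: pd.DataFrame) -> pd.Series:
    """Collapse TNM stage to low (1-2) / high (3-4); missing stays missing."""
    if "stage" not in metadata.columns:
        raise ValueError("metadata has no 'stage' column")
    stage = metadata["stage"]
    out = pd.Series(pd.NA, index=metadata.index, dtype="object")
    out[stage.isin([1, 2])] = "low"
    out[stage.isin([3, 4])] = "high"
    return out


def confounding_test(m: MutationMatrix, groups: pd.Series) -> pd.DataFrame:
    """Fisher's exact test of each feature's mutation status against stage group.

    Stage-missing samples are excluded.  Returns per-feature odds ratio,
    two-sided p, and Benjamini-Hochberg q.
    """
    common = [s for s in m.sample_ids if s in groups.index and pd.notna(groups.loc[s])]
    if not common:
        raise ValueError("no samples with non-missing stage group")
    g = groups.loc[common]
    for label in ("low", "high"):
        if (g == label).sum() < 2:
            raise ValueError(f"need >=2 samples in stage group {label!r}")
    rows = []
    for feat in m.feature_ids:
        mut = m.data.loc[feat, common].to_numpy().astype(bool)
        high = (g == "high").to_numpy()
        table = [
            [int((mut & high).sum()), int((mut & ~high).sum())],
            [int((~mut & high).sum()), int((~mut & ~high).sum())],
        ]
        odds, p = stats.fisher_exact(table, alternative="two-sided")
        rows.append((feat, odds, p))
    out = pd.DataFrame(rows, columns=["feature", "odds_ratio", "p"]).set_index("feature")
    out["q"] = multipletests(out["p"], method="fdr_bh")[1] if len(out) else []
    return out
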