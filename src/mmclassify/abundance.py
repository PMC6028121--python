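"""Abundance-table container and compositional transforms.

The central microbiome object is a taxa-by-samples matrix of counts or
relative abundances, with Greengenes-style rank-prefixed lineage strings
("k__Bacteria; p__Firmicutes; ...") as taxon identifiers.  Internally the
table is always oriented taxa-rows x sample-columns (the QIIME classic
convention); readers re-orient on the way in.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Canonical taxonomic ranks and their lineage prefixes, shallow to deep.
RANKS = ("kingdom", "phylum", "class", "order", "family", "genus", "species")
RANK_PREFIXES = ("k", "p", "c", "o", "f", "g", "s")


def parse_lineage(lineage: str) -> list[str]:
    """Split a lineage string into stripped rank tokens.

    Tolerates both the spaced ("k__Bacteria; p__...") and unspaced
    dialects; comparison elsewhere is on the stripped tokens.
    """
    return [tok.strip() for tok in str(lineage).split(";")]


def canonical_lineage(lineage: str) -> str:
    """Normalized form used when matching taxa across tables/dialects."""
    return ";".join(parse_lineage(lineage))


def lineage_at_rank(lineage: str, rank: str) -> str:
    """Truncate a lineage to ``rank``, padding missing levels.

    A lineage shallower than the requested rank is bucketed under an
    explicit ``<prefix>__unclassified`` token rather than dropped.
    """
    depth = RANKS.index(rank) + 1
    tokens = parse_lineage(lineage)
    out = []
    for i in range(depth):
        prefix = RANK_PREFIXES[i]
        if i < len(tokens) and tokens[i] not in ("", f"{prefix}__"):
            out.append(tokens[i])
        else:
            out.append(f"{prefix}__unclassified")
    return ";".join(out)


@dataclass
class AbundanceTable:
    """Taxa x samples abundance matrix (counts or proportions).

    Parameters
    ----------
    data : pandas.DataFrame
        Rows indexed by lineage string, columns by sample id.  Values are
        non-negative counts or proportions.
    normalized : bool
        True when each sample column sums to one (relative abundances).
    rank : str or None
        Taxonomic level the rows were collapsed to, if any.
    """

    data: pd.DataFrame
    normalized: bool = False
    rank: str | None = None

    def __post_init__(self) -> None:
        self.data = self.data.astype(float)
        vals = self.data.to_numpy()
        if vals.size and np.nanmin(vals) < 0:
            raise ValueError("abundance values must be non-negative")
        if self.data.columns.duplicated().any():
            dupes = self.data.columns[self.data.columns.duplicated()].tolist()
            raise ValueError(f"duplicate sample ids: {dupes}")
        if self.data.index.duplicated().any():
            # merge duplicate taxa rows by summation
            self.data = self.data.groupby(level=0, sort=False).sum()
        if self.normalized:
            sums = self.data.sum(axis=0).to_numpy()
            if not np.allclose(sums, 1.0, atol=1e-9):
                raise ValueError("normalized table columns must sum to 1")

    # -- basic accessors -------------------------------------------------
    @property
    def taxon_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_taxa(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def to_feature_frame(self) -> pd.DataFrame:
        """Samples x taxa orientation for scikit-learn style estimators."""
        return self.data.T

    def select_samples(self, sample_ids) -> "AbundanceTable":
        return AbundanceTable(self.data[list(sample_ids)], normalized=self.normalized, rank=self.rank)

    def select_taxa(self, taxon_ids) -> "AbundanceTable":
        return AbundanceTable(self.data.loc[list(taxon_ids)], normalized=self.normalized, rank=self.rank)


def collapse_to_rank(table: AbundanceTable, rank: str) -> AbundanceTable:
    """Sum rows sharing a lineage prefix up to ``rank``.

    Per-sample totals are conserved exactly for integer counts; lineages
    that do not resolve to ``rank`` fall into an ``unclassified`` bucket
    (with a logged warning).
    """
    if rank not in RANKS:
        raise ValueError(f"unknown rank {rank!r}; expected one of {RANKS}")
    keys = [lineage_at_rank(t, rank) for t in table.taxon_ids]
    n_unclassified = sum("unclassified" in k for k in keys)
    if n_unclassified:
        logger.warning("%d lineages shallower than rank %s bucketed as unclassified", n_unclassified, rank)
    out = table.data.groupby(keys, sort=True).sum()
    out.index.name = table.data.index.name
    return AbundanceTable(out, normalized=table.normalized, rank=rank)


def relative_abundance(table: AbundanceTable) -> AbundanceTable:
    """Divide each sample column by its total.

    Idempotent on already-normalized tables (up to floating error).
    Raises on all-zero samples, which have no defined composition.
    """
    totals = table.data.sum(axis=0)
    zero = totals[totals == 0]
    if len(zero):
        raise ValueError(f"all-zero sample(s): {list(zero.index)}")
    return AbundanceTable(table.data / totals, normalized=True, rank=table.rank)
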