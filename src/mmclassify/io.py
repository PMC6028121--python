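"""Readers and writers for the four tabular input families.

Inputs: QIIME-classic OTU/taxon TSV, per-mutation annotation TSV,
sample metadata TSV, and a three-column Uniprot-idmapping-dialect
gene-to-pathway file.  Outputs: TSV result tables, edge-list TSV and
GraphML for networks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .abundance import AbundanceTable, canonical_lineage

logger = logging.getLogger(__name__)

PROVENANCE_PREFIX = "# mmclassify"


@dataclass
class ParseReport:
    """What a reader kept, merged, or dropped, and why."""

    n_rows: int = 0
    n_kept: int = 0
    n_merged_duplicates: int = 0
    dropped: list[tuple[str, str]] = field(default_factory=list)  # (row key, reason)

    def drop(self, key: str, reason: str) -> None:
        self.dropped.append((key, reason))
        logger.warning("dropped row %s: %s", key, reason)


# ---------------------------------------------------------------------------
# abundance tables
# ---------------------------------------------------------------------------

def read_abundance_table(path, orientation: str = "taxa_rows") -> tuple[AbundanceTable, ParseReport]:
    """Read a QIIME-classic TSV into a counts-mode :class:`AbundanceTable`.

    Handles the optional leading ``# Constructed from ...`` comment, a
    header row beginning ``#OTU ID``, and an optional trailing taxonomy
    column (used as the taxon id when present).  Duplicate taxa rows are
    summed; a duplicate sample id is an error.

    Parameters
    ----------
    orientation : {"taxa_rows", "samples_rows"}
        Layout of the file; internal orientation is always taxa x samples.
    """
    if orientation not in ("taxa_rows", "samples_rows"):
        raise ValueError("orientation must be 'taxa_rows' or 'samples_rows'")
    lines = Path(path).read_text().splitlines()
    header_idx = 0
    for i, line in enumerate(lines):
        if not line.startswith("#"):
            header_idx = i - 1 if i > 0 and lines[i - 1].lstrip("#").strip().lower().startswith("otu id") else i
            break
    else:
        raise ValueError(f"{path}: no data rows")
    header = lines[header_idx].lstrip("#").rstrip("\n")
    # duplicate header fields must be caught on the raw line: pandas would
    # silently mangle them to "S1.1" style names
    fields = header.split("\t")[1:]
    dupes = pd.Index(fields)[pd.Index(fields).duplicated()].tolist()
    if dupes:
        raise ValueError(f"{path}: duplicate sample id(s): {dupes}")
    body = [header] + [l for l in lines[header_idx + 1:] if l.strip()]
    from io import StringIO

    df = pd.read_csv(StringIO("\n".join(body)), sep="\t", dtype=str)
    report = ParseReport(n_rows=len(df))

    id_col = df.columns[0]
    tax_cols = [c for c in df.columns if c.strip().lower() in ("taxonomy", "consensus lineage", "consensuslineage")]
    if tax_cols:
        taxa = df[tax_cols[0]]
        df = df.drop(columns=tax_cols)
    else:
        taxa = df[id_col]
    df = df.drop(columns=[id_col]).set_axis(taxa.values, axis=0)

    if pd.Index(df.columns).duplicated().any():
        dupes = pd.Index(df.columns)[pd.Index(df.columns).duplicated()].tolist()
        raise ValueError(f"{path}: duplicate sample id(s): {dupes}")

    # strict numeric conversion with row/column named on failure
    values = np.empty(df.shape, dtype=float)
    for j, col in enumerate(df.columns):
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna()
        if bad.any():
            row = df.index[bad.to_numpy().nonzero()[0][0]]
            raise ValueError(f"{path}: non-numeric cell at row {row!r}, column {col!r}")
        values[:, j] = converted.to_numpy()
    out = pd.DataFrame(values, index=df.index, columns=df.columns)
    if orientation == "samples_rows":
        out = out.T
    n_before = len(out)
    table = AbundanceTable(out)  # merges duplicate taxa rows
    report.n_merged_duplicates = n_before - table.n_taxa
    report.n_kept = table.n_taxa
    return table, report


def write_abundance_table(table: AbundanceTable, path, provenance: str | None = None) -> None:
    """Write a table as QIIME-classic TSV (round-trips integer counts bit-exactly)."""
    with open(path, "w") as fh:
        if provenance:
            fh.write(f"{PROVENANCE_PREFIX} {provenance}\n")
        data = table.data
        if not table.normalized and np.allclose(data.to_numpy() % 1, 0):
            data = data.astype(np.int64)
        fh.write("#OTU ID\t" + "\t".join(map(str, table.sample_ids)) + "\n")
        data.to_csv(fh, sep="\t", header=False)


# ---------------------------------------------------------------------------
# mutation records
# ---------------------------------------------------------------------------

@dataclass
class MutationRecord:
    sample_id: str
    gene_symbol: str
    ensembl_gene_id: str | None
    effect_class: str  # synonymous | missense | lof | other
    raw_effect: str


#: Default column mapping for mutation TSVs; overridable because the exact
#: schema of deposited mutation tables varies between pipelines.
DEFAULT_MUTATION_COLUMNS = {
    "sample": "sample_id",
    "gene": "gene_symbol",
    "ensembl": "ensembl_gene_id",
    "effect": "effect",
}


def read_mutations(path, columns: dict | None = None) -> tuple[list[MutationRecord], ParseReport]:
    """Read a per-mutation annotation TSV into records.

    Effect classes are filled via :func:`mmclassify.mutations.classify_effect`;
    unknown effect strings become ``other`` and are counted in the report.
    Rows missing a gene symbol are skipped and logged.
    """
    from .mutations import classify_effect

    cols = dict(DEFAULT_MUTATION_COLUMNS)
    if columns:
        cols.update(columns)
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    for key in ("sample", "gene", "effect"):
        if cols[key] not in df.columns:
            raise ValueError(f"{path}: missing required column {cols[key]!r}")
    report = ParseReport(n_rows=len(df))
    records: list[MutationRecord] = []
    for i, row in df.iterrows():
        gene = row.get(cols["gene"])
        if pd.isna(gene) or not str(gene).strip():
            report.drop(f"row {i}", "missing gene symbol")
            continue
        raw = str(row.get(cols["effect"], "") or "")
        eff = classify_effect(raw)
        ens = row.get(cols.get("ensembl", ""), None)
        records.append(
            MutationRecord(
                sample_id=str(row[cols["sample"]]),
                gene_symbol=str(gene).strip(),
                ensembl_gene_id=None if pd.isna(ens) else str(ens),
                effect_class=eff,
                raw_effect=raw,
            )
        )
    report.n_kept = len(records)
    return records, report


# ---------------------------------------------------------------------------
# sample metadata
# ---------------------------------------------------------------------------

def read_metadata(path) -> pd.DataFrame:
    """Read sample metadata (sample_id, patient_id, tissue, stage, age, sex).

    Missing fields stay as explicit missing values; downstream operations
    decide whether to exclude them.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    if "sample_id" not in df.columns:
        raise ValueError(f"{path}: missing 'sample_id' column")
    df = df.set_index("sample_id")
    if df.index.duplicated().any():
        raise ValueError(f"{path}: duplicate sample ids")
    if "stage" in df.columns:
        df["stage"] = pd.to_numeric(df["stage"], errors="coerce").astype("Int64")
        bad = df["stage"].dropna()
        if len(bad) and not bad.isin([1, 2, 3, 4]).all():
            raise ValueError("stage values must be in {1,2,3,4} when present")
    if "age" in df.columns:
        df["age"] = pd.to_numeric(df["age"], errors="coerce")
    if "tissue" in df.columns and "patient_id" in df.columns:
        per = df.groupby("patient_id")["tissue"].value_counts()
        if (per > 1).any():
            raise ValueError("each patient may have at most one tumor and one normal sample")
    return df


# ---------------------------------------------------------------------------
# pathway maps
# ---------------------------------------------------------------------------

def read_pathway_map(path, database: str) -> dict[str, set[str]]:
    """Invert a 3-column idmapping-dialect file to pathway -> gene set.

    Only rows whose database tag matches ``database`` (case-insensitive)
    are kept; a gene may appear in multiple pathways.
    """
    df = pd.read_csv(path, sep="\t", header=None, names=["gene", "db", "value"], dtype=str)
    keep = df[df["db"].str.upper() == database.upper()]
    if keep.empty:
        raise ValueError(f"{path}: no rows with database tag {database!r}")
    out: dict[str, set[str]] = {}
    for _, row in keep.iterrows():
        out.setdefault(row["value"], set()).add(row["gene"])
    return out


# ---------------------------------------------------------------------------
# network output
# ---------------------------------------------------------------------------

def write_edge_list(graph: nx.Graph, path, provenance: str | None = None) -> None:
    with open(path, "w") as fh:
        if provenance:
            fh.write(f"{PROVENANCE_PREFIX} {provenance}\n")
        fh.write("taxon_i\ttaxon_j\tr\tpseudo_p\tstratum\n")
        stratum = graph.graph.get("stratum", "")
        for u, v, d in graph.edges(data=True):
            fh.write(f"{u}\t{v}\t{d['r']:.6g}\t{d['pseudo_p']:.6g}\t{stratum}\n")


def write_graphml(graph: nx.Graph, path) -> None:
    nx.write_graphml(graph, path)


def write_tsv(df: pd.DataFrame, path, provenance: str | None = None, index: bool = True) -> None:
    """Write a result table as TSV with an optional provenance comment line."""
    with open(path, "w") as fh:
        if provenance:
            fh.write(f"{PROVENANCE_PREFIX} {provenance}\n")
        df.to_csv(fh, sep="\t", index=index)
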