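"""End-to-end orchestration: simulate -> discriminate -> risk index ->
evaluate -> network -> robustness, driven by one config mapping, with a
provenance manifest (input hashes, parameters, seed) per run.

A failure in one mutation feature is collected and reported without
aborting the other features.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .abundance import AbundanceTable, relative_abundance
from .evaluation import accuracy_at_specificity, kfold_roc, loo_optimal_cutoff
from .io import read_abundance_table, read_metadata, write_abundance_table, write_edge_list, write_graphml, write_tsv
from .lefse import DiscriminationConfig, discriminant_taxa
from .risk import fdr_adjust, loo_risk_indices, permutation_test
from .robustness import PerTaxonLinearModel
from .simulate import SyntheticConfig, generate_dataset
from .sparcc import SparccConfig, differential_networks

logger = logging.getLogger(__name__)

DEFAULTS = {
    "kw_alpha": 0.05,
    "lda_threshold": 2.0,
    "n_bootstrap": 30,
    "bootstrap_fraction": 2.0 / 3.0,
    "min_patients": 10,
    "spec": 0.8,
    "B": 999,
    "k_folds": 10,
    "sparcc": {},
    "stages": ["discriminate", "risk_index", "evaluate"],
}


def _sha256(path: Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _discrimination_config(cfg: dict, seed: int) -> DiscriminationConfig:
    return DiscriminationConfig(
        kw_alpha=cfg["kw_alpha"],
        lda_threshold=cfg["lda_threshold"],
        n_bootstrap=cfg["n_bootstrap"],
        bootstrap_fraction=cfg["bootstrap_fraction"],
        seed=seed,
    )


def run_pipeline(config: dict) -> dict:
    """Execute the requested stages; returns (and writes) the run manifest.

    ``config`` keys: either ``simulate`` (a :class:`SyntheticConfig`
    field mapping) or ``abundance_path`` (+ optional ``metadata_path``);
    ``out_dir``; ``seed``; optional threshold overrides (see
    ``DEFAULTS``); ``stages``.
    """
    cfg = {**DEFAULTS, **config}
    if "seed" not in cfg:
        raise ValueError("seed is mandatory for stochastic stages")
    seed = int(cfg["seed"])
    out_dir = Path(cfg["out_dir"])
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": seed,
        "parameters": {k: v for k, v in cfg.items() if k not in ("stages", "out_dir")},
        "stages": {},
        "outputs": {},
        "errors": {},
    }
    provenance = f"version={__version__} seed={seed}"

    # ---- inputs -----------------------------------------------------------
    if "simulate" in cfg:
        sim_cfg = SyntheticConfig(**{**cfg["simulate"], "seed": seed})
        ds = generate_dataset(sim_cfg)
        counts, labels_df = ds.abundance, ds.labels.data
        write_abundance_table(counts, out_dir / "otu_table.tsv", provenance)
        write_tsv(labels_df, out_dir / "labels.tsv", provenance)
        truth = pd.DataFrame(
            [(f, t, fold, d) for f, entries in ds.truth.items() for t, fold, d in entries],
            columns=["feature", "taxon", "fold_change", "direction"],
        )
        write_tsv(truth, out_dir / "truth.tsv", provenance, index=False)
        manifest["stages"]["simulate"] = {"n_samples": counts.n_samples, "n_taxa": counts.n_taxa}
    else:
        if "abundance_path" not in cfg:
            raise FileNotFoundError("config needs 'simulate' or 'abundance_path'")
        counts, _ = read_abundance_table(cfg["abundance_path"])
        labels_df = pd.read_csv(cfg["labels_path"], sep="\t", index_col=0, comment="#")
        labels_df = labels_df[counts.sample_ids]

    if cfg.get("feature_scope") == "stage":
        if "metadata_path" not in cfg:
            raise ValueError("feature scope 'stage' requires metadata_path with a 'stage' column")
        from .mutations import stage_groups

        meta = read_metadata(cfg["metadata_path"])
        groups = stage_groups(meta)
        labels_df = pd.DataFrame({"stage": (groups == "high").astype(int)}).T

    rel = relative_abundance(counts)
    X = rel.to_feature_frame()

    # ---- per-feature analyses --------------------------------------------
    dcfg = _discrimination_config(cfg, seed)
    summary_rows = []
    for feature in labels_df.index:
        y = labels_df.loc[feature].reindex(X.index)
        try:
            if "discriminate" in cfg["stages"]:
                taxa = discriminant_taxa(rel, y, dcfg)
                write_tsv(
                    pd.DataFrame(
                        [(t.taxon_id, t.enriched_class, t.kw_p, t.lda_log10) for t in taxa],
                        columns=["taxon", "enriched_class", "kw_p", "lda_log10"],
                    ),
                    out_dir / f"{feature}_discriminant_taxa.tsv",
                    provenance,
                    index=False,
                )
            row = {"feature": feature}
            if "risk_index" in cfg["stages"]:
                result = loo_risk_indices(rel, y, dcfg)
                perm_p, result = permutation_test(rel, y, dcfg, B=cfg["B"], observed=result)
                write_tsv(result.risk_index.to_frame(), out_dir / f"{feature}_risk_index.tsv", provenance)
                row.update(
                    n_taxa=result.n_taxa_used,
                    observed_diff=result.observed_diff,
                    mwu_p=result.mwu_p,
                    perm_p=result.perm_p,
                )
            if "evaluate" in cfg["stages"]:
                roc = kfold_roc(rel, y, k=cfg["k_folds"], config=dcfg, random_state=seed)
                scores = loo_risk_indices(rel, y, dcfg).risk_index if "risk_index" not in cfg["stages"] else result.risk_index
                cut = accuracy_at_specificity(scores.dropna(), y.loc[scores.dropna().index], spec=cfg["spec"])
                loo_cut = loo_optimal_cutoff(scores.to_numpy(), y.to_numpy())
                pd.DataFrame({"fpr": roc.mean_fpr, "tpr": roc.mean_tpr}).to_csv(
                    out_dir / f"{feature}_mean_roc.tsv", sep="\t", index=False
                )
                row.update(
                    auc=roc.auc,
                    cutoff=loo_cut.cutoff,
                    sensitivity=loo_cut.sensitivity,
                    specificity=loo_cut.specificity,
                    accuracy_at_spec=cut.accuracy,
                    loo_accuracy=loo_cut.accuracy,
                )
            if "network" in cfg["stages"]:
                taxa_ids = [t.taxon_id for t in discriminant_taxa(rel, y, dcfg)]
                scfg = SparccConfig(seed=seed, **cfg["sparcc"])
                net_mut, net_wt, diff = differential_networks(counts, y, taxa_ids, scfg, feature_name=feature)
                for name, g in (("mutated", net_mut), ("wildtype", net_wt)):
                    write_edge_list(g, out_dir / f"{feature}_{name}_edges.tsv", provenance)
                    write_graphml(g, out_dir / f"{feature}_{name}.graphml")
                row["n_differential_edges"] = len(diff)
            if "robustness" in cfg["stages"]:
                lm = PerTaxonLinearModel().fit(X, y)
                write_tsv(lm.summary_frame(), out_dir / f"{feature}_robustness.tsv", provenance)
                row["lm_min_q"] = float(lm.summary_frame()["q"].min()) if len(lm.results_) else np.nan
            summary_rows.append(row)
        except Exception as exc:  # collected, not fatal for other features
            logger.exception("feature %s failed", feature)
            manifest["errors"][str(feature)] = f"{type(exc).__name__}: {exc}"

    if summary_rows:
        summary = pd.DataFrame(summary_rows).set_index("feature")
        if "perm_p" in summary.columns:
            summary["q"] = fdr_adjust(summary["perm_p"].to_numpy())
        write_tsv(summary, out_dir / "summary.tsv", provenance)

    for path in sorted(out_dir.glob("*")):
        if path.name != "manifest.json" and path.is_file():
            manifest["outputs"][path.name] = _sha256(path)
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
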