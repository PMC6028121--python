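import numpy as np
import pandas as pd
import pytest

from mmclassify.io import MutationRecord
from mmclassify.mutations import (
    MutationMatrix,
    build_matrix,
    classify_effect,
    collapse_to_pathways,
    confounding_test,
    gene_id_map,
    prevalence_filter,
    stage_groups,
)


def _rec(sample, gene, effect_class, ensembl=None):
    return MutationRecord(sample, gene, ensembl, effect_class, effect_class)


class TestClassifyEffect:
    @pytest.mark.parametrize(
        "raw,expected",
        [
            ("stop_gained", "lof"),
            ("Frameshift", "lof"),
            ("STOP LOST", "lof"),
            ("missense_variant", "missense"),
            ("nonsynonymous SNV", "missense"),
            ("synonymous_variant", "synonymous"),
            ("silent", "synonymous"),
            ("intergenic_region", "other"),
        ],
    )
    def test_alias_table(self, raw, expected):
        assert classify_effect(raw) == expected

    def test_composite_resolves_to_most_severe(self):
        assert classify_effect("missense_variant&stop_gained") == "lof"
        assert classify_effect("synonymous_variant&missense_variant") == "missense"


class TestBuildMatrix:
    def test_binarization_idempotent_on_duplicates(self):
        records = [_rec("S1", "APC", "lof"), _rec("S1", "APC", "lof"), _rec("S2", "APC", "lof")]
        m = build_matrix(records, ["S1", "S2", "S3"])
        assert m.data.loc["APC"].tolist() == [1, 1, 0]

    def test_scope_filters_effects(self):
        records = [_rec("S1", "APC", "lof"), _rec("S2", "APC", "missense"), _rec("S3", "APC", "synonymous")]
        samples = ["S1", "S2", "S3"]
        assert build_matrix(records, samples, "lof").data.loc["APC"].sum() == 1
        assert build_matrix(records, samples, "missense").data.loc["APC"].tolist() == [0, 1, 0]
        assert build_matrix(records, samples, "nonsynonymous").data.loc["APC"].sum() == 2
        assert build_matrix(records, samples, "total").data.loc["APC"].sum() == 3

    def test_unknown_scope_rejected(self):
        with pytest.raises(ValueError, match="effect_scope"):
            build_matrix([], [], "nonsense")

    def test_records_outside_sample_list_ignored(self):
        m = build_matrix([_rec("SX", "APC", "lof")], ["S1"])
        assert m.data.empty or m.data.to_numpy().sum() == 0

    def test_non_binary_matrix_rejected(self):
        with pytest.raises(ValueError, match="binary"):
            MutationMatrix(pd.DataFrame({"S1": [2]}, index=["APC"]))


class TestPathwayCollapse:
    def test_or_semantics(self):
        records = [_rec("S1", "APC", "lof"), _rec("S2", "CTNNB1", "lof")]
        m = build_matrix(records, ["S1", "S2", "S3"])
        pmap = {"wnt": {"APC", "CTNNB1"}, "empty_path": {"NOTAGENE"}}
        out = collapse_to_pathways(m, pmap)
        # pathway indicator is the OR of member-gene indicators
        assert out.data.loc["wnt"].tolist() == [1, 1, 0]
        assert "empty_path" not in out.feature_ids

    def test_ensembl_id_matching(self):
        records = [_rec("S1", "APC", "lof", ensembl="ENSG00000134982")]
        m = build_matrix(records, ["S1"])
        pmap = {"wnt": {"ENSG00000134982"}}
        out = collapse_to_pathways(m, pmap, gene_ids=gene_id_map(records))
        assert out.data.loc["wnt", "S1"] == 1

    def test_requires_gene_level_input(self):
        m = MutationMatrix(pd.DataFrame({"S1": [1]}, index=["wnt"]), feature_kind="kegg_pathway")
        with pytest.raises(ValueError, match="gene-level"):
            collapse_to_pathways(m, {})

    def test_collapse_conservation(self):
        # any mutated member gene implies the pathway is mutated, and a
        # pathway is never mutated in a sample with no mutated member
        rng = np.random.default_rng(0)
        genes = [f"G{i}" for i in range(12)]
        samples = [f"S{i}" for i in range(9)]
        data = pd.DataFrame(rng.integers(0, 2, (12, 9)), index=genes, columns=samples)
        m = MutationMatrix(data)
        pmap = {f"pw{j}": set(rng.choice(genes, 4, replace=False)) for j in range(5)}
        out = collapse_to_pathways(m, pmap)
        for pw, members in pmap.items():
            if pw not in out.feature_ids:
                continue
            expected = (m.data.loc[sorted(members)].sum(axis=0) > 0).astype(int)
            assert out.data.loc[pw].tolist() == expected.tolist()


class TestPrevalenceAndStage:
    def test_prevalence_filter(self):
        data = pd.DataFrame(
            [[1, 1, 1], [1, 0, 0]], index=["common", "rare"], columns=["S1", "S2", "S3"]
        )
        kept, report = prevalence_filter(MutationMatrix(data), min_patients=2)
        assert kept.feature_ids == ["common"]
        assert report.dropped == ["rare"] and report.n_dropped == 1

    def test_stage_groups(self):
        meta = pd.DataFrame({"stage": [1, 2, 3, 4, pd.NA]}, index=list("abcde"))
        g = stage_groups(meta)
        assert g.tolist()[:4] == ["low", "low", "high", "high"]
        assert pd.isna(g.loc["e"])

    def test_confounding_test_perfect_association(self):
        samples = [f"S{i}" for i in range(10)]
        data = pd.DataFrame([[1] * 5 + [0] * 5], index=["APC"], columns=samples)
        groups = pd.Series(["high"] * 5 + ["low"] * 5, index=samples)
        out = confounding_test(MutationMatrix(data), groups)
        # hypergeometric: 2 / C(10,5) for the perfectly confounded table
        assert out.loc["APC", "p"] == pytest.approx(2 / 252)

    def test_confounding_excludes_missing_stage(self):
        samples = [f"S{i}" for i in range(6)]
        data = pd.DataFrame([[1, 0, 1, 0, 1, 0]], index=["APC"], columns=samples)
        groups = pd.Series(["high", "high", "low", "low", pd.NA, pd.NA], index=samples)
        out = confounding_test(MutationMatrix(data), groups)
        assert 0 < out.loc["APC", "p"] <= 1
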