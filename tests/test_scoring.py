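from itertools import product

import numpy as np
import pandas as pd
import pytest

from surfscore.io import ValidationError
from surfscore.scoring import (
    ScoringConfig,
    classify_cancer_genes,
    evidence_matrix,
    pan_cancer_union,
    per_sample_evidence,
    s_score,
    s_score_table,
    score_tumor_type,
    standardize,
)
from surfscore.simulate import gen_cohort


def evidence_oracle(cna, expr_z, mut_classes, cfg=ScoringConfig()):
    """Independent restatement of the evidence sign rule."""
    onc = int(cna == cfg.cna_amplified) + int(expr_z > cfg.expr_high)
    sup = (
        int(cna == cfg.cna_deleted)
        + int(expr_z < cfg.expr_low)
        + int(bool(set(mut_classes) & cfg.deleterious_classes))
    )
    return int(np.sign(onc - sup))


class TestPerSampleEvidence:
    @pytest.mark.parametrize(
        "cna,expr,muts",
        list(
            product(
                [-2, -1, 0, 1, 2],
                [-2.5, -2.0, 0.0, 2.0, 2.5],
                [[], ["missense"], ["nonsense"], ["silent", "splice_site"]],
            )
        ),
    )
    def test_matches_sign_oracle(self, omics_factory, cna, expr, muts):
        rows = [("S1", "G1", c) for c in muts]
        omics = omics_factory(["G1"], ["S1"], cna=[[cna]], expr=[[expr]], mutation_rows=rows)
        expected = evidence_oracle(cna, expr, muts)
        assert per_sample_evidence("G1", "S1", omics) == expected
        assert evidence_matrix(["G1"], omics).iloc[0, 0] == expected

    def test_no_signal_is_zero(self, omics_factory):
        omics = omics_factory(["G1"], ["S1"], cna=[[0]], expr=[[1.5]])
        assert per_sample_evidence("G1", "S1", omics) == 0

    def test_deletion_plus_nonsense_is_minus_one(self, omics_factory):
        omics = omics_factory(
            ["G1"], ["S1"], cna=[[-2]], expr=[[0.0]],
            mutation_rows=[("S1", "G1", "nonsense")],
        )
        assert per_sample_evidence("G1", "S1", omics) == -1

    def test_conflicting_signals_cancel(self, omics_factory):
        omics = omics_factory(["G1"], ["S1"], cna=[[2]], expr=[[-2.5]])
        assert per_sample_evidence("G1", "S1", omics) == 0

    def test_missing_gene_is_no_signal(self, omics_factory):
        omics = omics_factory(["G1"], ["S1"], cna=[[2]], expr=[[2.5]])
        assert per_sample_evidence("GX", "S1", omics) == 0
        assert evidence_matrix(["GX"], omics).iloc[0, 0] == 0

    def test_unknown_sample_errors(self, omics_factory):
        omics = omics_factory(["G1"], ["S1"], cna=[[0]])
        with pytest.raises(ValidationError):
            per_sample_evidence("G1", "SX", omics)

    def test_missense_oncogenic_config(self, omics_factory):
        omics = omics_factory(
            ["G1"], ["S1"], cna=[[0]], expr=[[0.0]],
            mutation_rows=[("S1", "G1", "missense")],
        )
        assert per_sample_evidence("G1", "S1", omics) == 0
        cfg = ScoringConfig(missense_oncogenic=True)
        assert per_sample_evidence("G1", "S1", omics, cfg) == 1


class TestSScore:
    def test_ten_percent_suppressor(self):
        e = np.zeros(100)
        e[:10] = -1
        assert s_score(e) == -10.0

    def test_all_positive_bound(self):
        assert s_score(np.ones(50)) == 100.0

    def test_symmetric_cancellation(self):
        e = np.concatenate([np.ones(50), -np.ones(50)])
        assert s_score(e) == 0.0

    def test_empty_errors(self):
        with pytest.raises(ValidationError):
            s_score(np.array([]))

    def test_monotone_in_suppressor_count(self):
        # raising a suppressor's alteration frequency never raises S
        scores = []
        for k in range(0, 101, 10):
            e = np.zeros(100)
            e[:k] = -1
            scores.append(s_score(e))
        assert scores == sorted(scores, reverse=True)


class TestStandardize:
    def test_symmetric_three_values(self):
        s = pd.Series([-1.0, 0.0, 1.0], index=list("abc"))
        z = standardize(s)
        assert z.tolist() == pytest.approx([-1.0, 0.0, 1.0])

    def test_mean_zero_sd_one(self):
        rng = np.random.default_rng(0)
        s = pd.Series(rng.normal(5, 3, size=200))
        z = standardize(s)
        assert abs(z.mean()) < 1e-12
        assert abs(z.std(ddof=1) - 1) < 1e-12

    def test_idempotence(self):
        rng = np.random.default_rng(1)
        s = pd.Series(rng.normal(size=50))
        z = standardize(s)
        pd.testing.assert_series_equal(standardize(z), z)

    def test_gene_at_mean_is_zero(self):
        s = pd.Series([1.0, 2.0, 3.0])
        assert standardize(s)[1] == 0.0

    def test_zero_variance_errors(self):
        with pytest.raises(ValidationError):
            standardize(pd.Series([2.0, 2.0, 2.0]))

    def test_single_gene_errors(self):
        with pytest.raises(ValidationError):
            standardize(pd.Series([1.0]))


class TestClassify:
    def test_boundary_inclusive_main(self):
        z = pd.Series({"a": 3.0, "b": -3.0, "c": 2.9})
        cls = classify_cancer_genes(z, 3.0, inclusive=True)
        assert cls.tolist() == ["oncogene", "suppressor", "none"]

    def test_relaxed_strict(self):
        z = pd.Series({"a": -2.5, "b": 2.0})
        assert classify_cancer_genes(z, 3.0)["a"] == "none"
        cls = classify_cancer_genes(z, 2.0, inclusive=False)
        assert cls.tolist() == ["suppressor", "none"]

    def test_empty_union(self):
        z = pd.Series({"a": 1.0, "b": -1.5})
        table = pd.DataFrame(
            {"gene_id": z.index, "class": classify_cancer_genes(z, 3.0)}
        )
        assert pan_cancer_union({"T1": table}) == []

    def test_union_across_tumors(self):
        t1 = pd.DataFrame({"gene_id": ["a", "b"], "class": ["oncogene", "none"]})
        t2 = pd.DataFrame({"gene_id": ["a", "b"], "class": ["none", "suppressor"]})
        assert pan_cancer_union({"T1": t1, "T2": t2}) == ["a", "b"]

    def test_nonpositive_threshold_errors(self):
        with pytest.raises(ValidationError):
            classify_cancer_genes(pd.Series([1.0]), 0.0)


class TestSyntheticRecovery:
    def test_planted_signs_single_seed(self):
        planted = {
            f"G{i:05d}": ("suppressor" if i <= 5 else "oncogene", 0.15)
            for i in range(1, 11)
        }
        cohort = gen_cohort(
            n_genes=500, n_samples=500, background_rate=0.01, planted=planted, seed=99
        )
        genes = list(cohort.cna.index)
        s = s_score_table(genes, cohort.omics)
        for gene, (role, _freq) in planted.items():
            if role == "suppressor":
                assert s[gene] < 0
            else:
                assert s[gene] > 0

    def test_score_tumor_type_table(self):
        planted = {"G00001": ("suppressor", 0.3)}
        cohort = gen_cohort(
            n_genes=100, n_samples=200, background_rate=0.01, planted=planted, seed=3
        )
        table = score_tumor_type(list(cohort.cna.index), cohort.omics, "TT")
        assert set(table.columns) == {"gene_id", "tumor_type", "S", "z", "class"}
        row = table.set_index("gene_id").loc["G00001"]
        assert row["class"] == "suppressor"
        assert row["z"] <= -3
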