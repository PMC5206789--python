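from itertools import chain, combinations

import pytest

from surfscore.catalog import (
    DEFAULT_EXCLUSION_VOCABULARY,
    CatalogConfig,
    build_catalog,
    classify_gene,
    classify_isoform,
    family_coverage,
    is_exclusively_internal,
    set_overlap,
)
from surfscore.io import ProteinRecord, SignalPeptideCall, ValidationError
from surfscore.simulate import gen_annotation_bundle


def protein(length=300, pid="P1", gene="G1"):
    return ProteinRecord(pid, gene, length)


class TestIsoformRules:
    def test_r1_no_segments(self):
        assert classify_isoform(protein(), []) == ("no_tm", ["R1"])

    def test_r2_single_tm_in_first_50(self):
        verdict, trace = classify_isoform(protein(), [(10, 32)])
        assert (verdict, trace) == ("secreted", ["R2"])

    def test_two_tm_domains_pass(self):
        verdict, _ = classify_isoform(protein(), [(10, 32), (60, 82)])
        assert verdict == "pass"

    def test_r3_tm_outside_signal_region_passes(self):
        sp = SignalPeptideCall("P1", True, 25)
        verdict, _ = classify_isoform(protein(), [(55, 77)], sp)
        assert verdict == "pass"

    def test_r3_tm_inside_signal_region_secreted(self):
        sp = SignalPeptideCall("P1", True, 80)
        verdict, trace = classify_isoform(protein(), [(55, 77)], sp)
        assert (verdict, trace) == ("secreted", ["R3"])

    @pytest.mark.parametrize(
        "end,expected",
        [(49, "secreted"), (50, "secreted"), (51, "pass")],
    )
    def test_r2_boundary(self, end, expected):
        verdict, _ = classify_isoform(protein(), [(end - 20, end)])
        assert verdict == expected

    @pytest.mark.parametrize(
        "cleavage,expected",
        [(76, "pass"), (77, "secreted"), (78, "secreted")],
    )
    def test_r3_boundary(self, cleavage, expected):
        # TM (55, 77) is covered by the signal peptide iff end <= cleavage
        sp = SignalPeptideCall("P1", True, cleavage)
        verdict, _ = classify_isoform(protein(), [(55, 77)], sp)
        assert verdict == expected

    def test_r2_start_anchor_config(self):
        cfg = CatalogConfig(r2_anchor="start")
        verdict, _ = classify_isoform(protein(), [(45, 70)], cfg=cfg)
        assert verdict == "secreted"
        verdict, _ = classify_isoform(protein(), [(51, 70)], cfg=cfg)
        assert verdict == "pass"

    def test_segment_outside_protein_errors(self):
        with pytest.raises(ValidationError):
            classify_isoform(protein(length=40), [(10, 60)])

    def test_monotonicity_adding_second_segment(self):
        # a gene rejected by R2 can only move toward the surface
        verdict_one, _ = classify_isoform(protein(), [(10, 32)])
        assert verdict_one == "secreted"
        verdict_two, _ = classify_isoform(protein(), [(10, 32), (100, 122)])
        assert verdict_two == "pass"


class TestGeneRule:
    def test_exclusively_internal(self):
        d = classify_gene("G1", {"P1": "pass"}, {"nucleus", "ribosome"})
        assert d.verdict == "internal_compartment"

    def test_mixed_compartments_surface(self):
        d = classify_gene("G1", {"P1": "pass"}, {"nucleus", "plasma membrane"})
        assert d.verdict == "surfaceome"

    def test_unannotated_surface(self):
        d = classify_gene("G1", {"P1": "pass"}, set())
        assert d.verdict == "surfaceome"

    def test_no_passing_isoform_most_permissive(self):
        d = classify_gene("G1", {"P1": "no_tm", "P2": "secreted"})
        assert d.verdict == "secreted"
        d = classify_gene("G1", {"P1": "no_tm"})
        assert d.verdict == "no_tm"

    def test_any_isoform_passing_wins(self):
        d = classify_gene("G1", {"P1": "no_tm", "P2": "pass"}, set())
        assert d.verdict == "surfaceome"

    def test_empty_isoforms_error(self):
        with pytest.raises(ValidationError):
            classify_gene("G1", {})

    def test_exclusivity_predicate_matches_bruteforce(self):
        vocab = sorted(DEFAULT_EXCLUSION_VOCABULARY) + ["plasma membrane"]
        labels = vocab[:6]
        for r in range(len(labels) + 1):
            for subset in combinations(labels, r):
                subset = set(subset)
                expected = bool(subset) and subset <= DEFAULT_EXCLUSION_VOCABULARY
                assert is_exclusively_internal(subset) == expected


class TestBuildCatalog:
    def test_empty_input(self):
        result = build_catalog([], {}, None, None)
        assert result.surfaceome == set()
        assert sum(result.counts.values()) == 0

    def test_r2_saturation(self):
        proteins = [protein(pid=f"P{i}", gene=f"G{i}") for i in range(10)]
        tm = {p.protein_id: [(10, 30)] for p in proteins}
        result = build_catalog(proteins, tm)
        assert result.surfaceome == set()
        assert result.counts["secreted"] == 10

    def test_zero_isoform_gene_errors(self):
        with pytest.raises(ValidationError, match="zero isoforms"):
            build_catalog([protein()], {"P1": []}, genes=["G1", "GX"])

    def test_synthetic_truth_recovery(self):
        bundle = gen_annotation_bundle(n_genes=100, seed=123)
        result = build_catalog(
            bundle.proteins, bundle.tm_segments, bundle.signalp, bundle.compartments
        )
        truth = dict(zip(bundle.truth["gene_id"], bundle.truth["verdict"]))
        assert {g: d.verdict for g, d in result.decisions.items()} == truth

    def test_verdict_partition(self):
        bundle = gen_annotation_bundle(n_genes=137, seed=5)
        result = build_catalog(
            bundle.proteins, bundle.tm_segments, bundle.signalp, bundle.compartments
        )
        assert sum(result.counts.values()) == 137
        for d in result.decisions.values():
            assert d.reason_trace


class TestBenchmarks:
    def test_family_fully_covered(self):
        assert family_coverage({"A", "B", "C"}, {"A", "B"}) == 1.0

    def test_family_disjoint(self):
        assert family_coverage({"A"}, {"B", "C"}) == 0.0

    def test_family_fraction(self):
        catalog = {f"G{i}" for i in range(44)} | {"X"}
        family = {f"G{i}" for i in range(44)} | {f"F{i}" for i in range(6)}
        assert family_coverage(catalog, family) == pytest.approx(0.88)

    def test_empty_family_errors(self):
        with pytest.raises(ValidationError):
            family_coverage({"A"}, set())

    def test_overlap_ratios(self):
        catalog = {f"C{i}" for i in range(3758 - 664)} | {f"I{i}" for i in range(664)}
        external = {f"I{i}" for i in range(664)} | {f"E{i}" for i in range(996 - 664)}
        inter, frac_ext, frac_cat = set_overlap(catalog, external)
        assert inter == 664
        assert frac_ext == pytest.approx(664 / 996)
        assert frac_cat == pytest.approx(664 / 3758)

    def test_identical_sets(self):
        s = {"A", "B", "C"}
        assert set_overlap(s, set(s)) == (3, 1.0, 1.0)

    def test_empty_set_errors(self):
        with pytest.raises(ValidationError):
            set_overlap(set(), {"A"})


def test_cleavage_without_positive_is_rejected():
    with pytest.raises(ValidationError):
        SignalPeptideCall("P1", False, 20)
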