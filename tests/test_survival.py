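import numpy as np
import pandas as pd
import pytest

from surfscore.alteration import AlterationMatrix, build_alteration_matrix
from surfscore.io import ValidationError
from surfscore.simulate import gen_survival_cohort
from surfscore.survival import (
    combination_search,
    gene_screen,
    km_estimate,
    logrank_test,
)

from .oracles import ecdf_survivor, logrank_chi2_oracle, permutation_pvalue


def bool_matrix(values, genes, samples):
    df = pd.DataFrame(np.asarray(values, dtype=bool), index=genes, columns=samples)
    return AlterationMatrix(values=df, layers={})


def clinical_frame(times, events, samples=None):
    samples = samples or [f"S{i}" for i in range(len(times))]
    return pd.DataFrame(
        {"sample_id": samples, "os_time_days": times, "os_event": events}
    )


class TestKaplanMeier:
    def test_one_event_among_four(self):
        curve = km_estimate([1.0, 5.0, 6.0, 7.0], [1, 0, 0, 0])
        assert curve.times.tolist() == [1.0]
        assert curve.survival.tolist() == [0.75]

    def test_no_events_flat_one(self):
        curve = km_estimate([1.0, 2.0, 3.0], [0, 0, 0])
        assert curve.times.size == 0
        assert curve.at(2.5) == 1.0

    def test_all_events_equals_empirical_survivor(self):
        curve = km_estimate([1.0, 2.0, 3.0, 4.0], [1, 1, 1, 1])
        assert curve.survival.tolist() == pytest.approx([0.75, 0.5, 0.25, 0.0])

    def test_matches_ecdf_random_battery(self):
        rng = np.random.default_rng(12)
        for _ in range(100):
            n = int(rng.integers(1, 51))
            times = np.round(rng.exponential(10, n), 2)
            curve = km_estimate(times, np.ones(n, dtype=bool))
            for t, s in zip(curve.times, curve.survival):
                assert s == pytest.approx(ecdf_survivor(times, t), abs=1e-12)

    def test_censored_at_event_time_stays_at_risk(self):
        # events precede censoring at ties: n=3 at t=1, one event
        curve = km_estimate([1.0, 1.0, 2.0], [1, 0, 0])
        assert curve.n_risk.tolist() == [3]
        assert curve.survival.tolist() == pytest.approx([2 / 3])

    def test_invariants(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            n = int(rng.integers(2, 40))
            times = np.round(rng.exponential(5, n), 1)
            events = rng.random(n) < 0.7
            curve = km_estimate(times, events)
            s = curve.survival
            assert np.all((0 <= s) & (s <= 1))
            assert np.all(np.diff(s) <= 1e-12)
            assert np.all(np.diff(curve.n_risk) < 0)
            assert curve.at(0.0) <= 1.0

    def test_empty_errors(self):
        with pytest.raises(ValidationError):
            km_estimate([], [])


class TestLogRank:
    def test_identical_groups_null(self):
        times = [1.0, 2.0, 3.0, 1.0, 2.0, 3.0]
        events = [1, 1, 0, 1, 1, 0]
        groups = [1, 1, 1, 0, 0, 0]
        res = logrank_test(groups, times, events)
        assert res.chi2 == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)

    def test_label_swap_invariance(self):
        rng = np.random.default_rng(8)
        times = rng.exponential(10, 30)
        events = rng.random(30) < 0.8
        g = rng.random(30) < 0.5
        if g.all() or not g.any():
            g[0] = ~g[0]
        a = logrank_test(g, times, events)
        b = logrank_test(~g, times, events)
        assert a.chi2 == pytest.approx(b.chi2)
        assert a.p == pytest.approx(b.p)

    def test_empty_group_errors(self):
        with pytest.raises(ValidationError):
            logrank_test([1, 1, 1], [1.0, 2.0, 3.0], [1, 1, 1])

    def test_zero_events_warns_p_one(self):
        with pytest.warns(UserWarning, match="zero events"):
            res = logrank_test([1, 0], [5.0, 6.0], [0, 0])
        assert res.chi2 == 0.0
        assert res.p == 1.0

    def test_two_vs_two_frozen_values(self):
        # early events in group A vs late in group B, no censoring
        times = np.array([1.0, 2.0, 3.0, 4.0])
        events = np.ones(4, dtype=bool)
        group = np.array([True, True, False, False])
        res = logrank_test(group, times, events)
        assert res.chi2 == pytest.approx(2.8823529411764706, rel=1e-12)
        # the asymptotic chi-square tail is an approximation at n=4; the
        # exact-permutation route must agree with the oracle exactly
        p_perm_impl = permutation_pvalue(
            times, events, group,
            statistic=lambda t, e, g: logrank_test(g, t, e).chi2,
        )
        p_perm_oracle = permutation_pvalue(times, events, group)
        assert p_perm_impl == p_perm_oracle == pytest.approx(1 / 3)

    def test_statistic_matches_oracle_random(self):
        rng = np.random.default_rng(21)
        for _ in range(50):
            n = int(rng.integers(4, 40))
            times = np.round(rng.exponential(10, n), 1)
            events = rng.random(n) < 0.8
            g = np.zeros(n, dtype=bool)
            g[rng.choice(n, int(rng.integers(1, n)), replace=False)] = True
            res = logrank_test(g, times, events)
            assert res.chi2 == pytest.approx(
                logrank_chi2_oracle(times, events, g), abs=1e-9
            )

    def test_asymptotic_p_close_to_mc_permutation_at_moderate_n(self):
        rng = np.random.default_rng(7)
        n = 60
        times = rng.exponential(100, n)
        events = rng.random(n) < 0.8
        g = np.zeros(n, dtype=bool)
        g[rng.choice(n, 25, replace=False)] = True
        res = logrank_test(g, times, events)
        hits = 0
        B = 2000
        for _ in range(B):
            gp = np.zeros(n, dtype=bool)
            gp[rng.choice(n, 25, replace=False)] = True
            if logrank_test(gp, times, events).chi2 >= res.chi2 - 1e-12:
                hits += 1
        assert abs(hits / B - res.p) < 0.05


class TestGeneScreen:
    def test_redundant_genes_collapse(self):
        # G1 and G2 have identical altered-sample sets
        n = 40
        rng = np.random.default_rng(5)
        col = rng.random(n) < 0.4
        matrix = bool_matrix([col, col, rng.random(n) < 0.4], ["G1", "G2", "G3"],
                             [f"S{i}" for i in range(n)])
        times = np.where(col, rng.exponential(5, n), rng.exponential(50, n))
        clin = clinical_frame(times, np.ones(n, dtype=int))
        res = gene_screen(["G1", "G2", "G3"], matrix, clin, alpha=0.05)
        assert "G1" in res.selected
        assert "G2" not in res.selected
        row = res.table.set_index("gene_id").loc["G2"]
        assert row["reason"] == "redundant_with:G1"

    def test_alpha_zero_empty(self):
        matrix = bool_matrix([[1, 0, 1, 0]], ["G1"], ["S0", "S1", "S2", "S3"])
        clin = clinical_frame([1.0, 2.0, 3.0, 4.0], [1, 1, 1, 1],
                              ["S0", "S1", "S2", "S3"])
        res = gene_screen(["G1"], matrix, clin, alpha=0.0)
        assert res.selected == []

    def test_degenerate_split_skipped(self):
        matrix = bool_matrix([[1, 1, 1], [0, 1, 0]], ["G1", "G2"], ["S0", "S1", "S2"])
        clin = clinical_frame([1.0, 2.0, 3.0], [1, 1, 1], ["S0", "S1", "S2"])
        res = gene_screen(["G1", "G2"], matrix, clin, alpha=1.0)
        row = res.table.set_index("gene_id").loc["G1"]
        assert row["reason"] == "degenerate_split"
        assert not row["kept"]

    def test_planted_gene_ranks_first(self):
        wins = 0
        for seed in range(20):
            cohort, clinical, signature = gen_survival_cohort(
                n_null=50, n_signature=1, seed=seed
            )
            genes = list(cohort.cna.index)
            matrix = build_alteration_matrix(genes, cohort.omics)
            res = gene_screen(genes, matrix, clinical, alpha=1.0, top_k=1)
            wins += res.selected[:1] == signature
        assert wins >= 18  # >= 90% of 20 seeds


class TestCombinationSearch:
    def _planted(self, seed=0):
        cohort, clinical, signature = gen_survival_cohort(seed=seed)
        genes = list(cohort.cna.index)
        matrix = build_alteration_matrix(genes, cohort.omics)
        return genes, matrix, clinical, signature

    def test_counts_all_subsets(self):
        genes, matrix, clinical, _ = self._planted()
        combos = combination_search(genes, matrix, clinical, k=3)
        assert len(combos) == 1140  # C(20, 3)

    def test_planted_triple_top_ranked(self):
        genes, matrix, clinical, signature = self._planted(seed=4)
        combos = combination_search(genes, matrix, clinical, k=3)
        top = sorted(combos.iloc[0][["gene1", "gene2", "gene3"]])
        assert top == signature

    def test_k1_reduces_to_gene_screen(self):
        genes, matrix, clinical, _ = self._planted(seed=2)
        combos = combination_search(genes, matrix, clinical, k=1)
        screen = gene_screen(genes, matrix, clinical, alpha=1.1, top_k=len(genes))
        screened_p = screen.table.set_index("gene_id")["p"]
        for _, row in combos.iterrows():
            assert row["p"] == pytest.approx(screened_p[row["gene1"]])

    def test_deterministic(self):
        genes, matrix, clinical, _ = self._planted(seed=6)
        a = combination_search(genes, matrix, clinical, k=3)
        b = combination_search(genes, matrix, clinical, k=3)
        pd.testing.assert_frame_equal(a, b)

    def test_too_few_genes_errors(self):
        genes, matrix, clinical, _ = self._planted()
        with pytest.raises(ValidationError):
            combination_search(genes[:2], matrix, clinical, k=3)
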