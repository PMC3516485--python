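import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from trknob.expression import (
    de_genes, eligible_switch_loci, fisher_exact_2x2, rpkm_from_counts, run_switch_scan,
    switch_test, tr_enrichment, unexpressed_enrichment,
)
from trknob.genotypes import GenotypeTable

from oracles import fisher_two_sided_enumeration


class TestRpkm:
    def test_direct_formula(self):
        counts = pd.DataFrame({"s1": [100]}, index=["g"])
        out = rpkm_from_counts(counts, pd.Series({"g": 1000}), pd.Series({"s1": 10**7}))
        assert out.loc["g", "s1"] == pytest.approx(10.0)

    def test_zero_count_zero_rpkm(self):
        counts = pd.DataFrame({"s1": [0]}, index=["g"])
        out = rpkm_from_counts(counts, pd.Series({"g": 500}), pd.Series({"s1": 10**6}))
        assert out.loc["g", "s1"] == 0.0

    def test_depth_invariance(self):
        counts = pd.DataFrame({"s1": [100, 40]}, index=["g1", "g2"])
        lens = pd.Series({"g1": 1000, "g2": 2000})
        a = rpkm_from_counts(counts, lens, pd.Series({"s1": 10**7}))
        b = rpkm_from_counts(counts * 2, lens, pd.Series({"s1": 2 * 10**7}))
        pd.testing.assert_frame_equal(a, b)

    def test_zero_total_is_error(self):
        with pytest.raises(ValueError):
            rpkm_from_counts(pd.DataFrame({"s1": [1]}, index=["g"]),
                             pd.Series({"g": 100}), pd.Series({"s1": 0}))


def _one_locus_table(lengths_by_isolate):
    pops = {iso: ("ory" if iso.startswith("a") else "fla") for iso in lengths_by_isolate}
    lengths = pd.DataFrame([lengths_by_isolate], index=["L1"]).astype(float)
    return GenotypeTable(lengths, pd.Series(pops))


class TestEligibleSwitchLoci:
    def test_six_two_split_is_eligible(self):
        t = _one_locus_table({f"a{i}": (240 if i < 6 else 244) for i in range(8)}
                             | {f"b{i}": 240 for i in range(2)})
        out = eligible_switch_loci(t, "popA")
        assert "L1" in out
        assert {k: len(v) for k, v in out["L1"].items()} == {240.0: 6, 244.0: 2}

    def test_seven_one_split_not_eligible(self):
        t = _one_locus_table({f"a{i}": (240 if i < 7 else 244) for i in range(8)}
                             | {f"b{i}": 240 for i in range(2)})
        assert eligible_switch_loci(t, "popA") == {}

    def test_three_classes_all_common(self):
        vals = [240] * 3 + [244] * 3 + [250] * 2
        t = _one_locus_table({f"a{i}": vals[i] for i in range(8)}
                             | {f"b{i}": 240 for i in range(2)})
        out = eligible_switch_loci(t, "popA")
        assert len(out["L1"]) == 3

    def test_rare_allele_carriers_dropped_not_merged(self):
        vals = [240] * 4 + [244] * 3 + [260]
        t = _one_locus_table({f"a{i}": vals[i] for i in range(8)}
                             | {f"b{i}": 240 for i in range(2)})
        out = eligible_switch_loci(t, "popA")
        assert 260.0 not in out["L1"]
        assert {k: len(v) for k, v in out["L1"].items()} == {240.0: 4, 244.0: 3}


class TestSwitchTest:
    def test_null_case_two_classes(self):
        r = switch_test({240: [10, 11, 12, 13], 244: [10, 11, 12, 13]})
        assert r.p == pytest.approx(1.0)
        assert r.test == "t_test"

    def test_pooled_t_against_hand_computation(self):
        a, b = [10, 11, 12, 13], [20, 21, 22, 23]
        r = switch_test({1: a, 2: b})
        sp2 = (3 * np.var(a, ddof=1) + 3 * np.var(b, ddof=1)) / 6
        t_expected = (np.mean(a) - np.mean(b)) / math.sqrt(sp2 * (1 / 4 + 1 / 4))
        p_expected = 2 * stats.t.sf(abs(t_expected), 6)
        assert r.statistic == pytest.approx(t_expected)
        assert r.p == pytest.approx(p_expected)

    def test_three_equal_mean_classes_anova(self):
        r = switch_test({1: [5, 6, 7], 2: [5, 6, 7], 3: [5, 6, 7]})
        assert r.test == "anova"
        assert r.statistic == pytest.approx(0.0)

    def test_two_class_anova_equals_t_squared(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(0, 1, 5), rng.normal(1, 1, 6)
        t_res = switch_test({1: a, 2: b})
        F, p = stats.f_oneway(a, b)
        assert t_res.statistic**2 == pytest.approx(F)
        assert t_res.p == pytest.approx(p)

    def test_underpowered_class_flagged(self):
        r = switch_test({1: [5.0], 2: [6, 7, 8]})
        assert r.underpowered and r.p is None

    def test_class_count_contract(self):
        with pytest.raises(ValueError):
            switch_test({1: [1, 2]})


def test_run_switch_scan_bonferroni(bundle):
    results = run_switch_scan(bundle.genotypes, bundle.expression, bundle.locus_to_gene,
                              grouping="popA")
    tested = [r for r in results if r.p is not None]
    assert tested, "study-scale fixture should yield eligible switch loci"
    cutoff = 0.05 / len(tested)
    for r in tested:
        assert r.significant_bonferroni == (r.p < cutoff)
        assert set(len(v) for v in r.allele_classes.values()) <= {2, 3, 4, 5, 6}


class TestDeGenes:
    def _expr(self, rows, isolates=None):
        isolates = isolates or [f"a{i}" for i in range(8)] + [f"b{i}" for i in range(8)]
        return pd.DataFrame(rows, columns=isolates), pd.Series(
            {i: ("x" if i.startswith("a") else "y") for i in isolates})

    def test_constant_gene_not_de(self):
        expr, pops = self._expr([[5.0] * 16])
        out = de_genes(expr, pops)
        assert not out["de"].iloc[0]
        assert out["p"].iloc[0] == 1.0

    def test_planted_twofold_shift_detected(self):
        rng = np.random.default_rng(1)
        rows = [np.concatenate([rng.normal(100, 5, 8), rng.normal(200, 5, 8)])]
        expr, pops = self._expr(rows)
        assert de_genes(expr, pops)["de"].iloc[0]

    def test_null_calibration_near_alpha(self):
        rng = np.random.default_rng(2)
        expr, pops = self._expr(rng.normal(50, 5, size=(2000, 16)))
        frac = de_genes(expr, pops)["de"].mean()
        assert abs(frac - 0.05) < 3 * math.sqrt(0.05 * 0.95 / 2000)

    def test_population_size_contract(self):
        expr = pd.DataFrame([[1.0, 2.0, 3.0]], columns=["a0", "a1", "b0"])
        pops = pd.Series({"a0": "x", "a1": "x", "b0": "y"})
        with pytest.raises(ValueError):
            de_genes(expr, pops)


class TestFisherExact:
    def test_de_tr_counts_from_study(self):
        r = fisher_exact_2x2(12, 115, 892, 11044)
        assert round(r.p_two_sided, 2) == 0.39
        assert r.odds_ratio == pytest.approx(12 * 11044 / (115 * 892))

    def test_unexpressed_tr_counts_from_study(self):
        r = fisher_exact_2x2(1, 126, 133, 11670)
        assert round(r.p_two_sided, 2) == 1.00

    def test_empty_outcome_column(self):
        assert fisher_exact_2x2(0, 10, 0, 20).p_two_sided == 1.0

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_2x2(-1, 2, 3, 4)

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(st.integers(0, 8), st.integers(0, 8), st.integers(0, 8), st.integers(0, 8))
    def test_matches_enumeration_and_transpose_invariance(self, a, b, c, d):
        p = fisher_exact_2x2(a, b, c, d).p_two_sided
        assert p == pytest.approx(fisher_two_sided_enumeration(a, b, c, d), abs=1e-10)
        assert p == pytest.approx(fisher_exact_2x2(a, c, b, d).p_two_sided, abs=1e-12)
        assert p == pytest.approx(fisher_exact_2x2(d, c, b, a).p_two_sided, abs=1e-12)


class TestEnrichment:
    def test_study_scale_counts_reproduced(self):
        universe = {f"g{i}" for i in range(12063)}
        tr = {f"g{i}" for i in range(127)}
        de = {f"g{i}" for i in range(12)} | {f"g{i}" for i in range(127, 127 + 892)}
        r = tr_enrichment(de, tr, universe)
        assert (r.a, r.b, r.c, r.d) == (12, 115, 892, 11044)
        assert round(r.p_two_sided, 2) == 0.39

    def test_perfect_overlap_is_enriched(self):
        universe = {f"g{i}" for i in range(500)}
        tr = {f"g{i}" for i in range(30)}
        r = tr_enrichment(tr, tr, universe)
        assert r.p_two_sided < 1e-6

    def test_subset_contract(self):
        with pytest.raises(ValueError):
            tr_enrichment({"x"}, set(), {"y"})

    def test_unexpressed_enrichment_counts(self):
        isolates = [f"i{k}" for k in range(4)]
        expr = pd.DataFrame(
            np.vstack([np.zeros((2, 4)), np.full((8, 4), 3.0)]),
            index=[f"g{i}" for i in range(10)], columns=isolates)
        tr = {"g0", "g5"}
        r = unexpressed_enrichment(expr, tr)
        assert (r.a, r.b, r.c, r.d) == (1, 1, 1, 7)

    def test_no_unexpressed_genes(self):
        expr = pd.DataFrame(np.ones((5, 3)), index=[f"g{i}" for i in range(5)],
                            columns=["a", "b", "c"])
        assert unexpressed_enrichment(expr, {"g0"}).p_two_sided == 1.0
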