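import math

import numpy as np
import pandas as pd
import pytest

from trknob.genotypes import GenotypeTable
from trknob.knob import (
    FIXED_ALLELES, MODEL_ORDER, NO_EXPRESSION_DATA, UNEXPRESSED, KnobRegression,
    ModelSkipped, aicc, fit_model, run_knob_scan, select_best_model,
)

from oracles import ols_normal_equations


class TestAicc:
    def test_hand_computed_values(self):
        assert aicc(1.0, 2, 10) == pytest.approx(4 + 12 / 7, abs=1e-9)
        assert aicc(1.0, 3, 10) == pytest.approx(10.0, abs=1e-9)

    def test_strictly_increases_with_k_at_fixed_rss(self):
        vals = [aicc(2.5, k, 16) for k in (2, 3, 4)]
        assert vals == sorted(vals) and len(set(vals)) == 3

    def test_rss_floor_prevents_log_of_zero(self):
        assert math.isfinite(aicc(0.0, 2, 10))

    def test_undefined_when_denominator_vanishes(self):
        with pytest.raises(ValueError):
            aicc(1.0, 4, 5)

    def test_standard_variant_scales_log_likelihood_term(self):
        n, k, rss = 16, 2, 3.0
        assert aicc(rss, k, n, variant="standard") == pytest.approx(
            n * math.log(rss / n) + 2 * k + 2 * k * (k + 1) / (n - k - 1))


class TestFitModel:
    def test_exact_linear_fit_recovers_coefficients(self):
        x = np.array([1.0, 1.2, 1.5, 2.0, 2.5])
        y = 3 + 2 * x
        fit = fit_model(x, y, "linear")
        assert fit.coefficients == pytest.approx((3.0, 2.0), abs=1e-10)
        assert fit.R2 == 1.0
        assert fit.p == 0.0

    def test_constant_response_is_null_signal(self):
        x = np.linspace(1, 2, 8)
        y = np.full(8, 5.0)
        for model in MODEL_ORDER:
            fit = fit_model(x, y, model)
            assert (fit.R2, fit.F, fit.p) == (0.0, 0.0, 1.0)

    @pytest.mark.parametrize("model", MODEL_ORDER)
    @pytest.mark.parametrize("seed", [0, 1])
    def test_matches_normal_equations_oracle(self, model, seed):
        rng = np.random.default_rng(seed)
        x = 1 + rng.random(16) * 2
        y = rng.normal(10, 3, 16)
        fit = fit_model(x, y, model)
        transforms = {
            "linear": [x], "linear_log": [np.log(x)], "linear_sqrt": [np.sqrt(x)],
            "linear_squared": [x**2], "linear_reciprocal": [1 / x],
            "quadratic": [x, x**2], "cubic": [x, x**2, x**3],
        }[model]
        X = np.column_stack([np.ones_like(x)] + transforms)
        ref = ols_normal_equations(X, y)
        assert fit.coefficients == pytest.approx(tuple(ref["beta"]), rel=1e-8)
        assert fit.R2 == pytest.approx(ref["R2"], rel=1e-8)
        assert fit.F == pytest.approx(ref["F"], rel=1e-8)
        assert fit.p == pytest.approx(ref["p"], rel=1e-8)

    def test_cubic_rank_deficient_with_two_distinct_x(self):
        x = np.array([1.0, 1.0, 1.5, 1.5, 1.0, 1.5])
        with pytest.raises(ModelSkipped, match="rank-deficient"):
            fit_model(x, x * 2.0 + np.arange(6) * 0.01, "cubic")

    def test_small_sample_skipped(self):
        with pytest.raises(ModelSkipped, match="n=4"):
            fit_model([1, 1.2, 1.4, 1.6], [1, 2, 3, 4.0], "quadratic")

    def test_constant_x_is_caller_error(self):
        with pytest.raises(ValueError, match="constant"):
            fit_model([1.0] * 8, np.arange(8.0), "linear")


class TestSelectBestModel:
    def test_noiseless_quadratic_resolved_by_parsimony(self):
        rng = np.random.default_rng(2)
        x = 1 + np.sort(rng.choice(np.arange(1, 20), 16, replace=True)) * 0.05
        y = 4 - 3 * (x - 1.4) ** 2
        res = select_best_model(x, y)
        assert res.best_id == "quadratic"
        assert res.pattern == "optimality"

    def test_monotone_log_signal_selects_volume_family(self):
        rng = np.random.default_rng(4)
        x = np.repeat([1.0, 1.25, 1.5, 2.0], 4)
        y = 10 + 8 * np.log(x) + rng.normal(0, 0.15, 16)
        res = select_best_model(x, y)
        assert res.pattern == "volume"

    def test_rescaling_response_shifts_equal_k_models_identically(self):
        rng = np.random.default_rng(9)
        x = 1 + rng.random(16)
        y = rng.normal(50, 10, 16)
        r1 = select_best_model(x, y)
        r2 = select_best_model(x, y * 7.5)
        shift = {m: r2.fits[m].AICc - r1.fits[m].AICc for m in r1.fits}
        by_k = {}
        for m, f in r1.fits.items():
            by_k.setdefault(f.K, set()).add(round(shift[m], 9))
        for k, shifts in by_k.items():
            assert len(shifts) == 1  # same shift within an equal-K family
        # within-K ranking is preserved
        for k in by_k:
            ms = [m for m in r1.fits if r1.fits[m].K == k]
            assert sorted(ms, key=lambda m: r1.fits[m].AICc) == \
                sorted(ms, key=lambda m: r2.fits[m].AICc)

    def test_summary_reports_winner(self):
        x = np.linspace(1, 2, 12)
        res = select_best_model(x, 1 + x)
        text = res.summary()
        assert "best: linear" in text and "volume" in text

    def test_results_frame_marks_best(self):
        x = np.linspace(1, 2, 12)
        res = select_best_model(x, 1 + x)
        df = res.to_frame()
        assert df.loc[res.best_id, "best"]


class TestKnobScan:
    def _table(self, n_loci=6, seed=0):
        rng = np.random.default_rng(seed)
        isolates = [f"a{i}" for i in range(8)] + [f"b{i}" for i in range(8)]
        lengths = pd.DataFrame(
            200 + 4 * rng.integers(0, 5, size=(n_loci, 16)).astype(float),
            index=[f"L{i}" for i in range(n_loci)], columns=isolates)
        lengths.iloc[0] = 240.0  # fixed everywhere
        for j in range(1, 16):  # ensure other loci polymorphic per grouping
            lengths.iloc[1:, j] = lengths.iloc[1:, 0] + 4 * (1 + j % 3)
        pops = pd.Series({i: ("x" if i.startswith("a") else "y") for i in isolates})
        return GenotypeTable(lengths, pops)

    def test_exclusion_bookkeeping_adds_up(self):
        gt = self._table()
        rng = np.random.default_rng(1)
        genes = [f"G{i}" for i in range(6)]
        expr = pd.DataFrame(rng.normal(100, 10, size=(6, 16)),
                            index=genes, columns=gt.lengths.columns)
        expr.iloc[1, 0] = 0.0  # unexpressed in one popA isolate
        mapping = {f"L{i}": f"G{i}" for i in range(6)}
        res = run_knob_scan(gt, expr, mapping)
        summary = res.summary_dict()
        assert summary["comparisons"] == 18
        assert summary["tests_run"] + sum(summary["exclusions"].values()) == 18
        assert summary["exclusions"][FIXED_ALLELES] == 3
        assert summary["exclusions"][UNEXPRESSED] == 2  # popA + combined

    def test_missing_gene_excluded_with_reason(self):
        gt = self._table()
        rng = np.random.default_rng(1)
        genes = [f"G{i}" for i in range(5)]  # G5 absent
        expr = pd.DataFrame(rng.normal(100, 10, size=(5, 16)),
                            index=genes, columns=gt.lengths.columns)
        mapping = {f"L{i}": f"G{i}" for i in range(6)}
        res = run_knob_scan(gt, expr, mapping)
        assert res.exclusions[NO_EXPRESSION_DATA] == 3

    def test_all_zero_rule_keeps_partially_expressed_genes(self):
        gt = self._table()
        rng = np.random.default_rng(1)
        genes = [f"G{i}" for i in range(6)]
        expr = pd.DataFrame(rng.normal(100, 10, size=(6, 16)),
                            index=genes, columns=gt.lengths.columns)
        expr.iloc[1, 0] = 0.0
        mapping = {f"L{i}": f"G{i}" for i in range(6)}
        res = run_knob_scan(gt, expr, mapping, unexpressed_rule="all_zero")
        assert UNEXPRESSED not in res.exclusions

    def test_bonferroni_cutoff_uses_tests_actually_run(self):
        gt = self._table()
        rng = np.random.default_rng(1)
        genes = [f"G{i}" for i in range(6)]
        expr = pd.DataFrame(rng.normal(100, 10, size=(6, 16)),
                            index=genes, columns=gt.lengths.columns)
        mapping = {f"L{i}": f"G{i}" for i in range(6)}
        res = run_knob_scan(gt, expr, mapping)
        assert res.bonferroni_cutoff == pytest.approx(0.05 / res.tests_run)

    def test_output_frame_schema(self):
        gt = self._table()
        rng = np.random.default_rng(1)
        expr = pd.DataFrame(rng.normal(100, 10, size=(6, 16)),
                            index=[f"G{i}" for i in range(6)], columns=gt.lengths.columns)
        res = run_knob_scan(gt, expr, {f"L{i}": f"G{i}" for i in range(6)})
        df = res.to_frame()
        assert set(df.columns) >= {"locus_id", "gene_id", "grouping", "best_model",
                                   "p", "AICc", "pattern", "excluded_reason"}
        assert len(df) == 18


def test_knob_regression_from_dataframe_drops_missing():
    df = pd.DataFrame({"nal": [1.0, 1.1, np.nan, 1.3, 1.5, 1.2, 1.4, 1.6],
                       "rpkm": [5, 6, 7, np.nan, 9, 8, 9, 10.0]})
    model = KnobRegression.from_dataframe(df)
    assert len(model.x) == 6
    res = model.fit()
    assert res.best is not None
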