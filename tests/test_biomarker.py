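import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mirpipe.biomarker import (
    cohort_summary,
    combined_roc,
    derive_covariates,
    is_smoker,
    lifetime_alcohol_grams,
    multivariable_fit,
    pack_years,
    pooled_mean,
    pooled_percent,
    roc_auc,
    univariate_fits,
)


def brute_force_auc(values, labels):
    """Pair-counting oracle: P(pos > neg) with ties as one half."""
    pos = [v for v, y in zip(values, labels) if y == 1]
    neg = [v for v, y in zip(values, labels) if y == 0]
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0
               for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestRocAuc:
    def test_perfect_separation(self):
        curve = roc_auc([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1])
        assert curve.auc == 1.0

    def test_all_ties(self):
        curve = roc_auc([5, 5, 5, 5], [0, 1, 0, 1])
        assert curve.auc == 0.5

    def test_worked_example(self):
        curve = roc_auc([3, 5, 7, 1, 2, 6], [1, 1, 1, 0, 0, 0])
        assert curve.auc == pytest.approx(7 / 9)

    def test_one_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([1, 2, 3], [1, 1, 1])

    @given(st.lists(st.integers(0, 8), min_size=4, max_size=20),
           st.data())
    @settings(max_examples=50, deadline=None)
    def test_matches_pair_count_oracle(self, values, data):
        labels = data.draw(st.lists(st.integers(0, 1),
                                    min_size=len(values),
                                    max_size=len(values)))
        if len(set(labels)) < 2:
            labels[0], labels[-1] = 0, 1
        curve = roc_auc(values, labels)
        assert curve.auc == pytest.approx(brute_force_auc(values, labels))

    def test_trapezoid_equals_rank_auc(self):
        rng = np.random.default_rng(3)
        values = rng.integers(0, 20, size=60)   # heavy ties
        labels = rng.integers(0, 2, size=60)
        labels[:2] = [0, 1]
        curve = roc_auc(values, labels)
        area = np.trapezoid(curve.tpr, curve.fpr)
        assert area == pytest.approx(curve.auc, abs=1e-12)

    def test_negation_identity(self):
        rng = np.random.default_rng(4)
        values = rng.normal(size=40)
        labels = rng.integers(0, 2, size=40)
        labels[:2] = [0, 1]
        a1 = roc_auc(values, labels).auc
        a2 = roc_auc(-values, labels).auc
        assert a1 + a2 == pytest.approx(1.0)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(5)
        values = rng.normal(size=40)
        labels = rng.integers(0, 2, size=40)
        labels[:2] = [0, 1]
        assert roc_auc(values, labels).auc == pytest.approx(
            roc_auc(np.exp(values), labels).auc)


class TestCombinedRoc:
    def test_redundant_predictor_equals_single(self):
        rng = np.random.default_rng(6)
        a = rng.normal(size=60)
        y = (a + rng.normal(scale=0.5, size=60) > 0).astype(int)
        single = roc_auc(a, y).auc
        combo = combined_roc(a, a.copy(), y).auc
        assert combo == pytest.approx(single, abs=1e-9)

    def test_noise_predictor_large_n(self):
        rng = np.random.default_rng(7)
        n = 600
        a = rng.normal(size=n)
        y = (a + rng.normal(scale=1.0, size=n) > 0).astype(int)
        b = rng.normal(size=n)
        combo = combined_roc(a, b, y).auc
        assert combo == pytest.approx(roc_auc(a, y).auc, abs=0.03)

    def test_additive_signal_improves(self):
        rng = np.random.default_rng(8)
        wins = 0
        reps = 20
        for _ in range(reps):
            n = 120
            a = rng.normal(size=n)
            b = rng.normal(size=n)
            y = (a + b + rng.normal(scale=0.8, size=n) > 0).astype(int)
            best_single = max(roc_auc(a, y).auc, roc_auc(b, y).auc)
            wins += int(combined_roc(a, b, y).auc >= best_single)
        assert wins >= int(0.9 * reps)

    def test_separation_capped_not_fatal(self):
        a = np.r_[np.zeros(10), np.ones(10)]
        b = np.r_[np.zeros(10), np.ones(10)]
        y = np.r_[np.zeros(10), np.ones(10)].astype(int)
        curve = combined_roc(a, b, y)
        assert curve.auc == 1.0


class TestUnivariateFits:
    def test_closed_form_three_points(self):
        fits = univariate_fits(pd.Series([1.0, 3.0, 5.0]),
                               pd.DataFrame({"x": [0.0, 1.0, 2.0]}))
        assert fits["x"].coef["x"] == pytest.approx(2.0)
        assert fits["x"].r_squared == pytest.approx(1.0)

    def test_constant_predictor_flagged(self):
        fits = univariate_fits(pd.Series([1.0, 2.0, 3.0, 4.0]),
                               pd.DataFrame({"k": [5.0] * 4}))
        assert fits["k"].note == "constant_predictor"

    def test_null_slope_within_3_se(self):
        rng = np.random.default_rng(9)
        hits = 0
        reps = 50
        for _ in range(reps):
            x = rng.normal(size=200)
            y = pd.Series(rng.normal(size=200))
            fit = univariate_fits(y, pd.DataFrame({"x": x}))["x"]
            hits += int(abs(fit.coef["x"]) < 3 * fit.se["x"])
        assert hits >= int(0.95 * reps)

    def test_ols_sanity(self):
        rng = np.random.default_rng(10)
        x = rng.normal(size=80)
        y = pd.Series(2.0 + 0.5 * x + rng.normal(size=80))
        fit = univariate_fits(y, pd.DataFrame({"x": x}))["x"]
        resid = y - (fit.coef["const"] + fit.coef["x"] * x)
        assert abs(np.dot(resid, x)) < 1e-8
        sse = float((resid ** 2).sum())
        sst = float(((y - y.mean()) ** 2).sum())
        assert fit.r_squared == pytest.approx(1 - sse / sst)


class TestMultivariableFit:
    def test_no_qualifier_intercept_only(self):
        rng = np.random.default_rng(11)
        y = pd.Series(rng.normal(size=50))
        X = pd.DataFrame({"a": rng.normal(size=50),
                          "b": rng.normal(size=50)})
        uni = univariate_fits(y, X)
        if all(f.pvalues[n] >= 0.10 for n, f in uni.items()):
            fit = multivariable_fit(y, X, univariate=uni)
            assert fit.note == "no_predictor_qualified"
            assert fit.predictors == []

    def test_single_qualifier_equals_univariate(self):
        rng = np.random.default_rng(12)
        x = rng.normal(size=60)
        y = pd.Series(1.0 + 2.0 * x + rng.normal(scale=0.5, size=60))
        noise = pd.Series(rng.normal(size=60))
        X = pd.DataFrame({"x": x, "noise": noise})
        uni = univariate_fits(y, X)
        if uni["noise"].pvalues["noise"] < 0.10:
            pytest.skip("noise predictor qualified by chance")
        fit = multivariable_fit(y, X, univariate=uni)
        assert fit.predictors == ["x"]
        assert fit.coef["x"] == pytest.approx(uni["x"].coef["x"])

    def test_entry_gate_strictly_below(self):
        rng = np.random.default_rng(13)
        x = rng.normal(size=100)
        y = pd.Series(0.5 * x + rng.normal(size=100))
        X = pd.DataFrame({"x": x})
        uni = univariate_fits(y, X)
        fit = multivariable_fit(y, X, entry_p=uni["x"].pvalues["x"],
                                univariate=uni)
        assert fit.predictors == []  # p == entry_p does not qualify


class TestCovariates:
    def test_alcohol_conversion_printed_constants(self):
        assert lifetime_alcohol_grams(2, 1, 0) == pytest.approx(34.8)

    def test_pack_years_product(self):
        assert pack_years(1.0, 10.0) == 10.0

    def test_zero_consumption(self):
        assert lifetime_alcohol_grams(0, 0, 0) == 0.0
        assert pack_years(0, 0) == 0.0

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            lifetime_alcohol_grams(-1, 0, 0)
        with pytest.raises(ValueError):
            pack_years(-0.5, 2)
        with pytest.raises(ValueError):
            is_smoker(lifetime_packs=-1)

    def test_smoker_definition(self):
        assert is_smoker(lifetime_packs=20)
        assert not is_smoker(lifetime_packs=19.9)
        assert is_smoker(cigarettes_per_day=1, years_smoked=1)
        assert not is_smoker(cigarettes_per_day=1, years_smoked=0.5)

    def test_derive_covariates_frame(self):
        raw = pd.DataFrame({
            "wine_glasses": [2, 0], "beers": [1, 0], "liquor_shots": [0, 0],
            "packs_per_day": [1.0, 0.0], "years_smoked": [10.0, 0.0],
        })
        out = derive_covariates(raw)
        assert out.loc[0, "alcohol_grams"] == pytest.approx(34.8)
        assert out.loc[0, "pack_years"] == 10.0
        assert out.loc[0, "smoker"] == 1
        assert out.loc[1, "smoker"] == 0

    def test_derive_covariates_negative_rejected(self):
        raw = pd.DataFrame({"beers": [-1]})
        with pytest.raises(ValueError):
            derive_covariates(raw)


def _table1_cohort():
    """Reconstruct individual rows from the printed 2x2 sex counts."""
    rows = []
    for _ in range(24):
        rows.append({"pain": 0, "male": 1})
    for _ in range(14):
        rows.append({"pain": 0, "male": 0})
    for _ in range(24):
        rows.append({"pain": 1, "male": 1})
    for _ in range(4):
        rows.append({"pain": 1, "male": 0})
    return pd.DataFrame(rows)


class TestCohortSummary:
    def test_sex_chi2_rounds_to_004(self):
        table = _table1_cohort()
        summary = cohort_summary(table, "pain", dichotomous=["male"])
        p = summary.loc[summary["variable"] == "male", "p"].iloc[0]
        assert round(p, 2) == 0.04

    def test_identical_dichotomous_p_one(self):
        table = pd.DataFrame({
            "g": ["a"] * 10 + ["b"] * 10,
            "flag": ([1] * 5 + [0] * 5) * 2,
        })
        summary = cohort_summary(table, "g", dichotomous=["flag"])
        assert summary["p"].iloc[0] == pytest.approx(1.0)

    def test_pooled_mean_printed_example(self):
        assert round(pooled_mean([36.62, 40.11], [38, 28]), 2) == 38.10

    def test_pooled_percent(self):
        assert round(pooled_percent([24, 24], [38, 28]), 1) == 72.7

    def test_pooled_validation(self):
        with pytest.raises(ValueError):
            pooled_mean([1.0], [0])
        with pytest.raises(ValueError):
            pooled_percent([5], [4])

    def test_three_group_continuous_anova(self):
        rng = np.random.default_rng(14)
        table = pd.DataFrame({
            "g": ["a"] * 8 + ["b"] * 8 + ["c"] * 8,
            "age": rng.normal(40, 10, size=24),
        })
        summary = cohort_summary(table, "g", continuous=["age"])
        assert summary["test"].iloc[0] == "anova"
        assert 0 <= summary["p"].iloc[0] <= 1

    def test_empty_group_rejected(self):
        table = pd.DataFrame({"g": ["a"] * 5, "x": range(5)})
        with pytest.raises(ValueError):
            cohort_summary(table, "g", continuous=["x"])
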