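import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from apaswitch.protein_models import (
    _fast_fit,
    bootstrap_mirna,
    fit_base,
    fit_with_mirnas,
    residual_report,
    search_models,
)


def make_series(arr, prefix="g"):
    return pd.Series(np.asarray(arr, dtype=float),
                     index=[f"{prefix}{i}" for i in range(len(arr))])


@pytest.fixture()
def planted():
    """n=150 genes, y = 0.2*m - 2*score(miR-A) + eps(0.05), 20 null miRNAs."""
    rng = np.random.default_rng(123)
    n = 150
    m = make_series(rng.normal(0, 1, n))
    scores = pd.DataFrame(rng.uniform(-0.5, 0.5, size=(n, 21)),
                          index=m.index,
                          columns=["miR-A"] + [f"miR-N{i}" for i in range(20)])
    y = 0.2 * m - 2.0 * scores["miR-A"] + rng.normal(0, 0.05, n)
    return y, m, scores


class TestFitBase:
    def test_noiseless_recovery(self):
        m = make_series(np.linspace(-2, 2, 20))
        fit = fit_base(0.5 * m, m)
        assert fit.coefficients["logfc_mrna"] == pytest.approx(0.5, abs=1e-12)
        assert fit.r_squared == pytest.approx(1.0)

    def test_slope_matches_closed_form(self):
        rng = np.random.default_rng(1)
        m = make_series(rng.normal(size=40))
        y = make_series(rng.normal(size=40))
        fit = fit_base(y, m)
        slope = np.cov(m, y, ddof=1)[0, 1] / np.var(m, ddof=1)
        assert fit.coefficients["logfc_mrna"] == pytest.approx(slope, abs=1e-10)

    def test_constant_predictor_rejected(self):
        m = make_series(np.ones(20))
        with pytest.raises(ValueError, match="constant"):
            fit_base(m * 0, m)

    def test_min_rows_enforced(self):
        m = make_series(np.arange(5))
        with pytest.raises(ValueError, match=">= 10"):
            fit_base(m, m)

    def test_range_compression_slope_is_exponent(self):
        """Protein P = c * mRNA^b in both conditions implies a logFC
        regression slope of exactly b, with no error term."""
        rng = np.random.default_rng(9)
        b, c = 0.37, 5.0
        mrna_ct = rng.lognormal(3, 1, 50)
        mrna_in = rng.lognormal(3, 1, 50)
        logfc_m = make_series(np.log2(mrna_in / mrna_ct))
        logfc_p = make_series(np.log2((c * mrna_in ** b) / (c * mrna_ct ** b)))
        fit = fit_base(logfc_p, logfc_m)
        assert fit.coefficients["logfc_mrna"] == pytest.approx(b, abs=1e-6)


class TestFitWithMirnas:
    def test_planted_coefficient_recovery(self, planted):
        y, m, scores = planted
        fit = fit_with_mirnas(y, m, scores, ["miR-A"])
        coef = fit.coefficients["miR-A"]
        # 3-SE interval around the planted repression effect
        se = 0.05 / (np.std(scores["miR-A"]) * np.sqrt(len(y)))
        assert coef == pytest.approx(-2.0, abs=3 * se)

    def test_zero_variance_column_rejected(self, planted):
        y, m, scores = planted
        scores = scores.copy()
        scores["miR-flat"] = 0.25
        with pytest.raises(ValueError, match="zero-variance"):
            fit_with_mirnas(y, m, scores, ["miR-flat"])

    def test_collinear_pair_named(self, planted):
        y, m, scores = planted
        scores = scores.copy()
        scores["miR-copy"] = scores["miR-A"]
        with pytest.raises(ValueError, match="miR-A ~ miR-copy"):
            fit_with_mirnas(y, m, scores, ["miR-A", "miR-copy"])

    def test_nested_r2_monotone(self, planted):
        y, m, scores = planted
        base = fit_base(y, m)
        r2 = base.r_squared
        for subset in (["miR-N0"], ["miR-N0", "miR-N1"],
                       ["miR-N0", "miR-N1", "miR-A"]):
            fit = fit_with_mirnas(y, m, scores, subset)
            assert fit.r_squared >= r2 - 1e-12
            r2 = fit.r_squared

    def test_subset_size_bounds(self, planted):
        y, m, scores = planted
        with pytest.raises(ValueError):
            fit_with_mirnas(y, m, scores, [])
        with pytest.raises(ValueError):
            fit_with_mirnas(y, m, scores, list(scores.columns[:6]))

    def test_bic_matches_statsmodels_plus_variance_param(self, planted):
        y, m, scores = planted
        fit = fit_with_mirnas(y, m, scores, ["miR-A"])
        X = sm.add_constant(pd.DataFrame({"m": m, "s": scores["miR-A"]}))
        res = sm.OLS(y, X).fit()
        # statsmodels BIC does not count the error variance; ours does
        assert fit.bic == pytest.approx(res.bic + np.log(len(y)), abs=1e-8)


class TestFastFit:
    def test_matches_statsmodels(self):
        rng = np.random.default_rng(4)
        y = rng.normal(size=60)
        X = rng.normal(size=(60, 3))
        r2, bic, pvals = _fast_fit(y, X)
        res = sm.OLS(y, sm.add_constant(X)).fit()
        assert r2 == pytest.approx(res.rsquared, abs=1e-12)
        np.testing.assert_allclose(pvals, res.pvalues, atol=1e-12)


class TestSearchModels:
    def test_planted_mirna_found_among_nulls(self, planted):
        y, m, scores = planted
        ranked = search_models(y, m, scores)
        assert "miR-A" in ranked.iloc[0]["predictors"]

    def test_duplicate_column_enters_once(self, planted):
        y, m, scores = planted
        scores = scores.copy()
        scores["miR-dup"] = scores["miR-A"]
        ranked = search_models(y, m, scores)
        best = ranked.iloc[0]["predictors"]
        assert ("miR-A" in best) != ("miR-dup" in best)

    def test_two_mirna_truth_beats_base(self):
        rng = np.random.default_rng(77)
        n = 150
        m = make_series(rng.normal(0, 1, n))
        scores = pd.DataFrame(rng.uniform(-0.5, 0.5, size=(n, 10)),
                              index=m.index,
                              columns=[f"miR-{i}" for i in range(10)])
        y = 0.2 * m - 1.5 * scores["miR-0"] - 1.0 * scores["miR-1"] \
            + rng.normal(0, 0.1, n)
        ranked = search_models(y, m, scores)
        base_bic = ranked.loc[ranked["n_mirnas"] == 0, "bic"].iloc[0]
        truth = ranked[ranked["predictors"] == "logfc_mrna+miR-0+miR-1"]
        if truth.empty:
            truth = ranked[ranked["predictors"] == "logfc_mrna+miR-1+miR-0"]
        assert truth["bic"].iloc[0] < base_bic

    def test_greedy_and_exhaustive_agree_on_clear_signal(self, planted):
        y, m, scores = planted
        ex = search_models(y, m, scores, strategy="exhaustive_within_significant")
        gr = search_models(y, m, scores, strategy="greedy_forward")
        assert "miR-A" in ex.iloc[0]["predictors"]
        assert "miR-A" in gr.iloc[0]["predictors"]

    def test_no_significant_returns_univariate_only(self):
        rng = np.random.default_rng(8)
        n = 60
        m = make_series(rng.normal(0, 1, n))
        scores = pd.DataFrame(rng.uniform(-0.5, 0.5, size=(n, 5)),
                              index=m.index,
                              columns=[f"miR-{i}" for i in range(5)])
        y = 0.3 * m + rng.normal(0, 0.5, n)
        ranked = search_models(y, m, scores)
        assert ranked["n_mirnas"].max() <= 1


class TestBootstrap:
    def test_predictive_mirna_always_wins(self, planted):
        y, m, scores = planted
        boot, kw_p = bootstrap_mirna(y, m, scores, n_perm=200, seed=5)
        row = boot.set_index("mirna_id").loc["miR-A"]
        assert row["win_fraction"] == 1.0
        assert kw_p < 0.05

    def test_r2_matches_statsmodels(self, planted):
        y, m, scores = planted
        boot, _ = bootstrap_mirna(y, m, scores, n_perm=100, seed=5)
        for mirna in ("miR-A", "miR-N3"):
            X = sm.add_constant(pd.DataFrame({"m": m, "s": scores[mirna]}))
            res = sm.OLS(y, X).fit()
            got = boot.set_index("mirna_id").loc[mirna, "true_r2"]
            assert got == pytest.approx(res.rsquared, abs=1e-10)

    def test_too_few_permutations_rejected(self, planted):
        y, m, scores = planted
        with pytest.raises(ValueError):
            bootstrap_mirna(y, m, scores, n_perm=50)

    def test_seed_reproducibility(self, planted):
        y, m, scores = planted
        a, _ = bootstrap_mirna(y, m, scores, n_perm=100, seed=9)
        b, _ = bootstrap_mirna(y, m, scores, n_perm=100, seed=9)
        pd.testing.assert_frame_equal(a, b)


class TestResidualReport:
    def test_perfect_fit_zero_residuals(self):
        m = make_series(np.linspace(-2, 2, 20))
        fit = fit_base(0.5 * m, m)
        rep = residual_report(fit)
        np.testing.assert_allclose(rep["residual"], 0.0, atol=1e-12)

    def test_planted_outlier_ranked_first(self):
        rng = np.random.default_rng(2)
        m = make_series(rng.normal(0, 1, 40))
        y = 0.5 * m + rng.normal(0, 0.05, 40)
        y.iloc[7] -= 3.0  # protein suppressed 3 log2 units below prediction
        fit = fit_base(y, m)
        rep = residual_report(fit)
        assert rep.index[0] == m.index[7]
        assert rep["residual"].iloc[0] < -2

    def test_residuals_sum_to_zero(self):
        rng = np.random.default_rng(3)
        m = make_series(rng.normal(0, 1, 30))
        y = make_series(rng.normal(0, 1, 30))
        fit = fit_base(y, m)
        assert abs(fit.residuals.sum()) < 1e-9
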