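"""Imputation, OLS, BH-FDR and bootstrap layer."""

import numpy as np
import pandas as pd
import pytest

from heartscales import (behavioural_regression, bh_fdr, bootstrap_ols,
                         fit_ols, impute_iterative)
from heartscales.io import ConfigError


class TestImputation:
    def test_complete_table_returned_unchanged(self, rng):
        df = pd.DataFrame(rng.normal(size=(20, 3)), columns=list("abc"))
        out = impute_iterative(df, seed=1)
        pd.testing.assert_frame_equal(out, df)

    def test_observed_cells_bit_identical(self, rng):
        df = pd.DataFrame(rng.normal(size=(30, 3)), columns=list("abc"))
        holes = rng.random(30) < 0.2
        df.loc[holes, "c"] = np.nan
        out = impute_iterative(df, seed=2)
        assert out.loc[~holes, "c"].equals(df.loc[~holes, "c"])
        assert out["a"].equals(df["a"])
        assert not out["c"].isna().any()

    def test_linear_structure_recovered(self, rng):
        """MCAR holes in a column linearly determined by two others."""
        n = 200
        a, b = rng.normal(size=n), rng.normal(size=n)
        c = 2.0 * a - b + rng.normal(0, 0.1, n)
        df = pd.DataFrame({"a": a, "b": b, "c": c})
        holes = rng.random(n) < 0.10
        truth = df.loc[holes, "c"].copy()
        df.loc[holes, "c"] = np.nan
        out = impute_iterative(df, seed=3)
        rmse = np.sqrt(((out.loc[holes, "c"] - truth) ** 2).mean())
        assert rmse < 0.3

    def test_all_missing_column_rejected(self):
        df = pd.DataFrame({"a": [1.0, 2.0], "b": [np.nan, np.nan]})
        with pytest.raises(ConfigError):
            impute_iterative(df)


class TestFitOLS:
    def test_exact_linear_fit(self, rng):
        X = pd.DataFrame(rng.normal(size=(40, 3)), columns=list("abc"))
        y = 1.0 + 2.0 * X.a - 3.0 * X.b + 0.5 * X.c
        fit = fit_ols(y.to_numpy(), X)
        assert fit.r2 == pytest.approx(1.0)
        assert fit.params.loc["a", "coef"] == pytest.approx(2.0, abs=1e-8)

    def test_null_model_f_calibrated(self):
        hits = 0
        n_sim = 300
        for s in range(n_sim):
            rng = np.random.default_rng(s)
            X = pd.DataFrame(rng.normal(size=(62, 6)),
                             columns=list("abcdef"))
            y = rng.normal(size=62)
            hits += fit_ols(y, X).f_p < 0.05
        assert 0.02 <= hits / n_sim <= 0.09

    def test_rank_deficiency_names_collinear_columns(self, rng):
        X = pd.DataFrame({"a": rng.normal(size=30)})
        X["b"] = 2.0 * X["a"]
        with pytest.raises(ConfigError, match="a.*b|b.*a"):
            fit_ols(rng.normal(size=30), X)

    def test_fdr_family_excludes_intercept(self, rng):
        X = pd.DataFrame(rng.normal(size=(40, 3)), columns=list("abc"))
        y = rng.normal(size=40)
        fit = fit_ols(y, X)
        assert np.isnan(fit.params.loc["const", "q"])
        assert fit.params.loc[list("abc"), "q"].notna().all()


class TestBHFDR:
    def test_hand_worked_step_up_example(self):
        q = bh_fdr([0.01, 0.02, 0.03, 0.04, 0.05, 0.2])
        assert np.allclose(q, [0.06, 0.06, 0.06, 0.06, 0.06, 0.2])

    def test_single_p_unchanged_and_all_ones(self):
        assert bh_fdr([0.3])[0] == pytest.approx(0.3)
        assert np.allclose(bh_fdr([1.0, 1.0, 1.0]), 1.0)

    def test_monotone_in_p_and_bounded(self, rng):
        p = rng.random(50)
        q = bh_fdr(p)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)
        assert np.all((q >= p - 1e-12) & (q <= 1.0))

    def test_out_of_range_rejected(self):
        with pytest.raises(ConfigError):
            bh_fdr([0.5, 1.5])


class TestBootstrap:
    def test_noiseless_model_degenerate_ci(self, rng):
        X = pd.DataFrame(rng.normal(size=(50, 2)), columns=["a", "b"])
        y = 3.0 + 1.5 * X.a - 0.5 * X.b
        bt = bootstrap_ols(y, X, B=200, seed=4)
        width = bt["ci_high"] - bt["ci_low"]
        assert (width < 1e-6).all()
        assert bt.loc["a", "boot_coef"] == pytest.approx(1.5, abs=1e-9)

    def test_deterministic_given_seed(self, rng):
        X = pd.DataFrame(rng.normal(size=(40, 2)), columns=["a", "b"])
        y = X.a + rng.normal(size=40)
        b1 = bootstrap_ols(y, X, B=300, seed=9)
        b2 = bootstrap_ols(y, X, B=300, seed=9)
        pd.testing.assert_frame_equal(b1, b2)

    def test_bootstrap_se_tracks_analytic_se(self):
        """Mean bootstrap/analytic SE ratio near 1 for Gaussian designs."""
        ratios = []
        for s in range(6):
            rng = np.random.default_rng(100 + s)
            X = pd.DataFrame(rng.normal(size=(60, 2)), columns=["a", "b"])
            y = (2 + 1.5 * X.a - 0.8 * X.b
                 + rng.normal(0, 1, 60)).to_numpy()
            fit = fit_ols(y, X)
            bt = bootstrap_ols(y, X, B=2000, seed=s)
            ratios.extend((bt["boot_se"] / fit.params["se"])
                          .loc[["a", "b"]].tolist())
        assert abs(np.mean(ratios) - 1.0) < 0.15

    def test_ci_ordering_invariant(self, rng):
        X = pd.DataFrame(rng.normal(size=(40, 2)), columns=["a", "b"])
        y = X.a + rng.normal(size=40)
        bt = bootstrap_ols(y, X, B=400, seed=0)
        assert (bt["ci_low"] <= bt["boot_coef"]).all()
        assert (bt["boot_coef"] <= bt["ci_high"]).all()


class TestBehaviouralRegression:
    def _table(self, seed=0, missing_rate=0.05):
        from heartscales import CohortSpec, simulate_behavioural_table

        spec = CohortSpec(n_per_group=31, n_channels=8, seed=seed,
                          missing_rate=missing_rate,
                          behav_effects={"ifs": -3.0})
        return simulate_behavioural_table(spec)

    def test_full_fit_structure(self):
        fit = behavioural_regression(
            self._table(), "ifs",
            predictors=["diagnosis", "age", "sex", "education", "site"],
            B=200, seed=0)
        cols = {"coef", "se", "t", "p", "q", "boot_coef", "boot_se",
                "ci_low", "ci_high"}
        assert cols <= set(fit.params.columns)
        assert 0.0 <= fit.r2 <= 1.0
        assert fit.n == 62

    def test_diagnosis_effect_recovered_within_2se(self):
        hits = 0
        for s in range(25):
            fit = behavioural_regression(
                self._table(seed=200 + s), "ifs",
                predictors=["diagnosis", "age", "sex", "education", "site"],
                B=100, seed=s)
            c = fit.params.loc["diagnosis"]
            hits += abs(c["coef"] + 3.0) <= 2 * c["se"]
        assert hits >= 20  # ~95% nominal; generous Monte-Carlo slack

    def test_negative_patient_coefficient_sign_convention(self):
        fit = behavioural_regression(
            self._table(), "ifs",
            predictors=["diagnosis", "age", "sex", "education", "site"],
            B=100, seed=1)
        assert fit.params.loc["diagnosis", "coef"] < 0
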