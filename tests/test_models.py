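"""Feature assembly, LASSO-Cox fitting and survival model evaluation."""

import numpy as np
import pandas as pd
import pytest

import lesionhet as lh
from lesionhet.models import (
    FeatureTable,
    ModelFitError,
    assemble_feature_table,
    breslow_partial_loglik,
    concordance_index,
    cox_hr,
    fit_lasso_cox,
    km_logrank,
    nomogram_points,
    risk_score,
    time_dependent_roc,
)
from lesionhet.synthetic import simulate_survival

from helpers import brute_concordance, manual_km


def _sim_outcomes(lp, rate=1e-3, seed=0, censor=2200.0, dropout=6600.0):
    rng = np.random.default_rng(seed)
    outs = [simulate_survival(v, rate, censor, rng, dropout_upper=dropout) for v in lp]
    return np.array([o.time for o in outs]), np.array([o.event for o in outs])


class TestAssembleFeatureTable:
    def test_heterogeneity_has_107_columns(self, cohort84, het84, tables84):
        table = assemble_feature_table(
            tables84["clinical"], tables84["lesions"], het84, "heterogeneity"
        )
        assert table.X.shape[1] == 107

    def test_integrated_is_union_without_duplicates(self, cohort84, het84, tables84):
        conv = assemble_feature_table(tables84["clinical"], tables84["lesions"], het84, "conventional")
        integ = assemble_feature_table(tables84["clinical"], tables84["lesions"], het84, "integrated")
        assert set(integ.X.columns) == set(conv.X.columns) | set(het84.columns)
        assert integ.X.columns.is_unique

    def test_training_standardization_moments(self, cohort84, het84, tables84):
        table = assemble_feature_table(
            tables84["clinical"], tables84["lesions"], het84, "integrated"
        ).fit_standardizer(cohort84.train_ids)
        Z = table.transform(cohort84.train_ids)
        assert np.allclose(Z.mean(), 0.0, atol=1e-9)
        assert np.allclose(Z.std(ddof=0), 1.0, atol=1e-9)

    def test_test_set_uses_training_constants(self, cohort84, het84, tables84):
        table = assemble_feature_table(
            tables84["clinical"], tables84["lesions"], het84, "conventional"
        ).fit_standardizer(cohort84.train_ids)
        Z_test = table.transform(cohort84.test_ids)
        raw = table.X.loc[cohort84.test_ids]
        assert np.allclose(Z_test, (raw - table.means) / table.sds)


class TestBreslowPll:
    def test_matches_direct_enumeration(self, rng):
        lp = rng.normal(size=8)
        time = rng.uniform(1, 100, size=8)
        event = rng.integers(0, 2, size=8)
        event[0] = 1
        expected = 0.0
        for i in range(8):
            if event[i]:
                denom = np.log(np.sum(np.exp(lp[time >= time[i]])))
                expected += lp[i] - denom
        assert breslow_partial_loglik(lp, time, event) == pytest.approx(expected, rel=1e-12)


class TestFitLassoCox:
    def test_huge_penalty_zeroes_all_coefficients(self, rng):
        X = pd.DataFrame(rng.normal(size=(60, 5)), columns=list("abcde"))
        time, event = _sim_outcomes(X["a"].to_numpy(), seed=1)
        fit = fit_lasso_cox(X, time, event, seed=0, alphas=[1e6])
        assert (fit.coefficients == 0).all()
        assert risk_score(fit, X).eq(0).all()

    def test_planted_feature_selected(self, rng):
        X = pd.DataFrame(rng.normal(size=(200, 12)), columns=[f"f{i}" for i in range(12)])
        time, event = _sim_outcomes(1.2 * X["f3"].to_numpy(), seed=2)
        fit = fit_lasso_cox(X, time, event, seed=0)
        assert "f3" in fit.selected

    def test_refit_close_to_classical_cox(self, rng):
        X = pd.DataFrame({"x": rng.normal(size=250)})
        time, event = _sim_outcomes(0.8 * X["x"].to_numpy(), seed=3)
        fit = fit_lasso_cox(X, time, event, seed=0)
        assert fit.selected == ["x"]
        classical = cox_hr(X["x"], time, event)
        # the penalized estimate is shrunk toward, but close to, the MLE
        assert np.sign(fit.coefficients["x"]) == np.sign(classical.loc["x", "coef"])
        assert abs(fit.coefficients["x"] - classical.loc["x", "coef"]) < 0.3

    def test_zero_events_raises(self, rng):
        X = pd.DataFrame(rng.normal(size=(20, 3)))
        with pytest.raises(ModelFitError):
            fit_lasso_cox(X, np.ones(20), np.zeros(20, dtype=int))


class TestRiskScore:
    def _toy_fit(self):
        coef = pd.Series({"a": 0.5, "b": 0.0, "c": -1.2})
        return lh.models.CoxModelFit(
            coefficients=coef, alpha=0.1, cv_alphas=np.array([0.1]),
            cv_scores=np.array([0.0]), baseline_hazard=pd.DataFrame(),
            train_median_risk=0.0,
        )

    def test_zero_features_zero_score(self):
        fit = self._toy_fit()
        X = pd.DataFrame(0.0, index=["p1", "p2"], columns=["a", "b", "c"])
        assert risk_score(fit, X).eq(0).all()

    def test_manual_dot_product(self):
        fit = self._toy_fit()
        X = pd.DataFrame(
            {"a": [1.0, 2.0, -1.0], "b": [9.0, 9.0, 9.0], "c": [0.5, 0.0, 1.0]},
            index=["p1", "p2", "p3"],
        )
        scores = risk_score(fit, X)
        assert scores["p1"] == pytest.approx(0.5 * 1.0 - 1.2 * 0.5)
        assert scores["p2"] == pytest.approx(1.0)
        assert scores["p3"] == pytest.approx(-0.5 - 1.2)

    def test_non_selected_feature_is_ignored(self):
        fit = self._toy_fit()
        X = pd.DataFrame({"a": [1.0], "b": [0.0], "c": [2.0]}, index=["p"])
        base = risk_score(fit, X)["p"]
        X["b"] = 1e6
        assert risk_score(fit, X)["p"] == base

    def test_missing_selected_feature_raises(self):
        fit = self._toy_fit()
        with pytest.raises(KeyError):
            risk_score(fit, pd.DataFrame({"a": [1.0]}))


class TestConcordance:
    def test_perfect_and_reversed_ranking(self):
        time = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        event = np.ones(5, dtype=int)
        scores = -time  # higher risk = earlier event
        c, _ = concordance_index(scores, time, event, n_bootstrap=0)
        assert c == 1.0
        c_rev, _ = concordance_index(-scores, time, event, n_bootstrap=0)
        assert c_rev == 0.0

    def test_random_scores_near_half(self, rng):
        time, event = _sim_outcomes(np.zeros(400), seed=4)
        c, _ = concordance_index(rng.normal(size=400), time, event, n_bootstrap=0)
        assert c == pytest.approx(0.5, abs=0.06)

    def test_matches_brute_force_with_censoring(self, rng):
        scores = np.array([2.1, 0.3, 1.1, 1.1, -0.5, 0.9])
        time = np.array([10.0, 40.0, 25.0, 25.0, 60.0, 15.0])
        event = np.array([1, 0, 1, 0, 1, 1])
        c, _ = concordance_index(scores, time, event, n_bootstrap=0)
        assert c == pytest.approx(brute_concordance(scores, time, event))

    def test_antisymmetry(self, rng):
        scores = rng.normal(size=50)
        time, event = _sim_outcomes(scores, seed=5)
        c, _ = concordance_index(scores, time, event, n_bootstrap=0)
        c_neg, _ = concordance_index(-scores, time, event, n_bootstrap=0)
        assert c_neg == pytest.approx(1.0 - c, abs=1e-12)

    def test_bootstrap_ci_brackets_estimate(self, rng):
        scores = rng.normal(size=80)
        time, event = _sim_outcomes(0.8 * scores, seed=6)
        c, (lo, hi) = concordance_index(scores, time, event, n_bootstrap=200, seed=1)
        assert lo <= c <= hi
        assert 0.0 <= lo and hi <= 1.0


class TestKmLogrank:
    def test_identical_groups_null_statistic(self):
        time = np.array([5.0, 10.0, 15.0, 20.0] * 2)
        event = np.array([1, 0, 1, 1] * 2)
        scores = np.array([0.0] * 4 + [1.0] * 4)
        res = km_logrank(scores, time, event, threshold=0.5)
        assert res["statistic"] == pytest.approx(0.0, abs=1e-12)
        assert res["p_value"] == pytest.approx(1.0)

    def test_product_limit_matches_hand_calculation(self):
        time = np.array([1.0, 2.0, 3.0, 4.0, 5.0] * 2)
        event = np.array([1, 0, 1, 1, 0] * 2)
        scores = np.array([0.0] * 5 + [1.0] * 5)
        res = km_logrank(scores, time, event, threshold=0.5)
        curve = res["curves"]["high"]
        expected = manual_km(time[:5], event[:5])  # [(1, .8), (3, 8/15), (4, 4/15)]
        for t, s in expected:
            assert curve.loc[t].iloc[0] == pytest.approx(s, rel=1e-9)

    def test_no_censoring_curve_reaches_zero(self):
        time = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        event = np.ones(6, dtype=int)
        scores = np.array([0, 0, 0, 1, 1, 1.0])
        res = km_logrank(scores, time, event, threshold=0.5)
        assert res["curves"]["low"].iloc[-1, 0] == pytest.approx(0.0)
        assert res["curves"]["high"].iloc[-1, 0] == pytest.approx(0.0)

    def test_empty_group_raises(self):
        with pytest.raises(ValueError):
            km_logrank(np.ones(4), np.arange(1.0, 5.0), np.ones(4, dtype=int), threshold=5.0)


class TestTimeDependentRoc:
    def test_perfect_separation_no_censoring(self):
        time = np.linspace(100, 1000, 20)
        event = np.ones(20, dtype=int)
        scores = -time
        auc = time_dependent_roc(scores, time, event, [500.0])
        assert auc.iloc[0] == pytest.approx(1.0)

    def test_random_scores_near_half(self, rng):
        time, event = _sim_outcomes(np.zeros(500), seed=7)
        scores = rng.normal(size=500)
        auc = time_dependent_roc(scores, time, event, [365.0])
        assert auc.iloc[0] == pytest.approx(0.5, abs=0.08)

    def test_reduces_to_binary_auc_without_censoring(self, rng):
        time = rng.uniform(10, 1000, size=120)
        event = np.ones(120, dtype=int)
        scores = -0.002 * time + rng.normal(scale=0.3, size=120)
        horizon = 400.0
        auc = time_dependent_roc(scores, time, event, [horizon]).iloc[0]
        pos = scores[time <= horizon]
        neg = scores[time > horizon]
        grid = pos[:, None] - neg[None, :]
        binary_auc = (np.sum(grid > 0) + 0.5 * np.sum(grid == 0)) / grid.size
        assert auc == pytest.approx(binary_auc, abs=1e-9)

    def test_out_of_range_horizon_warns_nan(self, rng):
        time, event = _sim_outcomes(np.zeros(50), seed=8)
        with pytest.warns(UserWarning):
            auc = time_dependent_roc(rng.normal(size=50), time, event, [1e7])
        assert np.isnan(auc.iloc[0])


class TestCoxHr:
    def test_beta_recovery(self, rng):
        x = rng.normal(size=500)
        time, event = _sim_outcomes(0.5 * x, seed=9)
        res = cox_hr(pd.Series(x, name="x"), time, event)
        assert res.loc["x", "coef"] == pytest.approx(0.5, abs=0.1)
        assert res.loc["x", "hr_ci_low"] < res.loc["x", "hr"] < res.loc["x", "hr_ci_high"]

    def test_scaling_reparameterization(self, rng):
        x = rng.normal(size=200)
        time, event = _sim_outcomes(0.7 * x, seed=10)
        res1 = cox_hr(pd.Series(x, name="x"), time, event)
        res2 = cox_hr(pd.Series(2 * x, name="x"), time, event)
        assert res2.loc["x", "coef"] == pytest.approx(res1.loc["x", "coef"] / 2, rel=1e-6)

    def test_null_coverage(self, rng):
        covered = 0
        for rep in range(200):
            x = rng.normal(size=100)
            time, event = _sim_outcomes(np.zeros(100), seed=1000 + rep)
            res = cox_hr(pd.Series(x, name="x"), time, event)
            if res.loc["x", "hr_ci_low"] <= 1.0 <= res.loc["x", "hr_ci_high"]:
                covered += 1
        assert 0.90 <= covered / 200 <= 0.99


class TestEndToEnd:
    @pytest.fixture(scope="class")
    def fitted(self, cohort84, het84, tables84):
        out = cohort84.outcome_frame("pfs")
        results = {}
        for kind in ("conventional", "heterogeneity", "integrated"):
            table = assemble_feature_table(
                tables84["clinical"], tables84["lesions"], het84, kind
            ).fit_standardizer(cohort84.train_ids)
            fit = fit_lasso_cox(
                table.transform(cohort84.train_ids),
                out.time.loc[cohort84.train_ids].to_numpy(),
                out.event.loc[cohort84.train_ids].to_numpy(),
                seed=0,
            )
            results[kind] = (table, fit)
        return results, out

    def test_integrated_model_ranks_best(self, cohort84, fitted):
        """With signal planted in both blocks the integrated model should
        not be beaten by either component model (small noise allowance)."""
        results, out = fitted
        cs = {}
        for kind, (table, fit) in results.items():
            scores = risk_score(fit, table.transform(cohort84.train_ids))
            cs[kind], _ = concordance_index(
                scores, out.time.loc[cohort84.train_ids], out.event.loc[cohort84.train_ids],
                n_bootstrap=0,
            )
        assert cs["conventional"] <= cs["integrated"] + 0.02
        assert cs["heterogeneity"] <= cs["integrated"] + 0.02

    def test_no_test_leakage_in_training_artifacts(self, cohort84, het84, tables84):
        """Perturbing test-set rows must not change any training artifact."""
        out = cohort84.outcome_frame("pfs")
        clin = tables84["clinical"]
        les = tables84["lesions"]

        def train_artifacts(het):
            table = assemble_feature_table(clin, les, het, "heterogeneity").fit_standardizer(
                cohort84.train_ids
            )
            fit = fit_lasso_cox(
                table.transform(cohort84.train_ids),
                out.time.loc[cohort84.train_ids].to_numpy(),
                out.event.loc[cohort84.train_ids].to_numpy(),
                seed=0,
            )
            return table.means, table.sds, fit.alpha, fit.coefficients, fit.train_median_risk

        base = train_artifacts(het84)
        corrupted = het84.copy()
        corrupted.loc[cohort84.test_ids] *= 100.0
        alt = train_artifacts(corrupted)
        pd.testing.assert_series_equal(base[0], alt[0])
        pd.testing.assert_series_equal(base[1], alt[1])
        assert base[2] == alt[2]
        pd.testing.assert_series_equal(base[3], alt[3])
        assert base[4] == alt[4]

    def test_nomogram_points_table(self, fitted):
        results, _ = fitted
        _, fit = results["integrated"]
        points = nomogram_points(fit)
        assert points["max_points"].max() == pytest.approx(100.0)
        assert set(points.index) == set(fit.selected)
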