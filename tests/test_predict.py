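"""Statistics and model machinery: published 2x2 tables, screening,
stepwise selection, nomogram, discrimination/calibration/decision curves."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats
from scipy.special import expit

from qeegpred.predict import (apply_model, bootstrap_validate, calibration,
                              compare_groups, decision_curve,
                              default_model_pipeline, fdr_correct,
                              fit_backward_logistic, iqr_categorize,
                              nomogram_scale, roc_auc, univariable_screen, vif)


def table_to_frame(pos_a, n_a, pos_b, n_b):
    """Binary feature table reproducing printed 2x2 group counts."""
    rows = (
        [{"group": 1, "x": 1}] * pos_a + [{"group": 1, "x": 0}] * (n_a - pos_a)
        + [{"group": 0, "x": 1}] * pos_b + [{"group": 0, "x": 0}] * (n_b - pos_b)
    )
    return pd.DataFrame(rows)


class TestCompareGroups:
    @pytest.mark.parametrize("pos_a,n_a,pos_b,n_b,expected_p", [
        (30, 64, 24, 42, 0.301),   # male sex
        (17, 64, 9, 42, 0.548),    # seizure duration > 5 min
        (23, 64, 9, 42, 0.111),    # valproic acid use
    ])
    def test_published_contingency_tables_reproduced(self, pos_a, n_a, pos_b,
                                                     n_b, expected_p):
        ft = table_to_frame(pos_a, n_a, pos_b, n_b)
        res = compare_groups(ft, features=["x"], categorical=["x"])
        assert res.loc[0, "test"] == "chi2"
        assert round(float(res.loc[0, "p"]), 3) == expected_p

    def test_identical_groups_no_difference(self):
        rng = np.random.default_rng(0)
        block = pd.DataFrame({"x": rng.normal(size=30), "c": rng.integers(0, 2, 30)})
        ft = pd.concat([block.assign(group=0), block.assign(group=1)],
                       ignore_index=True)
        res = compare_groups(ft, features=["x", "c"], categorical=["c"])
        chi = res[res["feature"] == "c"].iloc[0]
        assert chi["statistic"] == pytest.approx(0.0, abs=1e-12)

    def test_normality_guides_test_choice(self):
        rng = np.random.default_rng(1)
        ft = pd.DataFrame({
            "group": np.repeat([0, 1], 60),
            "gauss": rng.normal(size=120),
            "heavy": rng.lognormal(sigma=2.0, size=120),
        })
        res = compare_groups(ft, features=["gauss", "heavy"]).set_index("feature")
        assert res.loc["gauss", "test"] == "t"
        assert res.loc["heavy", "test"] == "mannwhitney"

    def test_small_expected_counts_use_fisher(self):
        ft = table_to_frame(2, 10, 1, 10)
        res = compare_groups(ft, features=["x"], categorical=["x"])
        assert res.loc[0, "test"] == "fisher"

    def test_zero_variance_flagged(self):
        ft = pd.DataFrame({"group": [0, 0, 1, 1], "x": [1.0, 1.0, 1.0, 1.0]})
        res = compare_groups(ft, features=["x"])
        assert res.loc[0, "note"] == "zero variance"
        assert np.isnan(res.loc[0, "p"])


class TestFDR:
    def test_bh_equal_spacing_example(self):
        np.testing.assert_allclose(fdr_correct([0.01, 0.02, 0.03, 0.04]),
                                   [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert fdr_correct([0.123])[0] == pytest.approx(0.123)

    def test_adjusted_at_least_raw_and_order_preserving(self, rng):
        p = rng.uniform(0, 1, 40)
        adj = fdr_correct(p)
        assert np.all(adj >= p - 1e-15)
        assert np.all(adj <= 1.0)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-15)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            fdr_correct([0.5, 1.2])


class TestScreen:
    def test_strong_predictor_retained(self):
        kept = 0
        for rep in range(20):
            rng = np.random.default_rng(rep)
            n = 200
            x = rng.normal(size=n)
            p = expit(np.log(3.0) * x)
            ft = pd.DataFrame({
                "group": rng.binomial(1, p),
                "signal": x,
                **{f"noise{i}": rng.normal(size=n) for i in range(5)},
            })
            selected, _ = univariable_screen(ft)
            kept += "signal" in selected
        assert kept >= 19

    def test_null_features_rarely_pass(self):
        ok = 0
        for rep in range(20):
            rng = np.random.default_rng(1000 + rep)
            ft = pd.DataFrame({f"f{i}": rng.normal(size=80) for i in range(20)})
            ft["group"] = rng.integers(0, 2, 80)
            selected, _ = univariable_screen(ft)
            ok += len(selected) <= 4
        assert ok >= 16

    def test_constant_feature_excluded_with_warning(self):
        rng = np.random.default_rng(2)
        ft = pd.DataFrame({"group": rng.integers(0, 2, 50),
                           "flat": np.ones(50)})
        with pytest.warns(UserWarning):
            selected, tab = univariable_screen(ft)
        assert "flat" not in selected
        assert tab.loc[0, "note"] == "constant"


class TestIQR:
    def test_values_one_to_eight(self):
        codes, cuts = iqr_categorize(np.arange(1.0, 9.0))
        np.testing.assert_array_equal(codes, [0, 0, 1, 1, 2, 2, 3, 3])

    def test_all_equal_collapses_with_warning(self):
        with pytest.warns(UserWarning):
            codes, cuts = iqr_categorize(np.full(10, 3.0))
        assert len(np.unique(codes)) == 1

    def test_validation_value_below_training_minimum(self):
        _, cuts = iqr_categorize(np.arange(10.0, 20.0))
        codes, _ = iqr_categorize(np.array([-5.0, 100.0]), cuts)
        assert codes[0] == 0
        assert codes[1] == 3


class TestBackwardLogistic:
    def test_true_predictors_recovered(self):
        rng = np.random.default_rng(3)
        n = 2000
        X = rng.normal(size=(n, 8))
        eta = 1.0 * X[:, 0] + 1.0 * X[:, 1]
        y = rng.binomial(1, expit(eta))
        ft = pd.DataFrame(X, columns=[f"v{i}" for i in range(8)])
        ft["group"] = y
        model = fit_backward_logistic(ft, [f"v{i}" for i in range(8)])
        assert {"v0", "v1"} <= set(model.predictors)
        assert model.coefficients["v0"] == pytest.approx(1.0, abs=0.2)
        assert model.coefficients["v1"] == pytest.approx(1.0, abs=0.2)

    def test_empty_candidates_intercept_only(self):
        ft = pd.DataFrame({"group": [0, 1] * 20, "x": np.arange(40.0)})
        with pytest.warns(UserWarning):
            model = fit_backward_logistic(ft, [])
        assert model.predictors == []
        assert apply_model(model, ft)[0] == pytest.approx(0.5, abs=0.05)

    def test_noise_predictors_eliminated(self):
        rng = np.random.default_rng(4)
        n = 500
        ft = pd.DataFrame({f"n{i}": rng.normal(size=n) for i in range(5)})
        ft["group"] = rng.integers(0, 2, n)
        model = fit_backward_logistic(ft, [f"n{i}" for i in range(5)])
        assert len(model.predictors) <= 2  # chance retentions only

    def test_categorized_predictor_round_trips(self):
        rng = np.random.default_rng(5)
        n = 400
        x = rng.normal(size=n)
        y = rng.binomial(1, expit(1.5 * x))
        ft = pd.DataFrame({"group": y, "x": x})
        model = fit_backward_logistic(ft, ["x"], categorize=["x"])
        assert "x" in model.encodings
        assert len(model.encodings["x"]) == 3
        probs = apply_model(model, ft)
        assert len(np.unique(np.round(probs, 12))) <= 4  # one per quartile


class TestVIF:
    def test_orthogonal_predictors_unit_vif(self):
        rng = np.random.default_rng(6)
        q, _ = np.linalg.qr(rng.normal(size=(100, 3)))
        ft = pd.DataFrame(q, columns=["a", "b", "c"])
        out = vif(ft, ["a", "b", "c"])
        for v in out.values():
            assert v == pytest.approx(1.0, abs=1e-3)

    def test_known_correlation_closed_form(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=300)
        e = rng.normal(size=300)
        x = (x - x.mean()) / x.std()
        e = e - e.mean()
        e -= x * (x @ e) / (x @ x)        # exactly orthogonal residual
        e /= np.linalg.norm(e) / np.sqrt(len(e))
        y = 0.9 * x + np.sqrt(1 - 0.81) * e
        ft = pd.DataFrame({"x": x, "y": y})
        out = vif(ft, ["x", "y"])
        assert out["x"] == pytest.approx(1 / (1 - 0.81), rel=1e-6)

    def test_duplicate_column_infinite(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=50)
        ft = pd.DataFrame({"a": x, "b": x})
        out = vif(ft, ["a", "b"])
        assert np.isinf(out["a"])

    def test_needs_two_predictors(self):
        ft = pd.DataFrame({"a": [1.0, 2.0]})
        with pytest.raises(ValueError):
            vif(ft, ["a"])


class TestNomogram:
    @staticmethod
    def _fit(n=300, betas=(1.2, -0.6), seed=9):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(n, len(betas)))
        y = rng.binomial(1, expit(X @ np.array(betas)))
        ft = pd.DataFrame(X, columns=[f"p{i}" for i in range(len(betas))])
        ft["group"] = y
        cols = list(ft.columns[:-1])
        return ft, fit_backward_logistic(ft, cols, removal_p=1.1)

    def test_round_trip_probabilities(self):
        ft, model = self._fit()
        scale = nomogram_scale(model)
        direct = apply_model(model, ft)
        via_points = np.array([
            scale.probability(scale.total_points(row))
            for _, row in ft.iterrows()
        ])
        assert np.abs(via_points - direct).max() < 0.01

    def test_largest_effect_spans_100_points(self):
        ft, model = self._fit()
        scale = nomogram_scale(model)
        spans = {
            c: abs(model.coefficients[c]
                   * (model.column_ranges[c][1] - model.column_ranges[c][0]))
            / scale.log_odds_per_point
            for c in model.coefficients
        }
        assert max(spans.values()) == pytest.approx(100.0)

    def test_two_to_one_beta_range_ratio(self):
        model_like = self._fit()[1]
        model_like.coefficients = {"a": 2.0, "b": 1.0}
        model_like.column_ranges = {"a": (0.0, 1.0), "b": (0.0, 1.0)}
        scale = nomogram_scale(model_like)
        pts_a = scale.points({"a": 1.0, "b": 0.0})["a"]
        pts_b = scale.points({"a": 0.0, "b": 1.0})["b"]
        assert pts_a == pytest.approx(100.0)
        assert pts_b == pytest.approx(50.0)


class TestROC:
    def test_perfect_separation(self):
        auc, ci = roc_auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
        assert auc == 1.0
        assert ci[0] <= 1.0 <= ci[1] + 1e-12

    def test_null_scores_near_half(self, rng):
        scores = rng.normal(size=1000)
        labels = rng.integers(0, 2, 1000)
        auc, _ = roc_auc(scores, labels)
        assert auc == pytest.approx(0.5, abs=0.05)

    def test_binormal_model_hits_phi_one(self, rng):
        n = 5000
        labels = rng.integers(0, 2, n)
        scores = rng.normal(size=n) + np.sqrt(2) * labels
        auc, _ = roc_auc(scores, labels)
        assert auc == pytest.approx(scipy.stats.norm.cdf(1.0), abs=0.02)

    def test_matches_brute_force_pair_counting(self, rng):
        scores = rng.normal(size=60).round(1)  # force ties
        labels = rng.integers(0, 2, 60)
        auc, _ = roc_auc(scores, labels)
        pos = scores[labels == 1]
        neg = scores[labels == 0]
        wins = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
        assert auc == pytest.approx(wins / (len(pos) * len(neg)))

    def test_one_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.9], [1, 1])

    def test_bootstrap_ci_contains_point(self, rng):
        scores = rng.normal(size=200) + rng.integers(0, 2, 200)
        labels = (scores > 0.5).astype(int) ^ (rng.random(200) < 0.2)
        auc, ci = roc_auc(scores, labels, ci_method="bootstrap", n_boot=200, seed=0)
        assert ci[0] <= auc <= ci[1]


class TestCalibration:
    def test_df_is_bins_minus_two(self, rng):
        p = rng.uniform(0.05, 0.95, 500)
        y = rng.binomial(1, p)
        _, _, _, df = calibration(p, y, n_bins=10)
        assert df == 8

    def test_well_specified_probabilities_fit(self):
        good = 0
        for rep in range(10):
            rng = np.random.default_rng(rep)
            p = rng.uniform(0.05, 0.95, 5000)
            y = rng.binomial(1, p)
            _, _, hp, _ = calibration(p, y)
            good += hp > 0.05
        assert good >= 8

    def test_miscalibrated_probabilities_rejected(self):
        bad = 0
        for rep in range(10):
            rng = np.random.default_rng(50 + rep)
            p = rng.uniform(0.05, 0.95, 5000)
            y = rng.binomial(1, p)
            _, _, hp, _ = calibration(p ** 2, y)
            bad += hp < 0.05
        assert bad >= 9

    def test_probability_bounds_enforced(self):
        with pytest.raises(ValueError):
            calibration([0.0, 0.5], [0, 1])


class TestDecisionCurve:
    def test_identities(self, rng):
        p = rng.uniform(0.01, 0.99, 400)
        y = rng.binomial(1, p)
        prev = y.mean()
        dca = decision_curve(p, y, thresholds=np.array([0.01, prev, 0.5]))
        assert dca["nb_none"].eq(0).all()
        at_prev = dca.loc[np.isclose(dca["threshold"], prev), "nb_all"].iloc[0]
        assert at_prev == pytest.approx(0.0, abs=1e-12)
        assert dca.loc[0, "nb_all"] == pytest.approx(prev, abs=0.01)

    def test_perfect_predictor_net_benefit_is_prevalence(self):
        y = np.array([0] * 70 + [1] * 30)
        p = np.where(y == 1, 0.999, 0.001)
        dca = decision_curve(p, y, thresholds=np.arange(0.05, 0.95, 0.05))
        np.testing.assert_allclose(dca["nb_model"], 0.3, atol=1e-12)

    def test_threshold_bounds(self):
        with pytest.raises(ValueError):
            decision_curve([0.5], [1], thresholds=np.array([1.0]))


class TestBootstrapValidation:
    @staticmethod
    def _null_table(seed, n=100, k=8):
        rng = np.random.default_rng(seed)
        ft = pd.DataFrame({f"f{i}": rng.normal(size=n) for i in range(k)})
        ft["group"] = rng.integers(0, 2, n)
        return ft

    def test_deterministic_under_seed(self):
        ft = self._null_table(0)
        pipe = default_model_pipeline([c for c in ft.columns if c != "group"])
        a = bootstrap_validate(ft, pipe, B=25, seed=3)
        b = bootstrap_validate(ft, pipe, B=25, seed=3)
        assert a["auc_corrected"] == b["auc_corrected"]

    def test_optimism_moves_corrected_toward_chance(self):
        """On null data where selection found something, the corrected AUC
        sits closer to 0.5 than the apparent AUC."""
        ft = self._null_table(1)
        pipe = default_model_pipeline([c for c in ft.columns if c != "group"],
                                      keep_threshold=0.5, removal_p=0.2,
                                      max_candidates=8)
        out = bootstrap_validate(ft, pipe, B=100, seed=0)
        assert out["auc_apparent"] > 0.55
        assert abs(out["auc_corrected"] - 0.5) < abs(out["auc_apparent"] - 0.5)

    def test_corrected_not_above_apparent_with_signal(self):
        rng = np.random.default_rng(2)
        n = 150
        x = rng.normal(size=n)
        ft = pd.DataFrame({"x": x, "noise": rng.normal(size=n),
                           "group": rng.binomial(1, expit(2 * x))})
        pipe = default_model_pipeline(["x", "noise"])
        out = bootstrap_validate(ft, pipe, B=60, seed=1)
        assert out["auc_corrected"] <= out["auc_apparent"] + 1e-9


class TestApplyModel:
    def test_reference_subject_gets_intercept_probability(self):
        ft, model = TestNomogram._fit()
        zero = pd.DataFrame({c: [0.0] for c in model.predictors})
        assert apply_model(model, zero)[0] == pytest.approx(
            expit(model.intercept)
        )

    def test_training_probabilities_consistent(self):
        rng = np.random.default_rng(11)
        x = rng.normal(size=200)
        ft = pd.DataFrame({"x": x, "group": rng.binomial(1, expit(x))})
        model = fit_backward_logistic(ft, ["x"], removal_p=1.1)
        import statsmodels.api as sm

        ref = sm.Logit(ft["group"], sm.add_constant(ft[["x"]])).fit(disp=0)
        np.testing.assert_allclose(apply_model(model, ft), ref.predict(),
                                   atol=1e-6)

    def test_missing_column_error_lists_names(self):
        _, model = TestNomogram._fit()
        with pytest.raises(KeyError, match="p0"):
            apply_model(model, pd.DataFrame({"other": [1.0]}))
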