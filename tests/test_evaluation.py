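import numpy as np
import pandas as pd
import pytest
from scipy.special import expit
from sklearn.metrics import roc_auc_score, roc_curve

from pedtriage import (
    EvalConfig,
    auroc,
    bootstrap_metric_ci,
    calibration_curve,
    cross_validated_predictions,
)
from pedtriage.errors import ConfigError, DataError
from pedtriage.evaluation import holdout_auroc, threshold_metrics
from pedtriage.preprocess import OUTCOME_COL


def brute_force_auroc(risks, y):
    """Oracle: average over all positive-negative pairs, ties counted 1/2."""
    risks, y = np.asarray(risks), np.asarray(y)
    pos, neg = risks[y == 1], risks[y == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestAuroc:
    def test_four_point_worked_example(self):
        risks = [0.1, 0.4, 0.35, 0.8]
        y = [0, 0, 1, 1]
        assert auroc(risks, y) == pytest.approx(brute_force_auroc(risks, y))
        assert auroc(risks, y) == 0.75

    def test_all_ties_is_half(self):
        assert auroc([0.3] * 10, [0, 1] * 5) == 0.5

    def test_perfect_ranking_is_one(self):
        y = np.array([0, 1, 0, 1, 1])
        assert auroc(y.astype(float), y) == 1.0

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_with_ties(self, seed):
        rng = np.random.default_rng(seed)
        risks = rng.choice([0.1, 0.3, 0.5, 0.7], size=30)
        y = rng.integers(0, 2, 30)
        if y.min() == y.max():
            y[0] = 1 - y[0]
        assert auroc(risks, y) == pytest.approx(brute_force_auroc(risks, y))

    def test_matches_sklearn(self):
        rng = np.random.default_rng(9)
        risks = rng.random(200)
        y = rng.integers(0, 2, 200)
        assert auroc(risks, y) == pytest.approx(roc_auc_score(y, risks))

    def test_single_class_undefined(self):
        with pytest.raises(DataError):
            auroc([0.1, 0.2], [1, 1])

    def test_trapezoid_on_roc_curve_equals_rank_formula(self):
        rng = np.random.default_rng(4)
        risks = rng.random(500)
        y = (rng.random(500) < expit(3 * risks - 1.5)).astype(int)
        fpr, tpr, _ = roc_curve(y, risks)
        assert np.all(np.diff(fpr) >= 0) and np.all(np.diff(tpr) >= 0)
        assert np.trapezoid(tpr, fpr) == pytest.approx(auroc(risks, y))


def logistic_cohort(n, beta, seed, intercept=-1.2):
    rng = np.random.default_rng(seed)
    x = rng.normal(size=n)
    y = (rng.random(n) < expit(intercept + beta * x)).astype(int)
    return pd.DataFrame({"x": x, OUTCOME_COL: y})


class TestCrossValidation:
    def test_every_row_predicted_once(self):
        df = logistic_cohort(500, 1.5, seed=0)
        oof = cross_validated_predictions(df, ["x"], EvalConfig(seed=1))
        assert not np.isnan(oof).any()
        assert np.all((oof > 0) & (oof < 1))

    def test_null_data_auroc_near_half(self):
        df = logistic_cohort(10000, 0.0, seed=2)
        oof = cross_validated_predictions(df, ["x"], EvalConfig(seed=3))
        assert auroc(oof, df[OUTCOME_COL]) == pytest.approx(0.5, abs=0.02)

    def test_known_effect_matches_frozen_mc_oracle(self):
        # oracle: Monte-Carlo AUROC of the true risk under
        # logit p = -1.2 + 1.5 x, x ~ N(0,1), on 1e6 draws -> 0.8157
        df = logistic_cohort(8000, 1.5, seed=5)
        oof = cross_validated_predictions(df, ["x"], EvalConfig(seed=6))
        assert auroc(oof, df[OUTCOME_COL]) == pytest.approx(0.8157, abs=0.02)

    def test_separable_data_gives_auroc_one(self):
        rng = np.random.default_rng(7)
        y = rng.integers(0, 2, 400)
        df = pd.DataFrame({"x": y + 0.01 * rng.random(400), OUTCOME_COL: y})
        oof = cross_validated_predictions(df, ["x"], EvalConfig(seed=0))
        assert auroc(oof, y) == 1.0

    def test_tiny_cohort_errors(self):
        df = logistic_cohort(25, 1.0, seed=1)
        with pytest.raises(DataError, match="larger"):
            cross_validated_predictions(df, ["x"], EvalConfig(n_folds=10))

    def test_oof_optimism_nonnegative_on_average(self, prepped_5000):
        import statsmodels.api as sm

        preds = ["sqrt_age", "temperature_c", "vs_spo2", "parent_concern", "pallor"]
        y = prepped_5000[OUTCOME_COL].to_numpy(dtype=float)
        X = sm.add_constant(prepped_5000[preds].to_numpy(dtype=float))
        apparent = auroc(sm.Logit(y, X).fit(disp=0).predict(X), y)
        oof = cross_validated_predictions(prepped_5000, preds, EvalConfig(seed=8))
        assert auroc(oof, y) <= apparent + 0.02

    def test_holdout_mode_runs(self):
        df = logistic_cohort(1000, 1.5, seed=10)
        out = holdout_auroc(df, ["x"], EvalConfig(seed=1), n_repeats=3)
        assert 0.6 < out["mean_auroc"] < 1.0 and len(out["per_repeat"]) == 3


class TestThresholdMetrics:
    def test_likelihood_ratio_identities(self):
        rng = np.random.default_rng(11)
        risks = rng.random(300)
        y = (rng.random(300) < risks).astype(int)
        m = threshold_metrics(risks, y, 0.4)
        assert m["lr_pos"] == pytest.approx(m["sensitivity"] / (1 - m["specificity"]))
        assert m["lr_neg"] == pytest.approx((1 - m["sensitivity"]) / m["specificity"])

    def test_counts_partition(self):
        rng = np.random.default_rng(12)
        risks, y = rng.random(100), rng.integers(0, 2, 100)
        m = threshold_metrics(risks, y, 0.5)
        assert m["tp"] + m["fp"] + m["fn"] + m["tn"] == 100


class TestBootstrapCI:
    def test_point_is_plug_in(self):
        rng = np.random.default_rng(0)
        risks = rng.random(200)
        y = (rng.random(200) < risks).astype(int)
        out = bootstrap_metric_ci(risks, y, "sensitivity", 0.5, 200, seed=1)
        assert out["point"] == threshold_metrics(risks, y, 0.5)["sensitivity"]

    def test_perfect_separation_collapses_ci(self):
        y = np.array([0] * 50 + [1] * 50)
        risks = y.astype(float)
        out = bootstrap_metric_ci(risks, y, "sensitivity", 0.5, 200, seed=2)
        assert (out["low"], out["high"]) == (1.0, 1.0)

    def test_se_stable_in_replicate_count(self):
        rng = np.random.default_rng(3)
        risks = rng.random(500)
        y = (rng.random(500) < risks).astype(int)
        se1 = bootstrap_metric_ci(risks, y, "specificity", 0.5, 2000, seed=4)["se"]
        se2 = bootstrap_metric_ci(risks, y, "specificity", 0.5, 4000, seed=5)["se"]
        assert abs(se1 - se2) / se1 < 0.15

    def test_small_b_rejected(self):
        with pytest.raises(ConfigError):
            bootstrap_metric_ci([0.1, 0.9], [0, 1], "sensitivity", 0.5, 50)


class TestCalibration:
    def test_constant_risk_single_bin(self):
        y = np.array([0, 1] * 50)
        cal = calibration_curve(np.full(100, 0.5), y, n_bins=10)
        assert cal.n_bins_effective == 1
        assert cal.bins["observed"].iloc[0] == pytest.approx(0.5)

    def test_anticalibrated_slope_negative(self):
        rng = np.random.default_rng(6)
        p = rng.uniform(0.05, 0.95, 4000)
        y = (rng.random(4000) < p).astype(int)
        cal = calibration_curve(1 - p, y, n_bins=10)
        assert cal.slope < 0

    def test_true_risks_well_calibrated(self):
        rng = np.random.default_rng(7)
        p = rng.uniform(0.05, 0.95, 8000)
        y = (rng.random(8000) < p).astype(int)
        cal = calibration_curve(p, y, n_bins=10, n_bootstrap=100, seed=8)
        assert cal.slope == pytest.approx(1.0, abs=0.1)
        assert cal.intercept == pytest.approx(0.0, abs=0.15)
        assert np.allclose(cal.bins["observed"], cal.bins["bin_mid"], atol=0.08)

    def test_bad_bin_count(self):
        with pytest.raises(ConfigError):
            calibration_curve([0.1, 0.9], [0, 1], n_bins=1)
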