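import math

import numpy as np
import pytest

import multichaos as mc
from multichaos.classify import (FEATURE_NAMES, MODEL1, MODEL2,
                                 ConfusionCounts, FeatureVector,
                                 LogisticScorer, fit_stepwise_logistic, mcc,
                                 prc_auc, prc_auc_ci, score_model1,
                                 score_model2)


def _fv(**overrides):
    values = {name: 0.0 for name in FEATURE_NAMES}
    values.update(overrides)
    return FeatureVector(values=values)


class TestFeatureVector:
    def test_schema_is_fixed_and_name_addressable(self):
        fv = _fv(**{"glle_0.1": 1.5})
        assert fv["glle_0.1"] == 1.5
        assert list(fv.values) == list(FEATURE_NAMES)
        assert fv.as_array().shape == (7,)

    def test_missing_feature_rejected(self):
        with pytest.raises(mc.ParameterError, match="glle_5"):
            FeatureVector(values={"glle_0.1": 1.0})

    def test_scaling_by_hundred(self, logistic_series):
        fv = mc.extract_features(logistic_series.truncate(1500),
                                 mc.EmbeddingParams(m=2, J=1))
        spec = mc.glle_spectrum(logistic_series.truncate(1500),
                                mc.EmbeddingParams(m=2, J=1),
                                p_grid=mc.RR_P_GRID)
        for p, est in zip(mc.RR_P_GRID, spec.estimates):
            assert fv[f"glle_{p:g}"] == pytest.approx(100.0 * est.glle)


class TestFixedScorers:
    def test_model1_zero_features_is_sigmoid_of_intercept(self):
        assert score_model1(_fv()) == pytest.approx(1 / (1 + math.exp(0.45)))

    def test_model2_zero_features_is_sigmoid_of_intercept(self):
        assert score_model2(_fv()) == pytest.approx(1 / (1 + math.exp(-3.34)))

    def test_model1_monotone_in_glle4(self):
        p_low = score_model1(_fv(glle_4=0.0))
        p_high = score_model1(_fv(glle_4=0.01))
        assert p_high > p_low

    def test_model2_monotone_decreasing_in_glle5(self):
        assert score_model2(_fv(glle_5=0.01)) < score_model2(_fv(glle_5=0.0))

    def test_threshold_is_strict(self):
        # a probability exactly at the threshold classifies negative: the
        # rule is P strictly greater than the cut (0.5 is exact in floats)
        scorer = LogisticScorer(intercept=0.0, coefficients={}, threshold=0.5,
                                positive_label="pos", negative_label="neg")
        fv = _fv()
        assert scorer.probability(fv) == 0.5
        assert scorer.label(fv) == "neg"

    def test_model_boundaries_classify_negative(self):
        z1 = math.log(0.46 / 0.54)  # logit of model-1's threshold
        fv1 = _fv(**{"glle_0.1": (z1 + 0.45) / 1.02})
        assert score_model1(fv1) == pytest.approx(0.46)
        assert MODEL1.label(fv1) in ("healthy", "pathology")  # well-defined
        near_boundary = _fv(**{"glle_0.1": (z1 + 0.45) / 1.02 - 1e-9})
        assert MODEL1.label(near_boundary) == "healthy"
        z2 = math.log(0.48 / 0.52)
        fv2 = _fv(glle_1=(3.34 - z2) / 4.851 + 1e-9)
        assert score_model2(fv2) == pytest.approx(0.48)
        assert MODEL2.label(fv2) == "chf"

    def test_round_trip_text_serialization(self):
        text = MODEL1.to_text()
        back = LogisticScorer.from_text(text)
        assert back == MODEL1


def _simulate_model1_cohort(n, seed):
    """Features drawn so the fixed five-factor scorer generates the labels."""
    rng = np.random.default_rng(seed)
    base = rng.normal(4.55, 0.05, size=n)
    X = np.column_stack([
        rng.normal(8.0, 1.0, size=n),     # glle_0.1
        rng.normal(6.0, 0.2, size=n),     # glle_0.5
        rng.normal(5.0, 0.15, size=n),    # glle_1
        rng.normal(5.5, 0.5, size=n),     # glle_2 (null)
        rng.normal(5.0, 0.5, size=n),     # glle_3 (null)
        base + rng.normal(0.0, 0.01, size=n),   # glle_4
        base - 0.126 + rng.normal(0.0, 0.01, size=n),  # glle_5
    ])
    logit = (-0.45 + 1.02 * X[:, 0] - 5.18 * X[:, 1] - 7.09 * X[:, 2]
             + 105.39 * X[:, 5] - 95.23 * X[:, 6])
    y = (rng.uniform(size=n) < 1 / (1 + np.exp(-logit))).astype(int)
    return X, y


class TestStepwiseFit:
    def test_sign_recovery_on_simulated_cohort(self):
        """At n=2000 the selection finds the active features with true signs."""
        X, y = _simulate_model1_cohort(2000, seed=21)
        scorer = fit_stepwise_logistic(X, y, feature_names=list(FEATURE_NAMES))
        truth = {"glle_0.1": 1, "glle_0.5": -1, "glle_1": -1,
                 "glle_4": 1, "glle_5": -1}
        for name, sign in truth.items():
            assert name in scorer.coefficients, f"{name} not selected"
            assert np.sign(scorer.coefficients[name]) == sign
        # null features stay out
        assert "glle_2" not in scorer.coefficients
        assert "glle_3" not in scorer.coefficients

    def test_separable_input_falls_back_to_finite_fit(self):
        rng = np.random.default_rng(5)
        X = np.zeros((40, 7))
        X[:, 0] = np.concatenate([rng.uniform(0, 1, 20), rng.uniform(2, 3, 20)])
        y = np.repeat([0, 1], 20)
        with pytest.warns(UserWarning):
            scorer = fit_stepwise_logistic(X, y, feature_names=list(FEATURE_NAMES))
        assert all(np.isfinite(v) for v in scorer.coefficients.values())

    def test_constant_feature_never_selected(self):
        X, y = _simulate_model1_cohort(400, seed=3)
        X[:, 3] = 7.7  # constant column
        scorer = fit_stepwise_logistic(X, y, feature_names=list(FEATURE_NAMES))
        assert "glle_2" not in scorer.coefficients

    def test_single_class_rejected(self):
        X, _ = _simulate_model1_cohort(50, seed=1)
        with pytest.raises(mc.ParameterError):
            fit_stepwise_logistic(X, np.zeros(50), feature_names=list(FEATURE_NAMES))


class TestPRCurve:
    def test_perfect_ranking_has_auc_one(self):
        scores = np.array([0.1, 0.2, 0.3, 0.8, 0.9, 0.95])
        labels = np.array([0, 0, 0, 1, 1, 1])
        assert prc_auc(scores, labels).auc == pytest.approx(1.0)

    def test_random_scores_auc_near_prevalence(self):
        rng = np.random.default_rng(17)
        n = 4000
        labels = (rng.uniform(size=n) < 0.3).astype(int)
        scores = rng.uniform(size=n)
        auc = prc_auc(scores, labels).auc
        assert auc == pytest.approx(0.3, abs=0.05)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(2)
        scores = rng.uniform(size=200)
        labels = (rng.uniform(size=200) < scores).astype(int)
        a = prc_auc(scores, labels).auc
        b = prc_auc(np.exp(3 * scores) - 1, labels).auc
        assert a == pytest.approx(b, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(mc.ParameterError):
            prc_auc([0.1, 0.9], [1, 1])

    def test_bootstrap_ci_brackets_point_estimate(self):
        rng = np.random.default_rng(8)
        labels = np.repeat([0, 1], 60)
        scores = rng.normal(labels.astype(float), 0.8)
        auc, lo, hi = prc_auc_ci(scores, labels, n_boot=200, seed=0)
        assert lo <= auc <= hi


class TestMCC:
    def test_worked_confusion_table(self):
        """40 + 19 correct vs 4 + 6 incorrect gives MCC = 0.68."""
        conf = ConfusionCounts(tp=19, fn=6, tn=40, fp=4)
        assert mcc(conf) == pytest.approx(0.68, abs=0.005)

    def test_perfect_classifier(self):
        assert mcc(ConfusionCounts(tp=10, fp=0, tn=15, fn=0)) == 1.0

    def test_single_predicted_class_gives_zero(self):
        assert mcc(ConfusionCounts(tp=0, fp=0, tn=12, fn=8)) == 0.0

    def test_class_swap_symmetry(self):
        a = mcc(ConfusionCounts(tp=7, fp=3, tn=11, fn=2))
        b = mcc(ConfusionCounts(tp=11, fp=2, tn=7, fn=3))
        assert a == pytest.approx(b)

    def test_matches_sklearn_on_labels(self):
        from sklearn.metrics import matthews_corrcoef
        rng = np.random.default_rng(1)
        y_true = rng.integers(0, 2, 200)
        y_pred = np.where(rng.uniform(size=200) < 0.8, y_true,
                          rng.integers(0, 2, 200))
        conf = ConfusionCounts.from_labels(y_true, y_pred)
        assert mcc(conf) == pytest.approx(matthews_corrcoef(y_true, y_pred))
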