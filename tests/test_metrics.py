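import numpy as np
import pandas as pd
import pytest
from scipy.stats import rankdata

import sparsekernels.metrics as m


class TestRegressionMetrics:
    def test_perfect_prediction_zeroes_everything(self):
        y = np.array([1.0, 2.0, 3.0])
        assert m.mse(y, y) == m.rmse(y, y) == m.mae(y, y) == m.maape(y, y) == 0.0

    def test_direct_evaluation(self):
        y, yhat = [1.0, 2.0], [2.0, 2.0]
        assert np.isclose(m.mse(y, yhat), 0.5)
        assert np.isclose(m.mae(y, yhat), 0.5)
        assert np.isclose(m.maape(y, yhat), np.pi / 8)

    def test_maape_zero_observed_limit(self):
        assert np.isclose(m.maape([0.0], [5.0]), np.pi / 2)

    def test_maape_bounded(self, rng):
        y = rng.normal(size=50)
        yhat = rng.normal(size=50)
        assert 0.0 <= m.maape(y, yhat) <= np.pi / 2

    def test_length_mismatch_errors(self):
        with pytest.raises(ValueError, match="equal-length"):
            m.mse([1.0], [1.0, 2.0])

    def test_nrmse_sd_example(self):
        # rmse = sqrt(2/3), sd = 1
        assert np.isclose(m.nrmse([1.0, 2.0, 3.0], [2.0, 2.0, 2.0], type="sd"),
                          np.sqrt(2.0 / 3.0))

    def test_nrmse_mean_predictor_identity(self, rng):
        """NRMSE(sd) of the mean predictor equals sqrt((n-1)/n) under the
        sample-sd convention, for any y."""
        for n in (5, 20, 100):
            y = rng.normal(size=n)
            yhat = np.full(n, y.mean())
            assert np.isclose(m.nrmse(y, yhat, type="sd"), np.sqrt((n - 1) / n))

    @pytest.mark.parametrize("type", ["sd", "mean", "range", "iqr"])
    def test_nrmse_zero_for_perfect(self, type):
        y = np.array([1.0, 2.0, 4.0])
        assert m.nrmse(y, y, type=type) == 0.0

    def test_nrmse_normalizers(self):
        y = np.array([1.0, 2.0, 3.0, 6.0])
        yhat = np.array([1.0, 2.0, 3.0, 4.0])
        r = m.rmse(y, yhat)
        assert np.isclose(m.nrmse(y, yhat, "mean"), r / 3.0)
        assert np.isclose(m.nrmse(y, yhat, "range"), r / 5.0)

    def test_nrmse_zero_normalizer_errors(self):
        with pytest.raises(ValueError, match="zero"):
            m.nrmse([2.0, 2.0, 2.0], [1.0, 2.0, 3.0], type="sd")
        with pytest.raises(ValueError, match="zero"):
            m.nrmse([-1.0, 1.0], [0.0, 0.0], type="mean")

    def test_nrmse_bad_type_errors(self):
        with pytest.raises(ValueError, match="type"):
            m.nrmse([1.0, 2.0], [1.0, 2.0], type="median")


def brute_force_metrics(cm: np.ndarray):
    """Independent recomputation of classification metrics from raw
    confusion counts (macro conventions for multiclass)."""
    L = cm.shape[0]
    total = cm.sum()
    acc = np.trace(cm) / total
    sens, spec, prec, f1s = [], [], [], []
    for i in range(L):
        tp = cm[i, i]
        fn = cm[i].sum() - tp
        fp = cm[:, i].sum() - tp
        tn = total - tp - fn - fp
        se = tp / (tp + fn) if tp + fn else 0.0
        pr = tp / (tp + fp) if tp + fp else 0.0
        sens.append(se)
        spec.append(tn / (tn + fp) if tn + fp else 0.0)
        prec.append(pr)
        f1s.append(2 * pr * se / (pr + se) if pr + se else 0.0)
    po = acc
    pe = sum(cm[i].sum() * cm[:, i].sum() for i in range(L)) / total**2
    kappa = (po - pe) / (1 - pe) if pe != 1 else 0.0
    # multiclass MCC covariance form
    t = cm.sum(axis=1)
    p = cm.sum(axis=0)
    c = np.trace(cm)
    num = c * total - t @ p
    den = np.sqrt(total**2 - p @ p) * np.sqrt(total**2 - t @ t)
    mcc = num / den if den else 0.0
    if L == 2:
        return dict(accuracy=acc, sensitivity=sens[0], specificity=spec[0],
                    precision=prec[0], f1=f1s[0], kappa=kappa, mcc=mcc)
    return dict(accuracy=acc, sensitivity=np.mean(sens), specificity=np.mean(spec),
                precision=np.mean(prec), f1=np.mean(f1s), kappa=kappa, mcc=mcc)


class TestClassificationMetrics:
    def test_perfect_labels(self):
        y = ["a", "b", "a", "b"]
        assert m.accuracy(y, y) == 1.0
        assert m.kappa(y, y) == 1.0
        assert m.mcc(y, y) == 1.0

    def test_hand_count_two_by_two(self):
        # positive class "case": TP=4 FN=1 FP=2 TN=3
        obs = ["case"] * 5 + ["ctrl"] * 5
        pred = ["case"] * 4 + ["ctrl"] + ["case"] * 2 + ["ctrl"] * 3
        assert np.isclose(m.accuracy(obs, pred), 0.7)
        assert np.isclose(m.sensitivity(obs, pred), 0.8)
        assert np.isclose(m.specificity(obs, pred), 0.6)
        assert np.isclose(m.precision(obs, pred), 2.0 / 3.0)

    def test_single_class_prediction_has_chance_agreement(self):
        obs = ["a", "b"] * 10
        pred = ["a"] * 20
        assert m.kappa(obs, pred) == 0.0
        assert m.mcc(obs, pred) == 0.0

    def test_brier_perfect_and_uniform(self):
        obs = ["a", "b"]
        assert m.brier(obs, np.array([[1.0, 0.0], [0.0, 1.0]])) == 0.0
        assert np.isclose(m.brier(obs, np.full((2, 2), 0.5)), 0.5)

    def test_invalid_probabilities_error(self):
        with pytest.raises(ValueError, match="sum to 1"):
            m.brier(["a", "b"], np.array([[0.9, 0.3], [0.5, 0.5]]))
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            m.brier(["a", "b"], np.array([[1.2, -0.2], [0.5, 0.5]]))

    def test_roc_auc_equals_mann_whitney(self, rng):
        """Binary ROC-AUC equals U/(n1*n0) with midrank ties."""
        for _ in range(5):
            scores = np.round(rng.random(40), 1)  # force ties
            obs = np.where(rng.random(40) < 0.4, "yes", "no")
            if len(set(obs)) < 2:
                continue
            P = np.column_stack([1 - scores, scores])
            auc = m.roc_auc(obs, P)
            ranks = rankdata(scores)
            pos = obs == "yes"
            n1, n0 = pos.sum(), (~pos).sum()
            u = ranks[pos].sum() - n1 * (n1 + 1) / 2
            assert np.isclose(auc, u / (n1 * n0))

    @pytest.mark.parametrize("n_levels", [2, 3])
    def test_brute_force_oracle_on_random_labels(self, n_levels):
        """All label-based metrics match an independent recomputation from
        the confusion matrix on 100 seeded random label sets."""
        levels = ["a", "b", "c"][:n_levels]
        for seed in range(100):
            rng = np.random.default_rng(seed)
            obs = rng.choice(levels, size=30)
            pred = rng.choice(levels, size=30)
            if len(set(obs)) < n_levels:
                continue
            pred = np.where(np.isin(pred, list(set(obs))), pred, obs)
            cm = m.confusion_matrix(obs, pred).to_numpy().astype(float)
            ref = brute_force_metrics(cm)
            assert np.isclose(m.accuracy(obs, pred), ref["accuracy"])
            assert np.isclose(m.sensitivity(obs, pred), ref["sensitivity"])
            assert np.isclose(m.specificity(obs, pred), ref["specificity"])
            assert np.isclose(m.precision(obs, pred), ref["precision"])
            assert np.isclose(m.f1(obs, pred), ref["f1"])
            assert np.isclose(m.kappa(obs, pred), ref["kappa"])
            assert np.isclose(m.mcc(obs, pred), ref["mcc"])


class TestConfusionMatrix:
    def test_perfect_is_diagonal(self):
        cm = m.confusion_matrix(["a", "b", "b"], ["a", "b", "b"])
        assert np.array_equal(cm.to_numpy(), [[1, 0], [0, 2]])

    def test_hand_count(self):
        cm = m.confusion_matrix(["a", "a", "b"], ["a", "b", "b"])
        assert np.array_equal(cm.to_numpy(), [[1, 1], [0, 1]])

    def test_total_conserved(self, rng):
        obs = rng.choice(["x", "y", "z"], size=50)
        pred = rng.choice(["x", "y", "z"], size=50)
        pred = np.where(np.isin(pred, list(set(obs))), pred, obs)
        assert m.confusion_matrix(obs, pred).to_numpy().sum() == 50

    def test_unseen_predicted_label_errors(self):
        with pytest.raises(ValueError, match="not in the observed level set"):
            m.confusion_matrix(["a", "b"], ["a", "q"])


class TestSummaries:
    def test_numeric_summary_matches_individual_calls(self, rng):
        y = rng.normal(size=30)
        yhat = y + rng.normal(scale=0.3, size=30)
        rep = m.numeric_summary(y, yhat)
        assert rep["MSE"] == m.mse(y, yhat)
        assert rep["MAAPE"] == m.maape(y, yhat)
        assert rep["NRMSE"]["iqr"] == m.nrmse(y, yhat, "iqr")
        assert set(rep) == {"MSE", "RMSE", "NRMSE", "MAE", "MAAPE"}
        assert set(rep["NRMSE"]) == {"sd", "mean", "range", "iqr"}

    def test_categorical_summary_matches_hand_counts(self):
        obs = ["case"] * 5 + ["ctrl"] * 5
        pred = ["case"] * 4 + ["ctrl"] + ["case"] * 2 + ["ctrl"] * 3
        rep = m.categorical_summary(obs, pred)
        assert np.isclose(rep["accuracy"], 0.7)
        assert np.isclose(rep["sensitivity"], 0.8)
        assert np.isclose(rep["specificity"], 0.6)
        assert rep["confusion_matrix"].to_numpy().sum() == 10

    def test_categorical_summary_includes_probability_metrics(self, rng):
        obs = np.where(rng.random(30) < 0.5, "a", "b")
        if len(set(obs)) < 2:
            obs[0] = "a"
            obs[1] = "b"
        p = rng.random(30)
        P = pd.DataFrame({"a": p, "b": 1 - p})
        pred = np.where(p > 0.5, "a", "b")
        rep = m.categorical_summary(obs, pred, probabilities=P)
        assert {"brier", "roc_auc", "pr_auc"} <= set(rep)
        assert rep["roc_auc"] == m.roc_auc(obs, P)
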