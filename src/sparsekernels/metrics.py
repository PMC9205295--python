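"""Regression and classification metrics for prediction benchmarking.

Regression: MSE, RMSE, NRMSE (normalized by sd, mean, range or IQR), MAE
and MAAPE (mean arctangent absolute percentage error, the bounded
[0, pi/2] analogue of MAPE that tolerates near-zero observations).
Classification: accuracy, sensitivity, specificity, precision, recall, F1,
Cohen's kappa, Matthews correlation, multiclass Brier score, ROC-AUC and
PR-AUC, plus the confusion matrix.  ``numeric_summary`` and
``categorical_summary`` evaluate the whole family in one pass.

Standard metrics delegate to scikit-learn; multiclass derived metrics are
macro-averaged and AUCs are one-vs-rest macro-averaged.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn import metrics as skm

logger = logging.getLogger(__name__)

__all__ = [
    "mse", "rmse", "mae", "maape", "nrmse",
    "accuracy", "sensitivity", "specificity", "precision", "recall", "f1",
    "kappa", "mcc", "brier", "roc_auc", "pr_auc",
    "confusion_matrix", "numeric_summary", "categorical_summary",
]

NRMSE_TYPES = ("sd", "mean", "range", "iqr")


# --------------------------------------------------------------------------
# regression
# --------------------------------------------------------------------------

def _check_pair(observed, predicted):
    y = np.asarray(observed, dtype=np.float64)
    yhat = np.asarray(predicted, dtype=np.float64)
    if y.shape != yhat.shape or y.ndim != 1:
        raise ValueError(
            f"observed and predicted must be equal-length vectors "
            f"(got {y.shape} vs {yhat.shape})"
        )
    if y.size == 0:
        raise ValueError("empty input")
    if not (np.all(np.isfinite(y)) and np.all(np.isfinite(yhat))):
        raise ValueError("non-finite values in input")
    return y, yhat


def mse(observed, predicted) -> float:
    y, yhat = _check_pair(observed, predicted)
    return float(np.mean((y - yhat) ** 2))


def rmse(observed, predicted) -> float:
    return float(np.sqrt(mse(observed, predicted)))


def mae(observed, predicted) -> float:
    y, yhat = _check_pair(observed, predicted)
    return float(np.mean(np.abs(y - yhat)))


def maape(observed, predicted) -> float:
    """Mean arctangent absolute percentage error, in [0, pi/2].

    A zero observed value with a different prediction contributes the
    arctan limit pi/2; the number of such cases is logged.
    """
    y, yhat = _check_pair(observed, predicted)
    zero = y == 0
    n_undefined = int(np.sum(zero & (yhat != y)))
    if n_undefined:
        logger.info("maape: %d zero-observed case(s) contribute pi/2", n_undefined)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.abs((y - yhat) / np.where(zero, 1.0, y))
    terms = np.arctan(ratio)
    terms[zero & (yhat != y)] = np.pi / 2
    terms[zero & (yhat == y)] = 0.0
    return float(np.mean(terms))


def nrmse(observed, predicted, type: str = "sd") -> float:
    """RMSE normalized by a dispersion summary of the observed values.

    ``type``: ``sd`` (sample standard deviation, the default), ``mean``,
    ``range`` (max - min) or ``iqr``.  A zero normalizer is an error.
    """
    if type not in NRMSE_TYPES:
        raise ValueError(f"nrmse type must be one of {NRMSE_TYPES}, got {type!r}")
    y, yhat = _check_pair(observed, predicted)
    if type == "sd":
        if y.size < 2:
            raise ValueError("sd normalization needs at least 2 observations")
        norm = float(np.std(y, ddof=1))
    elif type == "mean":
        norm = float(np.mean(y))
    elif type == "range":
        norm = float(np.max(y) - np.min(y))
    else:
        q75, q25 = np.percentile(y, [75, 25])
        norm = float(q75 - q25)
    if norm == 0:
        raise ValueError(f"zero {type!r} normalizer: observed values are degenerate")
    return rmse(y, yhat) / norm


# --------------------------------------------------------------------------
# classification
# --------------------------------------------------------------------------

def _check_labels(observed, predicted):
    obs = np.asarray(observed)
    pred = np.asarray(predicted)
    if obs.shape != pred.shape or obs.ndim != 1 or obs.size == 0:
        raise ValueError("observed and predicted must be equal-length non-empty vectors")
    levels = sorted(set(obs.tolist()))
    unseen = sorted(set(pred.tolist()) - set(levels))
    if unseen:
        raise ValueError(f"predicted label(s) {unseen} not in the observed level set {levels}")
    return obs, pred, levels


def _check_probabilities(observed, probabilities):
    obs = np.asarray(observed)
    levels = sorted(set(obs.tolist()))
    if isinstance(probabilities, pd.DataFrame):
        missing = [lv for lv in levels if lv not in probabilities.columns]
        if missing:
            raise ValueError(f"probability columns missing for level(s) {missing}")
        P = probabilities[levels].to_numpy(dtype=np.float64)
    else:
        P = np.asarray(probabilities, dtype=np.float64)
        if P.ndim == 1:
            if len(levels) != 2:
                raise ValueError("1-d probabilities only valid for binary problems")
            P = np.column_stack([1.0 - P, P])
    if P.shape != (obs.size, len(levels)):
        raise ValueError(f"probabilities must be {obs.size} x {len(levels)}")
    if np.any(P < -1e-9) or np.any(P > 1 + 1e-9):
        raise ValueError("probabilities outside [0, 1]")
    sums = P.sum(axis=1)
    if np.any(np.abs(sums - 1.0) > 1e-6):
        raise ValueError("probability rows must sum to 1 within 1e-6")
    return obs, np.clip(P, 0.0, 1.0), levels


def confusion_matrix(observed, predicted) -> pd.DataFrame:
    """Confusion counts, rows = observed levels, columns = predicted."""
    obs, pred, levels = _check_labels(observed, predicted)
    counts = skm.confusion_matrix(obs, pred, labels=levels)
    return pd.DataFrame(counts, index=levels, columns=levels)


def accuracy(observed, predicted) -> float:
    obs, pred, _ = _check_labels(observed, predicted)
    return float(skm.accuracy_score(obs, pred))


def sensitivity(observed, predicted) -> float:
    """Recall of the positive class (binary, first sorted level) or the
    macro-averaged recall for multiclass problems."""
    obs, pred, levels = _check_labels(observed, predicted)
    if len(levels) == 2:
        return float(skm.recall_score(obs, pred, pos_label=levels[0]))
    return float(skm.recall_score(obs, pred, labels=levels, average="macro"))


def specificity(observed, predicted) -> float:
    """True-negative rate; macro-averaged one-vs-rest for multiclass."""
    obs, pred, levels = _check_labels(observed, predicted)
    cm = skm.confusion_matrix(obs, pred, labels=levels).astype(float)
    total = cm.sum()
    per_class = []
    for i in range(len(levels)):
        tp = cm[i, i]
        fn = cm[i].sum() - tp
        fp = cm[:, i].sum() - tp
        tn = total - tp - fn - fp
        per_class.append(tn / (tn + fp) if (tn + fp) > 0 else 0.0)
    if len(levels) == 2:
        return float(per_class[0])
    return float(np.mean(per_class))


def precision(observed, predicted) -> float:
    obs, pred, levels = _check_labels(observed, predicted)
    if len(levels) == 2:
        return float(skm.precision_score(obs, pred, pos_label=levels[0], zero_division=0))
    return float(skm.precision_score(obs, pred, labels=levels, average="macro", zero_division=0))


def recall(observed, predicted) -> float:
    return sensitivity(observed, predicted)


def f1(observed, predicted) -> float:
    obs, pred, levels = _check_labels(observed, predicted)
    if len(levels) == 2:
        return float(skm.f1_score(obs, pred, pos_label=levels[0], zero_division=0))
    return float(skm.f1_score(obs, pred, labels=levels, average="macro", zero_division=0))


def kappa(observed, predicted) -> float:
    obs, pred, _ = _check_labels(observed, predicted)
    return float(skm.cohen_kappa_score(obs, pred))


def mcc(observed, predicted) -> float:
    obs, pred, _ = _check_labels(observed, predicted)
    return float(skm.matthews_corrcoef(obs, pred))


def brier(observed, probabilities) -> float:
    """Multiclass Brier score: mean squared Euclidean distance between the
    probability vectors and the one-hot encoded truth (range [0, 2])."""
    obs, P, levels = _check_probabilities(observed, probabilities)
    onehot = np.zeros_like(P)
    idx = {lv: i for i, lv in enumerate(levels)}
    onehot[np.arange(obs.size), [idx[v] for v in obs]] = 1.0
    return float(np.mean(np.sum((P - onehot) ** 2, axis=1)))


def roc_auc(observed, probabilities) -> float:
    """ROC-AUC; one-vs-rest macro-averaged for multiclass problems.

    Binary AUC equals the Mann-Whitney U statistic divided by n1*n0 with
    midrank tie handling."""
    obs, P, levels = _check_probabilities(observed, probabilities)
    if len(levels) == 2:
        return float(skm.roc_auc_score(obs == levels[1], P[:, 1]))
    return float(skm.roc_auc_score(obs, P, labels=levels, multi_class="ovr", average="macro"))


def pr_auc(observed, probabilities) -> float:
    """Precision-recall AUC (average precision); OvR macro for multiclass."""
    obs, P, levels = _check_probabilities(observed, probabilities)
    if len(levels) == 2:
        return float(skm.average_precision_score(obs == levels[1], P[:, 1]))
    scores = [
        skm.average_precision_score(obs == lv, P[:, i]) for i, lv in enumerate(levels)
    ]
    return float(np.mean(scores))


# --------------------------------------------------------------------------
# summaries
# --------------------------------------------------------------------------

def numeric_summary(observed, predicted) -> dict:
    """All regression metrics in one pass (the 4 NRMSE variants nested)."""
    return {
        "MSE": mse(observed, predicted),
        "RMSE": rmse(observed, predicted),
        "NRMSE": {t: nrmse(observed, predicted, type=t) for t in NRMSE_TYPES},
        "MAE": mae(observed, predicted),
        "MAAPE": maape(observed, predicted),
    }


def categorical_summary(observed, predicted, probabilities=None) -> dict:
    """All classification metrics in one pass.

    Probability-based metrics (Brier, ROC-AUC, PR-AUC) are included when
    ``probabilities`` is given (columns ordered by sorted level).
    """
    report = {
        "accuracy": accuracy(observed, predicted),
        "sensitivity": sensitivity(observed, predicted),
        "specificity": specificity(observed, predicted),
        "precision": precision(observed, predicted),
        "recall": recall(observed, predicted),
        "f1": f1(observed, predicted),
        "kappa": kappa(observed, predicted),
        "mcc": mcc(observed, predicted),
        "confusion_matrix": confusion_matrix(observed, predicted),
    }
    if probabilities is not None:
        report["brier"] = brier(observed, probabilities)
        report["roc_auc"] = roc_auc(observed, probabilities)
        report["pr_auc"] = pr_auc(observed, probabilities)
    return report
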