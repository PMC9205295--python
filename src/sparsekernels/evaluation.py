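"""Outer benchmarking protocol: random partitions, per-environment and
Global mean +/- SE summaries, and model-comparison arithmetic.

The protocol mirrors standard genomic-prediction benchmarking: a number of
random 80/20 train/test partitions of the phenotype records (stratified by
environment), per-partition tuning restricted to the training rows, and
metric summaries reported per environment and Globally (metrics computed
per fold over all environments pooled, then averaged over folds, with
SE = sd over folds / sqrt(number of folds)).
"""

from __future__ import annotations

import logging
import math
import warnings

import numpy as np
import pandas as pd

from . import metrics as m
from .learners import FittedModel, Predictions, fit, infer_response_type
from .tuning import TuneConfig, make_random_partitions

logger = logging.getLogger(__name__)

REGRESSION_METRICS = ("MAAPE", "MAE", "MSE", "NRMSE", "RMSE")


def percent_outperformance(mse_reference: float, mse_better: float) -> float:
    """Relative improvement of a model over a reference, in percent.

    ``100 * (mse_reference - mse_better) / mse_reference``, truncated (not
    rounded) to 2 decimals, the convention of the published comparison
    tables.  The reference must be positive.
    """
    if mse_reference <= 0:
        raise ValueError("reference MSE must be positive")
    value = 100.0 * (mse_reference - mse_better) / mse_reference
    # guard against binary-float dust just below a 2-decimal boundary
    return math.trunc(round(value * 100, 6)) / 100


def percent_relative_excess(mse_better: float, mse_worse: float) -> float:
    """Complementary convention: excess of the worse model relative to the
    BETTER model's MSE, ``100 * (mse_worse - mse_better) / mse_better``,
    truncated to 2 decimals."""
    if mse_better <= 0:
        raise ValueError("better MSE must be positive")
    value = 100.0 * (mse_worse - mse_better) / mse_better
    return math.trunc(round(value * 100, 6)) / 100


def _model_spec(entry):
    if isinstance(entry, str):
        return {"name": entry, "overrides": None}
    spec = dict(entry)
    if "name" not in spec:
        raise ValueError("model entries must be a name or a dict with a 'name' key")
    spec.setdefault("overrides", None)
    return spec


def run_benchmark(
    pheno: pd.DataFrame,
    features,
    models,
    partitions=None,
    tune: TuneConfig | None = None,
    reps: int = 5,
    testing_proportion: float = 0.2,
    seed: int = 0,
    kernel_for: tuple = ("bayesian_gblup",),
) -> pd.DataFrame:
    """Run the outer benchmark and collect a long-format prediction table.

    Parameters
    ----------
    pheno : DataFrame with columns ``Line``, ``Env`` and one trait column.
    features : DataFrame indexed by line id.
        The design matrix rows per line (markers, a kernel square root, or
        a sparse design P).  For models in ``kernel_for`` it must instead
        be the square line kernel (index = columns = line ids).
    models : list of names or dicts ``{"name", "overrides", ...}``.
    partitions : list of (train_idx, test_idx) over phenotype rows, or
        ``None`` to draw ``reps`` random environment-stratified splits.
    tune : TuneConfig applied when overrides request tuning.

    Returns
    -------
    DataFrame with one record per (model, fold, env, line): observed and
    predicted values (class probabilities appended for class responses).
    """
    required = {"Line", "Env"}
    if not required.issubset(pheno.columns):
        raise ValueError(f"phenotype table must contain columns {sorted(required)}")
    trait_cols = [c for c in pheno.columns if c not in required]
    if len(trait_cols) != 1:
        raise ValueError("phenotype table must contain exactly one trait column")
    trait = trait_cols[0]
    pheno = pheno.reset_index(drop=True)

    missing = sorted(set(pheno["Line"]) - set(features.index))
    if missing:
        raise ValueError(f"line id(s) in phenotypes missing from features: {missing}")

    if partitions is None:
        partitions = make_random_partitions(
            len(pheno), testing_proportion=testing_proportion, reps=reps,
            seed=seed, stratify=pheno["Env"].to_numpy(),
        )

    y_all = pheno[trait].to_numpy()
    response = infer_response_type(y_all)
    lines = pheno["Line"].to_numpy()

    records = []
    for spec in map(_model_spec, models):
        name = spec["name"]
        uses_kernel = name in kernel_for
        if uses_kernel:
            if features.shape[0] != features.shape[1]:
                raise ValueError(f"model {name!r} needs a square line kernel")
            K_lines = features
            X_obs = K_lines.loc[lines, lines].to_numpy()  # observation kernel
        else:
            X_obs = features.loc[lines].to_numpy(dtype=np.float64)

        for fold_no, (train_idx, test_idx) in enumerate(partitions, start=1):
            assert np.intersect1d(train_idx, test_idx).size == 0, "leaky partition"
            if uses_kernel:
                X_train = X_obs[np.ix_(train_idx, train_idx)]
                X_test = X_obs[np.ix_(test_idx, train_idx)]
            else:
                X_train = X_obs[train_idx]
                X_test = X_obs[test_idx]
            model = fit(name, X_train, y_all[train_idx],
                        defaults_override=spec["overrides"], tune=tune,
                        seed=seed + fold_no)
            preds = model.predict(X_test)
            for j, row in enumerate(test_idx):
                rec = {
                    "model": name,
                    "fold": fold_no,
                    "env": pheno.at[row, "Env"],
                    "line": pheno.at[row, "Line"],
                    "observed": y_all[row],
                    "predicted": preds.values[j],
                }
                if preds.probabilities is not None:
                    for lv in preds.probabilities.columns:
                        rec[f"prob_{lv}"] = preds.probabilities.iloc[j][lv]
                records.append(rec)
    return pd.DataFrame.from_records(records)


def _regression_cell(obs, pred):
    out = {
        "MAAPE": m.maape(obs, pred),
        "MAE": m.mae(obs, pred),
        "MSE": m.mse(obs, pred),
        "RMSE": m.rmse(obs, pred),
    }
    if len(obs) >= 2 and np.std(obs, ddof=1) > 0:
        out["NRMSE"] = m.nrmse(obs, pred, type="sd")
    else:
        warnings.warn(
            "NRMSE skipped for a cell with fewer than 2 records or constant "
            "observations", stacklevel=3,
        )
        out["NRMSE"] = np.nan
    return out


def _classification_cell(obs, pred):
    return {
        "accuracy": m.accuracy(obs, pred),
        "kappa": m.kappa(obs, pred),
        "f1": m.f1(obs, pred),
    }


def summaries(
    preds: pd.DataFrame,
    response_type: str = "continuous",
    global_mode: str = "pooled",
) -> pd.DataFrame:
    """Per-environment and Global mean +/- SE over folds.

    Every metric is computed per (env, fold) cell; each environment row is
    the mean and SE (sd over folds / sqrt(n_folds)) of its fold values.
    ``Global`` pools all environments within each fold before computing the
    metric, then averages over folds (set ``global_mode="env_mean"`` for
    the average-of-environment-means alternative).  A single fold leaves
    the SE undefined (NaN).
    """
    if preds.empty:
        raise ValueError("empty prediction table")
    if global_mode not in ("pooled", "env_mean"):
        raise ValueError("global_mode must be 'pooled' or 'env_mean'")
    cell_fn = _regression_cell if response_type == "continuous" else _classification_cell
    models = preds["model"].unique() if "model" in preds.columns else [None]
    rows = []
    for model in models:
        sub = preds if model is None else preds[preds["model"] == model]
        folds = sorted(sub["fold"].unique())
        per_env_fold = {}          # (env, fold) -> {metric: value}
        for (env, fold), grp in sub.groupby(["env", "fold"], sort=True):
            per_env_fold[(env, fold)] = cell_fn(
                np.asarray(grp["observed"]), np.asarray(grp["predicted"])
            )
        envs = sorted(sub["env"].unique())
        metric_names = next(iter(per_env_fold.values())).keys()
        for env in envs:
            for metric in metric_names:
                vals = np.array([
                    per_env_fold[(env, f)][metric]
                    for f in folds if (env, f) in per_env_fold
                ])
                rows.append(_summary_row(model, metric, env, vals))
        for metric in metric_names:
            if global_mode == "pooled":
                vals = []
                for f in folds:
                    grp = sub[sub["fold"] == f]
                    vals.append(cell_fn(
                        np.asarray(grp["observed"]), np.asarray(grp["predicted"])
                    )[metric])
                vals = np.array(vals)
            else:
                vals = np.array([
                    np.nanmean([
                        per_env_fold[(env, f)][metric]
                        for env in envs if (env, f) in per_env_fold
                    ])
                    for f in folds
                ])
            rows.append(_summary_row(model, metric, "Global", vals))
    out = pd.DataFrame(rows)
    if models[0] is None:
        out = out.drop(columns=["model"])
    return out


def _summary_row(model, metric, env, vals):
    vals = vals[~np.isnan(vals)]
    if vals.size == 0:
        mean, se = np.nan, np.nan
    else:
        mean = float(np.mean(vals))
        se = float(np.std(vals, ddof=1) / np.sqrt(vals.size)) if vals.size > 1 else np.nan
    if vals.size <= 1:
        logger.info("SE undefined for %s/%s/%s: %d fold value(s)", model, metric, env, vals.size)
    return {"model": model, "metric": metric, "env": env, "mean": mean, "SE": se}
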