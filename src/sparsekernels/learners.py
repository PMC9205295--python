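"""Unified fit/predict interface over the supported model families.

One ``fit(model_name, X, y)`` call covers gradient-boosted machines,
penalized linear models, support vector machines, random forests, the
in-package Gibbs samplers (Bayesian ridge and GBLUP) and a basic
feed-forward network, with the response type (continuous / binary /
categorical) inferred from ``y`` and sensible genomic-prediction defaults
resolved per model.  Hyperparameter values given as lists (grid) or bound
tuples (Bayesian optimization) are tuned by nested inner-CV before the
final fit.

The delegated back-ends are scikit-learn and xgboost; the mapping from the
field's parameter names to back-end arguments is the explicit translation
table below, which is the tested surface.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.dummy import DummyClassifier, DummyRegressor
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor
from sklearn.linear_model import ElasticNet, LogisticRegression
from sklearn.metrics import accuracy_score, log_loss
from sklearn.neural_network import MLPClassifier, MLPRegressor
from sklearn.svm import SVC, SVR

from .gibbs import BayesianRidgeGibbs, MixedModelFit, fit_brr, fit_gblup  # noqa: F401
from .metrics import mse
from .tuning import TuneConfig, TuneResult, bayes_opt, grid_search

MODEL_NAMES = (
    "boosted_machine",
    "linear_model",
    "svm",
    "random_forest",
    "bayesian_brr",
    "bayesian_gblup",
    "neural_network",
    "intercept",
)

#: Default hyperparameters per model, in the field's naming convention.
#: ``linear_model.alpha`` is the elastic-net mixing parameter (1 = lasso,
#: 0 = ridge); ``penalty`` is the regularization strength.  ``svm.gamma``
#: "1/p" resolves to one over the number of design columns.
MODEL_DEFAULTS: dict[str, dict] = {
    "boosted_machine": {
        "trees_number": 500,
        "max_depth": 1,
        "node_size": 10,
        "shrinkage": 0.1,
        "sampled_records_proportion": 0.5,
    },
    "linear_model": {"alpha": 1.0, "penalty": 0.01},
    "svm": {"kernel": "linear", "degree": 3, "gamma": "1/p", "coef0": 0.0, "cost": 1.0},
    "random_forest": {
        "trees_number": 500,
        "node_size": 5,
        "node_depth": None,
        "sampled_x_vars_number": None,
    },
    "bayesian_brr": {"iterations": 1500, "burn_in": 500},
    "bayesian_gblup": {"iterations": 1500, "burn_in": 500},
    "neural_network": {
        "neurons_number": 50,
        "learning_rate": 0.001,
        "epochs_number": 500,
        "batch_size": 32,
    },
    "intercept": {},
}

#: name -> (backend argument) translation, by model.
TRANSLATION: dict[str, dict[str, str]] = {
    "boosted_machine": {
        "trees_number": "n_estimators",
        "max_depth": "max_depth",
        "node_size": "min_child_weight",
        "shrinkage": "learning_rate",
        "sampled_records_proportion": "subsample",
    },
    "linear_model": {"alpha": "l1_ratio", "penalty": "alpha"},
    "svm": {"kernel": "kernel", "degree": "degree", "gamma": "gamma",
            "coef0": "coef0", "cost": "C"},
    "random_forest": {
        "trees_number": "n_estimators",
        "node_size": "min_samples_leaf",
        "node_depth": "max_depth",
        "sampled_x_vars_number": "max_features",
    },
    "neural_network": {
        "neurons_number": "hidden_layer_sizes",
        "learning_rate": "learning_rate_init",
        "epochs_number": "max_iter",
        "batch_size": "batch_size",
    },
}


@dataclass(frozen=True)
class ResponseSpec:
    """Inferred response type: continuous, binary (2 levels) or
    categorical (> 2 levels)."""

    type: str
    levels: tuple = ()

    @property
    def is_class(self) -> bool:
        return self.type in ("binary", "categorical")


def infer_response_type(y) -> ResponseSpec:
    """Infer the model family from the response vector.

    Label-typed vectors with 2 distinct levels are binary, with more
    categorical; numeric vectors are continuous (count responses are
    deliberately treated as continuous).  A constant response is an error.
    """
    arr = np.asarray(y)
    if arr.size == 0:
        raise ValueError("empty response")
    if pd.isna(arr).any():
        raise ValueError("response contains missing values")
    distinct = pd.unique(arr)
    if distinct.size < 2:
        raise ValueError("constant response: only one distinct value")
    if np.issubdtype(arr.dtype, np.number):
        return ResponseSpec(type="continuous")
    levels = tuple(sorted(distinct.tolist()))
    return ResponseSpec(type="binary" if len(levels) == 2 else "categorical",
                        levels=levels)


@dataclass
class Predictions:
    """Prediction output: numeric values, or class labels plus per-class
    probabilities (columns ordered by sorted level, rows summing to 1)."""

    values: np.ndarray
    probabilities: pd.DataFrame | None = None

    def __len__(self) -> int:
        return len(self.values)


def _resolve_params(model_name: str, overrides: dict | None) -> dict:
    if model_name not in MODEL_NAMES:
        raise ValueError(f"unknown model {model_name!r}; expected one of {MODEL_NAMES}")
    params = dict(MODEL_DEFAULTS[model_name])
    for key, val in (overrides or {}).items():
        if key not in params and model_name != "intercept":
            raise ValueError(f"unknown hyperparameter {key!r} for model {model_name!r}")
        params[key] = val
    return params


def _build_backend(model_name, params, response: ResponseSpec, n_features, seed):
    """Instantiate the back-end estimator from translated parameters."""
    is_class = response.is_class
    if model_name == "boosted_machine":
        from xgboost import XGBClassifier, XGBRegressor

        kw = {TRANSLATION[model_name][k]: v for k, v in params.items()}
        kw.update(random_state=seed, n_jobs=1, verbosity=0)
        return XGBClassifier(**kw) if is_class else XGBRegressor(**kw)
    if model_name == "linear_model":
        if is_class:
            return LogisticRegression(
                penalty="elasticnet", solver="saga", l1_ratio=params["alpha"],
                C=1.0 / max(params["penalty"], 1e-12), max_iter=5000,
            )
        return ElasticNet(alpha=params["penalty"], l1_ratio=params["alpha"],
                          max_iter=10000)
    if model_name == "svm":
        gamma = params["gamma"]
        if gamma == "1/p":
            gamma = 1.0 / n_features
        kw = dict(kernel=params["kernel"], degree=params["degree"], gamma=gamma,
                  coef0=params["coef0"], C=params["cost"])
        if is_class:
            return SVC(probability=True, random_state=seed, **kw)
        return SVR(**kw)
    if model_name == "random_forest":
        max_features = params["sampled_x_vars_number"]
        if max_features is None:
            # mirror the common forest convention: p/3 for regression,
            # sqrt(p) for classification
            max_features = "sqrt" if is_class else max(1, n_features // 3)
        kw = dict(n_estimators=params["trees_number"],
                  min_samples_leaf=params["node_size"],
                  max_depth=params["node_depth"], max_features=max_features,
                  random_state=seed, n_jobs=1)
        return RandomForestClassifier(**kw) if is_class else RandomForestRegressor(**kw)
    if model_name == "neural_network":
        kw = dict(hidden_layer_sizes=(params["neurons_number"],),
                  learning_rate_init=params["learning_rate"],
                  max_iter=params["epochs_number"],
                  batch_size=params["batch_size"], random_state=seed)
        return MLPClassifier(**kw) if is_class else MLPRegressor(**kw)
    if model_name == "intercept":
        return DummyClassifier(strategy="prior") if is_class else DummyRegressor()
    raise AssertionError(model_name)


@dataclass
class FittedModel:
    """A fitted learner carrying its resolved hyperparameters and response
    spec; ``predict`` validates column compatibility and returns labels
    plus probabilities for class responses."""

    model_name: str
    params: dict
    response: ResponseSpec
    backend: object = None
    mixed_fit: MixedModelFit | None = None
    n_features: int = 0
    _gblup_state: dict | None = None
    tune_result: TuneResult | None = None

    def save(self, path) -> None:
        """Serialize the fitted model (resolved hyperparameters + learned
        state) to a versioned on-disk bundle."""
        import pickle

        from . import __version__

        with open(path, "wb") as fh:
            pickle.dump({"format_version": 1, "package_version": __version__,
                         "model": self}, fh)

    @staticmethod
    def load(path) -> "FittedModel":
        import pickle

        with open(path, "rb") as fh:
            bundle = pickle.load(fh)
        if bundle.get("format_version") != 1:
            raise ValueError(f"unsupported model bundle version in {path}")
        return bundle["model"]

    def predict(self, X_new) -> Predictions:
        X_new = np.asarray(X_new, dtype=np.float64)
        if X_new.ndim != 2:
            raise ValueError("X_new must be 2-dimensional")
        if X_new.shape[0] == 0:
            return Predictions(values=np.empty(0))
        if X_new.shape[1] != self.n_features:
            raise ValueError(
                f"design mismatch: model was fitted on {self.n_features} columns "
                f"but X_new has {X_new.shape[1]}"
            )
        if self.model_name == "bayesian_brr":
            fit = self.mixed_fit
            return Predictions(values=fit.mu + X_new @ fit.effects)
        if self.model_name == "bayesian_gblup":
            st = self._gblup_state
            # kernel-regression extension: u(new) = K_new,train @ alpha
            return Predictions(values=self.mixed_fit.mu + X_new @ st["alpha"])
        if self.response.is_class:
            proba = self.backend.predict_proba(X_new)
            cols = list(self.backend.classes_)
            if self._label_map is not None:
                cols = [self._label_map[c] for c in cols]
            frame = pd.DataFrame(proba, columns=cols)
            frame = frame[sorted(frame.columns)]
            labels = frame.columns.to_numpy()[np.argmax(frame.to_numpy(), axis=1)]
            return Predictions(values=labels, probabilities=frame)
        return Predictions(values=np.asarray(self.backend.predict(X_new), dtype=np.float64))

    _label_map: dict | None = None


def _default_loss(response: ResponseSpec, loss: str | None) -> str:
    if loss is not None:
        return loss
    return "log_loss" if response.is_class else "mse"


def _eval_loss(loss, y_true, preds: Predictions, levels):
    if loss == "mse":
        return mse(np.asarray(y_true, dtype=float), preds.values)
    if loss == "log_loss":
        return log_loss(y_true, preds.probabilities[list(levels)], labels=list(levels))
    if loss == "accuracy":
        return -accuracy_score(y_true, preds.values)
    raise ValueError(f"unknown tuning loss {loss!r}")


def _fit_once(model_name, params, X, y, response, seed) -> FittedModel:
    n, p = X.shape
    if model_name == "bayesian_brr":
        if response.is_class:
            raise ValueError("bayesian_brr supports continuous responses only")
        fit = fit_brr(X, y, iterations=params["iterations"],
                      burn_in=params["burn_in"], seed=seed)
        return FittedModel(model_name, params, response, mixed_fit=fit, n_features=p)
    if model_name == "bayesian_gblup":
        if response.is_class:
            raise ValueError("bayesian_gblup supports continuous responses only")
        if n != p:
            raise ValueError(
                "bayesian_gblup expects a square observation kernel as the design"
            )
        fit = fit_gblup(X, None, y, iterations=params["iterations"],
                        burn_in=params["burn_in"], seed=seed)
        # resolve alpha = K^+ u so new kernel rows extend predictions
        alpha = np.linalg.pinv(X, rcond=1e-10) @ fit.effects
        return FittedModel(model_name, params, response, mixed_fit=fit,
                           n_features=p, _gblup_state={"alpha": alpha})
    backend = _build_backend(model_name, params, response, p, seed)
    label_map = None
    y_fit = y
    if model_name == "boosted_machine" and response.is_class:
        levels = list(response.levels)
        y_fit = np.array([levels.index(v) for v in np.asarray(y)])
        label_map = dict(enumerate(levels))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        backend.fit(X, y_fit)
    fm = FittedModel(model_name, params, response, backend=backend, n_features=p)
    fm._label_map = label_map
    return fm


def fit(
    model_name: str,
    X_design,
    y,
    defaults_override: dict | None = None,
    tune: TuneConfig | None = None,
    seed: int = 0,
) -> FittedModel:
    """Fit one of the supported models on an arbitrary design matrix.

    ``defaults_override`` updates the model's defaults; values given as a
    list define a grid dimension and values given as a (low, high[, scale
    [, type]]) tuple define Bayesian-optimization bounds — either triggers
    tuning under ``tune`` (inner k-fold CV; grid needs at least one listed
    hyperparameter with >= 2 values).  Scalars are fixed as-is.

    The returned :class:`FittedModel` reports the resolved (tuned)
    hyperparameters and the inferred :class:`ResponseSpec`.
    """
    X = np.asarray(X_design, dtype=np.float64)
    y_arr = np.asarray(y)
    if X.ndim != 2 or X.shape[0] != y_arr.shape[0]:
        raise ValueError("X_design must be 2-d with one row per response value")
    response = infer_response_type(y_arr)
    params = _resolve_params(model_name, defaults_override)

    grid_dims = {k: v for k, v in params.items() if isinstance(v, list)}
    bayes_dims = {k: v for k, v in params.items() if isinstance(v, tuple)}
    tune_result = None
    if grid_dims or bayes_dims:
        tune = tune or TuneConfig()
        loss_name = _default_loss(response, tune.loss)
        fixed = {k: v for k, v in params.items()
                 if k not in grid_dims and k not in bayes_dims}

        def fit_eval(combo, train_idx, val_idx):
            trial = {**fixed, **combo}
            fm = _fit_once(model_name, trial, X[train_idx], y_arr[train_idx],
                           response, seed)
            preds = fm.predict(X[val_idx])
            return _eval_loss(loss_name, y_arr[val_idx], preds, response.levels)

        if tune.strategy == "grid":
            if bayes_dims:
                raise ValueError("grid strategy takes value lists, not bound tuples")
            if not any(len(v) >= 2 for v in grid_dims.values()):
                raise ValueError(
                    "grid search needs at least one hyperparameter with >= 2 values"
                )
            tune_result = grid_search(fit_eval, grid_dims, X.shape[0], tune)
        else:
            if grid_dims:
                raise ValueError("bayes strategy takes bound tuples, not value lists")
            folds_cfg = tune

            def objective(combo):
                from .tuning import make_kfolds

                folds = make_kfolds(X.shape[0], folds_cfg.inner_folds, folds_cfg.seed)
                losses = []
                for fold in folds:
                    train = np.setdiff1d(np.arange(X.shape[0]), fold)
                    losses.append(fit_eval(combo, train, fold))
                return float(np.mean(losses))

            tune_result = bayes_opt(objective, bayes_dims, tune)
        params = {**fixed, **tune_result.best}

    fm = _fit_once(model_name, params, X, y_arr, response, seed)
    fm.tune_result = tune_result
    return fm


def predict(model: FittedModel, X_new) -> Predictions:
    """Functional alias for ``model.predict(X_new)``."""
    return model.predict(X_new)
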