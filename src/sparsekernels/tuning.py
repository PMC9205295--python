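"""Hyperparameter tuning: inner-CV grid search and Bayesian optimization.

Both strategies evaluate candidate hyperparameter combinations by k-fold
cross-validation on the (outer) training data only — nested CV, so the
outer test partition never influences the selection.  Grid search is an
exhaustive sweep of the Cartesian product of discrete value lists; Bayesian
optimization fits a Gaussian-process surrogate (Matern-5/2) to the observed
losses and proposes the next point by maximizing expected improvement, for
a default budget of 5 initial quasi-random points plus 10 iterations.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm, qmc
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import ConstantKernel, Matern, WhiteKernel


@dataclass(frozen=True)
class TuneConfig:
    """Settings shared by both tuning strategies.

    ``loss`` defaults to ``mse`` for continuous responses and ``log_loss``
    for class-valued ones (``accuracy`` available by flag in the learner
    interface).
    """

    strategy: str = "grid"
    inner_folds: int = 5
    bayes_iterations: int = 10
    initial_points: int = 5
    seed: int = 0
    loss: str | None = None

    def __post_init__(self) -> None:
        if self.strategy not in ("grid", "bayes"):
            raise ValueError("strategy must be 'grid' or 'bayes'")
        if self.inner_folds < 2:
            raise ValueError("inner_folds must be >= 2")
        if self.bayes_iterations < 1:
            raise ValueError("bayes_iterations must be >= 1")
        if self.initial_points < 1:
            raise ValueError("initial_points must be >= 1")


@dataclass
class TuneResult:
    """Evaluated combinations, their losses and the selected combination.

    ``table`` has one row per evaluated combination (mean inner-CV loss and
    its sd over folds, or the single objective value for Bayesian
    optimization); ``best`` minimizes the mean loss, ties broken by
    first-in-enumeration order.
    """

    table: pd.DataFrame
    best: dict
    best_loss: float


def make_kfolds(n: int, k: int, seed: int = 0) -> list[np.ndarray]:
    """Seeded k-fold partition of range(n): disjoint, exhaustive, sizes
    differing by at most 1."""
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > n:
        raise ValueError(f"k={k} folds cannot exceed n={n} observations")
    rng = np.random.default_rng(seed)
    idx = rng.permutation(n)
    return [np.sort(fold) for fold in np.array_split(idx, k)]


def make_random_partitions(
    n: int,
    testing_proportion: float = 0.2,
    reps: int = 5,
    seed: int = 0,
    stratify=None,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """``reps`` independent seeded train/test splits.

    ``|test| = round(testing_proportion * n)``; with ``stratify`` (e.g. an
    environment label per observation) the test fraction is drawn within
    each stratum, so every environment is represented in every test set.
    """
    if not (0.0 < testing_proportion < 1.0):
        raise ValueError("testing_proportion must be in (0, 1)")
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(reps):
        if stratify is None:
            perm = rng.permutation(n)
            n_test = round(testing_proportion * n)
            test = np.sort(perm[:n_test])
        else:
            labels = np.asarray(stratify)
            if labels.size != n:
                raise ValueError("stratify must have one label per observation")
            test_parts = []
            for lv in pd.unique(labels):
                members = np.flatnonzero(labels == lv)
                n_test = max(1, round(testing_proportion * members.size))
                test_parts.append(rng.choice(members, size=n_test, replace=False))
            test = np.sort(np.concatenate(test_parts))
        train = np.setdiff1d(np.arange(n), test)
        out.append((train, test))
    return out


def _cv_loss(fit_eval, params, folds, n):
    losses = []
    all_idx = np.arange(n)
    for fold in folds:
        train = np.setdiff1d(all_idx, fold)
        losses.append(float(fit_eval(params, train, fold)))
    losses = np.asarray(losses)
    return float(losses.mean()), float(losses.std(ddof=1)) if len(losses) > 1 else 0.0


def grid_search(fit_eval, space: dict, n_obs, config: TuneConfig | None = None) -> TuneResult:
    """Exhaustive sweep of a discrete hyperparameter space under inner CV.

    Parameters
    ----------
    fit_eval : callable(params: dict, train_idx, val_idx) -> float
        Trains on ``train_idx`` rows and returns the validation loss.
    space : dict of name -> list of values (all discrete).
    n_obs : int or sized
        Number of (outer-training) observations to fold.
    config : TuneConfig

    The full Cartesian product is evaluated on a common set of seeded inner
    folds; ``best`` is the argmin of the mean fold loss, first-enumerated
    combination winning ties.
    """
    config = config or TuneConfig()
    if not space or any(len(v) == 0 for v in space.values()):
        raise ValueError("empty hyperparameter space")
    n = n_obs if isinstance(n_obs, int) else len(n_obs)
    folds = make_kfolds(n, config.inner_folds, config.seed)
    names = list(space.keys())
    rows = []
    best = None
    best_loss = math.inf
    for combo in itertools.product(*(space[k] for k in names)):
        params = dict(zip(names, combo))
        mean_loss, sd_loss = _cv_loss(fit_eval, params, folds, n)
        rows.append({**params, "mean_loss": mean_loss, "sd_loss": sd_loss})
        if mean_loss < best_loss:          # strict: first-enumerated wins ties
            best, best_loss = params, mean_loss
    return TuneResult(table=pd.DataFrame(rows), best=best, best_loss=best_loss)


def _unit_to_params(u, names, bounds):
    params = {}
    for j, name in enumerate(names):
        low, high, scale, ptype = bounds[name]
        if scale == "log":
            val = math.exp(math.log(low) + u[j] * (math.log(high) - math.log(low)))
        else:
            val = low + u[j] * (high - low)
        if ptype == "int":
            val = int(round(val))
        params[name] = val
    return params


def _normalize_bounds(space: dict) -> dict:
    bounds = {}
    for name, spec in space.items():
        spec = tuple(spec)
        low, high = float(spec[0]), float(spec[1])
        scale = spec[2] if len(spec) > 2 else "linear"
        ptype = spec[3] if len(spec) > 3 else "float"
        if not low < high:
            raise ValueError(f"bounds for {name!r} must satisfy low < high")
        if scale not in ("linear", "log"):
            raise ValueError(f"scale for {name!r} must be 'linear' or 'log'")
        if scale == "log" and low <= 0:
            raise ValueError(f"log-scaled bounds for {name!r} must be positive")
        bounds[name] = (low, high, scale, ptype)
    return bounds


def bayes_opt(objective, space: dict, config: TuneConfig | None = None,
              n_candidates: int = 512) -> TuneResult:
    """Bayesian optimization of a black-box loss over bounded numerics.

    Parameters
    ----------
    objective : callable(params: dict) -> float
        The loss to minimize (for tuning: an inner-CV evaluation).
    space : dict of name -> (low, high[, scale[, type]])
        ``scale`` in {linear, log}; ``type`` in {float, int} — integer
        parameters are optimized on the continuous relaxation and rounded
        at evaluation.
    config : TuneConfig (``initial_points`` + ``bayes_iterations`` budget).
    n_candidates : int
        Size of the seeded candidate set over which expected improvement is
        maximized at each iteration.

    ``initial_points`` seeded quasi-random (Sobol) points are evaluated,
    then each iteration fits a GP (Matern-5/2 + noise) to the observed
    (point, loss) pairs and evaluates the candidate with maximal expected
    improvement.  Returns the best observed point and the full trace.
    """
    config = config or TuneConfig(strategy="bayes")
    bounds = _normalize_bounds(space)
    names = list(bounds.keys())
    d = len(names)
    rng = np.random.default_rng(config.seed)
    sampler = qmc.Sobol(d, scramble=True, seed=config.seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)  # non-power-of-2 draw count
        U = [np.asarray(u) for u in sampler.random(config.initial_points)]
    evaluated_u, losses, rows = [], [], []

    def _eval(u):
        params = _unit_to_params(u, names, bounds)
        val = float(objective(params))
        if not math.isfinite(val):
            raise ValueError(f"objective returned non-finite value for combination {params}")
        evaluated_u.append(u)
        losses.append(val)
        rows.append({**params, "loss": val})
        return val

    for u in U:
        _eval(u)

    gp_kernel = ConstantKernel(1.0) * Matern(length_scale=np.full(d, 0.3), nu=2.5) \
        + WhiteKernel(noise_level=1e-6, noise_level_bounds=(1e-10, 1e-1))
    for _ in range(config.bayes_iterations):
        X = np.vstack(evaluated_u)
        y = np.asarray(losses)
        y_mean, y_sd = y.mean(), y.std()
        y_std = (y - y_mean) / y_sd if y_sd > 0 else y - y_mean
        gp = GaussianProcessRegressor(kernel=gp_kernel, normalize_y=False,
                                      alpha=1e-10, random_state=config.seed)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            gp.fit(X, y_std)
        cand = rng.random((n_candidates, d))
        mu_c, sd_c = gp.predict(cand, return_std=True)
        best_std = y_std.min()
        with np.errstate(divide="ignore", invalid="ignore"):
            z = (best_std - mu_c) / np.where(sd_c > 0, sd_c, 1.0)
            ei = (best_std - mu_c) * norm.cdf(z) + sd_c * norm.pdf(z)
        ei = np.where(sd_c > 1e-12, ei, 0.0)
        _eval(cand[int(np.argmax(ei))])

    i_best = int(np.argmin(losses))
    best_params = _unit_to_params(evaluated_u[i_best], names, bounds)
    return TuneResult(table=pd.DataFrame(rows), best=best_params,
                      best_loss=float(losses[i_best]))
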