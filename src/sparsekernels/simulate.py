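"""Synthetic marker and multi-environment phenotype simulation.

Generates biallelic SNP dosage matrices (Hardy-Weinberg sampling at a
configurable minor-allele-frequency range, no linkage disequilibrium) and
phenotypes with a known additive (optionally epistatic) genetic
architecture, a target heritability and environment main effects — the
structure of multi-environment plant-breeding trials (hundreds of lines,
hundreds to thousands of markers, a handful of environments) at desk
scale.  The returned truth (marker effects, genetic values, variance
components) makes every downstream stage testable against known answers.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .kernels import MarkerScaler


@dataclass(frozen=True)
class SimConfig:
    """Study-condition parameters for the simulator.

    Defaults emulate a wheat-style multi-environment trial at desk scale:
    300 lines, 500 markers, 4 environments, heritability 0.5, additive
    architecture.  Heritability is enforced by construction at the line
    level: the genetic values are rescaled to variance ``sigma_u2 = h2``
    and residuals drawn with ``sigma_e2 = sigma_u2 (1 - h2)/h2 = 1 - h2``.
    """

    n_lines: int = 300
    p_markers: int = 500
    maf_range: tuple = (0.05, 0.5)
    h2: float = 0.5
    n_env: int = 4
    env_effect_sd: float = 1.0
    architecture: str = "additive"
    mu: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        low, high = self.maf_range
        if not (0.0 < low <= high <= 0.5):
            raise ValueError("maf_range must satisfy 0 < low <= high <= 0.5")
        if not (0.0 <= self.h2 <= 1.0):
            raise ValueError("h2 must be in [0, 1]")
        if self.architecture not in ("additive", "epistatic"):
            raise ValueError("architecture must be 'additive' or 'epistatic'")
        if self.n_lines < 2 or self.p_markers < 1 or self.n_env < 1:
            raise ValueError("n_lines >= 2, p_markers >= 1, n_env >= 1 required")
        if self.env_effect_sd < 0:
            raise ValueError("env_effect_sd must be >= 0")


def simulate_markers(cfg: SimConfig) -> pd.DataFrame:
    """Simulate a lines x markers dosage matrix.

    Each marker draws an allele frequency q ~ Uniform(maf_range) and each
    line an independent Binomial(2, q) dosage; monomorphic columns are
    resampled so every marker is informative.  Returns a DataFrame indexed
    by line id with the drawn frequencies in ``attrs["allele_freq"]``.
    """
    rng = np.random.default_rng(cfg.seed)
    q = rng.uniform(*cfg.maf_range, size=cfg.p_markers)
    X = rng.binomial(2, q, size=(cfg.n_lines, cfg.p_markers)).astype(np.float64)
    for _ in range(100):
        mono = X.std(axis=0) == 0
        if not mono.any():
            break
        q[mono] = rng.uniform(*cfg.maf_range, size=mono.sum())
        X[:, mono] = rng.binomial(2, q[mono], size=(cfg.n_lines, int(mono.sum())))
    lines = [f"L{i + 1:04d}" for i in range(cfg.n_lines)]
    markers = [f"M{j + 1:05d}" for j in range(cfg.p_markers)]
    out = pd.DataFrame(X, index=pd.Index(lines, name="Line"), columns=markers)
    out.attrs["allele_freq"] = q
    return out


def simulate_phenotypes(X: pd.DataFrame, cfg: SimConfig):
    """Simulate multi-environment phenotypes on top of a marker matrix.

    Additive genetic values ``g = X_scaled beta`` with ``beta ~ N(0, 1/p)``;
    the epistatic architecture adds pairwise products of a random 1% marker
    subset.  ``g`` is rescaled to variance ``sigma_u2 = h2`` (zeroed when
    h2 = 0) and residuals drawn per record with ``sigma_e2 = 1 - h2``
    (exactly zero when h2 = 1); environment main effects are
    ``N(0, env_effect_sd^2)``.  One record per line x environment.

    Returns
    -------
    (pheno, truth) : DataFrame with columns Line, Env, Trait; dict with
        beta, g, env_effects, sigma_u2, sigma_e2, h2.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    values = X.to_numpy(dtype=np.float64) if isinstance(X, pd.DataFrame) else np.asarray(X, float)
    n, p = values.shape
    Xs = MarkerScaler().fit_transform(values)
    beta = rng.normal(0.0, np.sqrt(1.0 / p), size=Xs.shape[1])
    g = Xs @ beta
    if cfg.architecture == "epistatic":
        k = max(2, int(round(0.01 * Xs.shape[1])))
        subset = rng.choice(Xs.shape[1], size=k, replace=False)
        pairs = [(a, b) for i, a in enumerate(subset) for b in subset[i + 1:]]
        W = np.column_stack([Xs[:, a] * Xs[:, b] for a, b in pairs])
        g = g + W @ rng.normal(0.0, np.sqrt(1.0 / max(len(pairs), 1)), size=len(pairs))

    sigma_u2 = cfg.h2
    sigma_e2 = 1.0 - cfg.h2
    if cfg.h2 == 0.0:
        g = np.zeros(n)
        beta = np.zeros_like(beta)
    else:
        g = g - g.mean()
        sd = g.std(ddof=1)
        if sd > 0:
            scale = np.sqrt(sigma_u2) / sd
            g = g * scale
            beta = beta * scale

    envs = [f"E{e + 1}" for e in range(cfg.n_env)]
    env_effects = rng.normal(0.0, cfg.env_effect_sd, size=cfg.n_env)
    lines = list(X.index) if isinstance(X, pd.DataFrame) else [f"L{i + 1:04d}" for i in range(n)]
    records = []
    for e, env in enumerate(envs):
        resid = rng.normal(0.0, np.sqrt(sigma_e2), size=n) if sigma_e2 > 0 else np.zeros(n)
        y = cfg.mu + env_effects[e] + g + resid
        for i, line in enumerate(lines):
            records.append({"Line": line, "Env": env, "Trait": y[i]})
    pheno = pd.DataFrame.from_records(records)
    truth = {
        "beta": beta,
        "g": g,
        "env_effects": dict(zip(envs, env_effects)),
        "sigma_u2": sigma_u2,
        "sigma_e2": sigma_e2,
        "h2": cfg.h2,
    }
    return pheno, truth


def simulate_dataset(cfg: SimConfig):
    """Markers, phenotypes and truth in one call."""
    X = simulate_markers(cfg)
    pheno, truth = simulate_phenotypes(X, cfg)
    return X, pheno, truth


def write_dataset(out_dir, cfg: SimConfig) -> None:
    """Emit markers.csv, pheno.csv and truth.json into ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    X, pheno, truth = simulate_dataset(cfg)
    X.to_csv(out / "markers.csv")
    pheno.to_csv(out / "pheno.csv", index=False)
    payload = {
        "config": {**asdict(cfg), "maf_range": list(cfg.maf_range)},
        "beta": truth["beta"].tolist(),
        "g": truth["g"].tolist(),
        "env_effects": truth["env_effects"],
        "sigma_u2": truth["sigma_u2"],
        "sigma_e2": truth["sigma_e2"],
        "h2": truth["h2"],
    }
    (out / "truth.json").write_text(json.dumps(payload, indent=2))
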