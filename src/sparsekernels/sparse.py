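"""Sparse (compressed, Nystrom) kernel approximations.

A dense n x n kernel K is approximated from an anchor subset of m lines as
``Q = K_nm K_mm^{-1} K_nm'``: only the m x m anchor kernel and the n x m
cross-kernel are ever formed.  With the eigendecomposition
``K_mm = U S U'`` the projected design matrix

    P = K_nm U S^{-1/2}

has at most m columns and satisfies ``P P' = Q``; fitting any learner on P
is the compressed kernel machine.  The *compression level* is one minus the
proportion of lines used as anchors, so compression 0 uses every line and
(for full-rank kernels) recovers the dense kernel exactly.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .kernels import KernelConfig, compute_kernel, median_squared_distance


@dataclass(frozen=True)
class SparseKernelSpec:
    """Compression settings for a sparse kernel.

    ``compression_level`` is the fraction of lines NOT used as anchors;
    the anchor count is ``m = ceil((1 - compression_level) * n)``.
    """

    compression_level: float = 0.0
    seed: int = 0
    eig_tol: float = 1e-10

    def __post_init__(self) -> None:
        if not (0.0 <= self.compression_level < 1.0):
            raise ValueError("compression_level must be in [0, 1)")
        if self.eig_tol <= 0:
            raise ValueError("eig_tol must be positive")

    @property
    def lines_proportion(self) -> float:
        return 1.0 - self.compression_level

    def anchor_count(self, n: int) -> int:
        return math.ceil(self.lines_proportion * n)


@dataclass
class SparseDesign:
    """Projected design matrix plus the metadata needed to reuse it."""

    P: np.ndarray
    anchor_ids: list
    eigenvalues: np.ndarray
    config: KernelConfig
    spec: SparseKernelSpec
    line_ids: list | None = None

    @property
    def m(self) -> int:
        return len(self.anchor_ids)

    @property
    def rank(self) -> int:
        return len(self.eigenvalues)

    def to_frame(self) -> pd.DataFrame:
        index = self.line_ids if self.line_ids is not None else range(len(self.P))
        cols = [f"pc{i + 1}" for i in range(self.P.shape[1])]
        return pd.DataFrame(self.P, index=index, columns=cols)

    def save(self, csv_path, meta_path=None) -> None:
        csv_path = Path(csv_path)
        frame = self.to_frame()
        frame.index.name = "Line"
        frame.to_csv(csv_path)
        meta_path = Path(meta_path) if meta_path else csv_path.with_suffix(".json")
        meta = {
            "anchor_ids": [str(a) for a in self.anchor_ids],
            "eigenvalues": self.eigenvalues.tolist(),
            "compression_level": self.spec.compression_level,
            "seed": self.spec.seed,
            "eig_tol": self.spec.eig_tol,
            "kernel": {
                "name": self.config.name,
                "gamma": self.config.gamma,
                "degree": self.config.degree,
                "coef0": self.config.coef0,
                "arc_depth": self.config.arc_depth,
            },
        }
        meta_path.write_text(json.dumps(meta, indent=2))


def select_anchor_lines(line_ids, spec: SparseKernelSpec) -> list:
    """Draw the anchor subset: m distinct lines, uniform, without replacement.

    Compression 0 returns all lines in their original order; otherwise the
    draw is seeded and deterministic.  Fewer than 2 anchors is an error.
    """
    line_ids = list(line_ids)
    n = len(line_ids)
    if n < 2:
        raise ValueError("need at least 2 lines")
    m = spec.anchor_count(n)
    if m < 2:
        raise ValueError(
            f"compression too aggressive: {spec.compression_level} leaves m={m} < 2 anchors"
        )
    if spec.compression_level == 0.0:
        return line_ids
    rng = np.random.default_rng(spec.seed)
    idx = np.sort(rng.choice(n, size=m, replace=False))
    return [line_ids[i] for i in idx]


def _truncated_eig(K_mm, eig_tol):
    w, U = np.linalg.eigh(0.5 * (K_mm + K_mm.T))
    order = np.argsort(w)[::-1]
    w, U = w[order], U[:, order]
    keep = w > eig_tol * max(w.max(), 0.0)
    if not keep.any():
        raise ValueError("anchor kernel is numerically singular: no eigenvalue survives truncation")
    return w[keep], U[:, keep]


def sparse_design(
    X,
    config: KernelConfig | None = None,
    spec: SparseKernelSpec | None = None,
    line_ids=None,
    anchor_ids=None,
) -> SparseDesign:
    """Build the projected design P = K_nm U S^{-1/2} from marker data.

    The anchor kernel K_mm is eigendecomposed and its spectrum truncated at
    ``spec.eig_tol`` relative to the leading eigenvalue (a pseudo-inverse in
    place of the literal K_mm^{-1}, so rank-deficient anchor sets are
    usable); the retained rank r <= m is the column count of P.

    For gaussian/exponential kernels the distance normalizer is computed
    once from the anchor set and reused for the cross-kernel, keeping K_nm
    and K_mm on a common scale.  ``anchor_ids`` overrides the seeded
    selection (e.g. for nested-anchor comparisons).
    """
    config = config or KernelConfig()
    spec = spec or SparseKernelSpec()
    X = np.asarray(X, dtype=np.float64)
    n = X.shape[0]
    ids = list(line_ids) if line_ids is not None else list(range(n))
    anchors = list(anchor_ids) if anchor_ids is not None else select_anchor_lines(ids, spec)
    pos = {lid: i for i, lid in enumerate(ids)}
    aidx = np.array([pos[a] for a in anchors])
    Xa = X[aidx]

    if config.name in ("gaussian", "exponential") and config.distance_scale is None:
        config = replace(config, distance_scale=median_squared_distance(Xa))

    K_mm = compute_kernel(Xa, Xa, config)
    K_nm = compute_kernel(X, Xa, config)
    S, U = _truncated_eig(K_mm, spec.eig_tol)
    P = K_nm @ (U / np.sqrt(S))
    return SparseDesign(P=P, anchor_ids=anchors, eigenvalues=S,
                        config=config, spec=spec, line_ids=ids)


def sparse_design_from_kernel(
    K,
    spec: SparseKernelSpec | None = None,
    line_ids=None,
    config: KernelConfig | None = None,
    anchor_ids=None,
) -> SparseDesign:
    """As :func:`sparse_design` but slicing a precomputed dense kernel.

    K_mm and K_nm are taken as sub-blocks of K rather than recomputed.
    """
    spec = spec or SparseKernelSpec()
    K = np.asarray(K, dtype=np.float64)
    if K.ndim != 2 or K.shape[0] != K.shape[1]:
        raise ValueError("precomputed kernel must be square")
    n = K.shape[0]
    ids = list(line_ids) if line_ids is not None else list(range(n))
    anchors = list(anchor_ids) if anchor_ids is not None else select_anchor_lines(ids, spec)
    pos = {lid: i for i, lid in enumerate(ids)}
    aidx = np.array([pos[a] for a in anchors])
    K_mm = K[np.ix_(aidx, aidx)]
    K_nm = K[:, aidx]
    S, U = _truncated_eig(K_mm, spec.eig_tol)
    P = K_nm @ (U / np.sqrt(S))
    return SparseDesign(P=P, anchor_ids=anchors, eigenvalues=S,
                        config=config or KernelConfig(), spec=spec, line_ids=ids)


def reconstruct_kernel(design: SparseDesign) -> np.ndarray:
    """The approximated dense kernel Q = P P' (symmetric PSD by construction)."""
    Q = design.P @ design.P.T
    return 0.5 * (Q + Q.T)


class NystromApproximator(TransformerMixin, BaseEstimator):
    """Compressed kernel feature map (scikit-learn transformer).

    ``fit(X)`` selects the anchor lines among the rows of X, computes the
    anchor kernel and its truncated eigendecomposition; ``transform(X2)``
    projects any line set onto the anchor basis, returning the design
    ``K_{X2,m} U S^{-1/2}``.  ``fit_transform(X)`` is the sparse design P of
    the training lines.

    Parameters mirror :class:`~sparsekernels.kernels.KernelConfig` plus the
    compression settings of :class:`SparseKernelSpec`.
    """

    def __init__(self, kernel: str = "linear", gamma: float | None = None,
                 degree: int = 3, coef0: float = 0.0, arc_depth: int = 1,
                 compression_level: float = 0.0, seed: int = 0,
                 eig_tol: float = 1e-10):
        self.kernel = kernel
        self.gamma = gamma
        self.degree = degree
        self.coef0 = coef0
        self.arc_depth = arc_depth
        self.compression_level = compression_level
        self.seed = seed
        self.eig_tol = eig_tol

    def fit(self, X, y=None):
        X = check_array(X, dtype=np.float64)
        spec = SparseKernelSpec(self.compression_level, self.seed, self.eig_tol)
        config = KernelConfig(name=self.kernel, gamma=self.gamma,
                              degree=self.degree, coef0=self.coef0,
                              arc_depth=self.arc_depth)
        ids = list(range(X.shape[0]))
        anchors = select_anchor_lines(ids, spec)
        Xa = X[np.asarray(anchors)]
        if config.name in ("gaussian", "exponential") and config.distance_scale is None:
            config = replace(config, distance_scale=median_squared_distance(Xa))
        K_mm = compute_kernel(Xa, Xa, config)
        S, U = _truncated_eig(K_mm, spec.eig_tol)
        self.config_ = config
        self.spec_ = spec
        self.anchor_indices_ = np.asarray(anchors)
        self.anchors_X_ = Xa
        self.eigenvalues_ = S
        self.projection_ = U / np.sqrt(S)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self, "projection_")
        X = check_array(X, dtype=np.float64)
        K_nm = compute_kernel(X, self.anchors_X_, self.config_)
        return K_nm @ self.projection_
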