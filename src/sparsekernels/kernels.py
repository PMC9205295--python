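"""Kernel functions on marker matrices and kernel square-root designs.

Seven kernel families are supported: linear, polynomial, sigmoid, gaussian,
exponential and arc-cosine of depth L >= 1.  All of them operate on a
centered-and-scaled marker matrix (lines x markers) and return either a
symmetric self-kernel or a rectangular cross-kernel between two line sets.
The symmetric positive-semidefinite square root of a kernel, post-multiplied
by a line-incidence matrix, turns any supervised learner into a kernel
machine: the learner sees ``Z @ K^{1/2}`` as an ordinary feature matrix.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted

logger = logging.getLogger(__name__)

KERNEL_NAMES = (
    "linear",
    "polynomial",
    "sigmoid",
    "gaussian",
    "exponential",
    "arc_cosine",
)


@dataclass(frozen=True)
class KernelConfig:
    """Kernel family and hyperparameters.

    Parameters
    ----------
    name : str
        One of ``linear, polynomial, sigmoid, gaussian, exponential,
        arc_cosine``.
    gamma : float or None
        Scale parameter.  ``None`` resolves to ``1/p`` for polynomial and
        sigmoid kernels and to ``1.0`` for gaussian/exponential kernels,
        whose distances are already normalized by the median heuristic.
    degree : int
        Polynomial degree (polynomial kernel only).
    coef0 : float
        Additive constant (polynomial and sigmoid kernels).
    arc_depth : int
        Depth L of the arc-cosine kernel; the depth-1 angular transform is
        applied recursively L times.
    distance_scale : float or None
        Squared-distance normalizer ``s`` for gaussian/exponential kernels.
        ``None`` means "median of the nonzero pairwise squared distances of
        the reference set"; pass ``1.0`` for the raw, unnormalized form.
    """

    name: str = "linear"
    gamma: float | None = None
    degree: int = 3
    coef0: float = 0.0
    arc_depth: int = 1
    distance_scale: float | None = None

    def __post_init__(self) -> None:
        if self.name not in KERNEL_NAMES:
            raise ValueError(
                f"unknown kernel {self.name!r}; expected one of {KERNEL_NAMES}"
            )
        if self.gamma is not None and self.gamma <= 0:
            raise ValueError("gamma must be positive")
        if self.degree < 1:
            raise ValueError("degree must be a positive integer")
        if self.arc_depth < 1:
            raise ValueError("arc_depth must be >= 1")

    def resolve_gamma(self, p: int) -> float:
        if self.gamma is not None:
            return float(self.gamma)
        if self.name in ("gaussian", "exponential"):
            return 1.0
        return 1.0 / p


class MarkerScaler(TransformerMixin, BaseEstimator):
    """Center and scale marker columns; drop zero-variance markers.

    Columns are standardized to mean 0 and sample (n-1 denominator) standard
    deviation 1.  Zero-variance (monomorphic) columns carry no information
    and are dropped; their indices are logged and kept in ``dropped_``.
    The fitted constants are retained so new lines are transformed with the
    training centering/scaling, as required for cross-kernels.
    """

    def fit(self, X, y=None):
        X = check_array(X, dtype=np.float64, ensure_min_samples=2)
        sd = X.std(axis=0, ddof=1)
        self.keep_ = sd > 0
        if not self.keep_.any():
            raise ValueError("no informative markers: all columns are zero-variance")
        self.dropped_ = np.flatnonzero(~self.keep_)
        if self.dropped_.size:
            logger.info(
                "dropping %d zero-variance marker column(s): %s",
                self.dropped_.size,
                self.dropped_.tolist(),
            )
        self.mean_ = X[:, self.keep_].mean(axis=0)
        self.scale_ = sd[self.keep_]
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self, "mean_")
        X = check_array(X, dtype=np.float64)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"expected {self.n_features_in_} marker columns, got {X.shape[1]}"
            )
        return (X[:, self.keep_] - self.mean_) / self.scale_


def center_scale(X):
    """Center and scale a marker matrix (drops zero-variance columns).

    Returns the transformed matrix; use :class:`MarkerScaler` directly when
    the fitted constants are needed to transform new lines.
    """
    return MarkerScaler().fit_transform(X)


def median_squared_distance(X) -> float:
    """Median of the nonzero pairwise squared Euclidean distances of X.

    The bandwidth heuristic used to normalize gaussian/exponential distances
    so that gamma stays dimensionless across marker densities.
    """
    X = np.asarray(X, dtype=np.float64)
    d2 = cdist(X, X, metric="sqeuclidean")
    vals = d2[np.triu_indices_from(d2, k=1)]
    vals = vals[vals > 0]
    if vals.size == 0:
        return 1.0
    return float(np.median(vals))


def _arc_cosine_depth1(dot, sq_a, sq_b):
    """Depth-1 arc-cosine transform of a dot-product-like matrix.

    ``k1(x, z) = (1/pi) * ||x|| ||z|| * (sin t + (pi - t) cos t)`` with
    ``t = arccos(x.z / (||x|| ||z||))``.  ``sq_a``/``sq_b`` are the
    self-kernel values (squared norms at depth 0).  Zero-norm rows yield 0.
    """
    norm_prod = np.sqrt(np.outer(sq_a, sq_b))
    with np.errstate(divide="ignore", invalid="ignore"):
        cos_t = np.where(norm_prod > 0, dot / np.where(norm_prod > 0, norm_prod, 1.0), 0.0)
    cos_t = np.clip(cos_t, -1.0, 1.0)
    theta = np.arccos(cos_t)
    out = (norm_prod / np.pi) * (np.sin(theta) + (np.pi - theta) * cos_t)
    return np.where(norm_prod > 0, out, 0.0)


def _arc_cosine(A, B, depth):
    # The diagonal is invariant under the depth-1 transform (theta = 0 gives
    # k(x,x) -> k(x,x)), so the self values stay ||x||^2 at every depth.
    sq_a = np.einsum("ij,ij->i", A, A)
    sq_b = np.einsum("ij,ij->i", B, B)
    k = A @ B.T
    for _ in range(depth):
        k = _arc_cosine_depth1(k, sq_a, sq_b)
    return k


def compute_kernel(A, B=None, config: KernelConfig | None = None):
    """Evaluate a kernel between two marker matrices.

    Parameters
    ----------
    A, B : arrays (n_a x p), (n_b x p)
        Centered/scaled marker matrices sharing the same p and the same
        scaling constants.  ``B=None`` computes the self-kernel of A.
    config : KernelConfig

    Returns
    -------
    ndarray of shape (n_a, n_b)

    Notes
    -----
    Gaussian/exponential distances are divided by ``config.distance_scale``
    (by default the median nonzero pairwise squared distance of A, the
    reference set) before gamma is applied, so cross-kernels against a
    reference set share its scale.
    """
    config = config or KernelConfig()
    A = np.asarray(A, dtype=np.float64)
    self_kernel = B is None
    B = A if self_kernel else np.asarray(B, dtype=np.float64)
    if A.ndim != 2 or B.ndim != 2:
        raise ValueError("marker matrices must be 2-dimensional")
    if A.shape[1] != B.shape[1]:
        raise ValueError(
            f"marker count mismatch: A has {A.shape[1]} columns, B has {B.shape[1]}"
        )
    p = A.shape[1]
    gamma = config.resolve_gamma(p)

    name = config.name
    if name == "linear":
        return A @ B.T / p
    if name == "polynomial":
        return (gamma * (A @ B.T) + config.coef0) ** config.degree
    if name == "sigmoid":
        return np.tanh(gamma * (A @ B.T) + config.coef0)
    if name in ("gaussian", "exponential"):
        s = config.distance_scale
        if s is None:
            s = median_squared_distance(A)
        if s <= 0:
            raise ValueError("distance_scale must be positive")
        d2 = cdist(A, B, metric="sqeuclidean")
        if name == "gaussian":
            return np.exp(-gamma * d2 / s)
        return np.exp(-gamma * np.sqrt(np.maximum(d2, 0.0)) / np.sqrt(s))
    # arc_cosine
    return _arc_cosine(A, B, config.arc_depth)


def kernel_sqrt(K, tol: float = 1e-10):
    """Symmetric PSD square root of a kernel matrix.

    Eigenvalues below ``tol * lambda_max`` (including all negatives, as
    produced e.g. by the indefinite sigmoid kernel) are clamped to zero; the
    result R satisfies ``R @ R == K_clamped``.  A warning is emitted when the
    clamped mass exceeds 1% of the trace.
    """
    K = np.asarray(K, dtype=np.float64)
    if K.ndim != 2 or K.shape[0] != K.shape[1]:
        raise ValueError("kernel must be a square matrix")
    scale = np.abs(K).max()
    if scale > 0 and np.abs(K - K.T).max() > 1e-8 * scale:
        raise ValueError("kernel must be symmetric")
    K = 0.5 * (K + K.T)
    w, V = np.linalg.eigh(K)
    cutoff = tol * max(w.max(), 0.0)
    clamped = w < cutoff
    clipped_mass = -w[w < 0].sum()
    trace = np.trace(K)
    if trace > 0 and clipped_mass > 0.01 * trace:
        warnings.warn(
            f"clamped negative eigenvalue mass ({clipped_mass:.3g}) exceeds 1% of "
            f"the kernel trace ({trace:.3g}); the kernel is far from PSD",
            stacklevel=2,
        )
    w = np.where(clamped, 0.0, w)
    return (V * np.sqrt(w)) @ V.T


def design_from_kernel(K, Z):
    """Observation-level design matrix ``Z @ K^{1/2}``.

    Z is the N x n 0/1 line-incidence matrix mapping observations to the n
    lines indexing K; replicated lines get identical design rows.
    """
    K = np.asarray(K, dtype=np.float64)
    Z = np.asarray(Z, dtype=np.float64)
    if Z.shape[1] != K.shape[0]:
        raise ValueError(
            f"incidence matrix has {Z.shape[1]} columns but kernel is of order {K.shape[0]}"
        )
    return Z @ kernel_sqrt(K)


class KernelTransformer(TransformerMixin, BaseEstimator):
    """Cross-kernel feature map against a fitted reference set.

    ``fit(X)`` stores the reference lines (and, for gaussian/exponential
    kernels, their median-distance scale); ``transform(X2)`` returns the
    rectangular kernel ``k(X2, X_ref)``.  With ``X2 = X`` this is the dense
    self-kernel.
    """

    def __init__(self, kernel: str = "linear", gamma: float | None = None,
                 degree: int = 3, coef0: float = 0.0, arc_depth: int = 1):
        self.kernel = kernel
        self.gamma = gamma
        self.degree = degree
        self.coef0 = coef0
        self.arc_depth = arc_depth

    def _config(self) -> KernelConfig:
        return KernelConfig(
            name=self.kernel, gamma=self.gamma, degree=self.degree,
            coef0=self.coef0, arc_depth=self.arc_depth,
        )

    def fit(self, X, y=None):
        X = check_array(X, dtype=np.float64)
        config = self._config()
        if config.name in ("gaussian", "exponential") and config.distance_scale is None:
            config = replace(config, distance_scale=median_squared_distance(X))
        self.config_ = config
        self.X_ref_ = X
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self, "X_ref_")
        X = check_array(X, dtype=np.float64)
        return compute_kernel(X, self.X_ref_, self.config_)
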