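import dataclasses

import numpy as np
import pytest
from sklearn.linear_model import Ridge
from sklearn.pipeline import make_pipeline

import sparsekernels as sk
from sparsekernels.kernels import KernelConfig, compute_kernel, kernel_sqrt
from sparsekernels.sparse import NystromApproximator, SparseKernelSpec

ALL_KERNELS = ["linear", "polynomial", "sigmoid", "gaussian", "exponential", "arc_cosine"]


def pinv_oracle(X, config, anchors):
    """Independent Nystrom oracle: K_nm pinv(K_mm) K_nm' with the anchor
    kernel clamped to its PSD part (identical to plain pinv for the PSD
    families; required for the indefinite sigmoid kernel)."""
    Xa = X[anchors]
    K_mm = compute_kernel(Xa, Xa, config)
    K_nm = compute_kernel(X, Xa, config)
    w, V = np.linalg.eigh(0.5 * (K_mm + K_mm.T))
    w = np.where(w > 1e-10 * max(w.max(), 0.0), w, 0.0)
    inv = np.where(w > 0, 1.0 / np.where(w > 0, w, 1.0), 0.0)
    return K_nm @ (V * inv) @ V.T @ K_nm.T


class TestAnchorSelection:
    def test_compression_zero_returns_all_in_order(self):
        ids = ["a", "b", "c", "d"]
        assert sk.select_anchor_lines(ids, SparseKernelSpec(0.0)) == ids

    def test_anchor_count(self):
        out = sk.select_anchor_lines(list(range(10)), SparseKernelSpec(0.5, seed=3))
        assert len(out) == 5 and len(set(out)) == 5

    def test_ceil_rule(self):
        out = sk.select_anchor_lines(list(range(7)), SparseKernelSpec(0.5, seed=3))
        assert len(out) == 4  # ceil(0.5 * 7)

    def test_seeded_replay(self):
        ids = list(range(30))
        a = sk.select_anchor_lines(ids, SparseKernelSpec(0.5, seed=9))
        b = sk.select_anchor_lines(ids, SparseKernelSpec(0.5, seed=9))
        c = sk.select_anchor_lines(ids, SparseKernelSpec(0.5, seed=10))
        assert a == b and a != c

    def test_too_aggressive_errors(self):
        with pytest.raises(ValueError, match="compression too aggressive"):
            sk.select_anchor_lines(list(range(3)), SparseKernelSpec(0.7))


class TestSparseDesign:
    def test_compression_zero_recovers_full_rank_kernel(self, scaled_markers):
        cfg = KernelConfig("linear")
        d = sk.sparse_design(scaled_markers, cfg, SparseKernelSpec(0.0))
        K = compute_kernel(scaled_markers, None, cfg)
        assert np.abs(sk.reconstruct_kernel(d) - K).max() < 1e-6

    def test_small_instance_matches_pinv_oracle(self, rng):
        X = sk.center_scale(rng.binomial(2, 0.4, (6, 3)).astype(float))
        cfg = KernelConfig("linear")
        d = sk.sparse_design(X, cfg, SparseKernelSpec(0.5, seed=1))
        anchors = np.array(d.anchor_ids)
        assert len(anchors) == 3
        assert np.abs(sk.reconstruct_kernel(d) - pinv_oracle(X, cfg, anchors)).max() < 1e-8

    def test_nystrom_interpolation_on_anchors(self, scaled_markers):
        cfg = KernelConfig("gaussian")
        d = sk.sparse_design(scaled_markers, cfg, SparseKernelSpec(0.4, seed=2))
        a = np.array(d.anchor_ids)
        Q = sk.reconstruct_kernel(d)
        K_mm = compute_kernel(scaled_markers[a], scaled_markers[a], d.config)
        assert np.abs(Q[np.ix_(a, a)] - K_mm).max() < 1e-8

    @pytest.mark.parametrize("name", ALL_KERNELS)
    def test_oracle_equivalence_all_kernels(self, name, rng):
        X = sk.center_scale(rng.binomial(2, 0.35, (25, 18)).astype(float))
        cfg = KernelConfig(name)
        d = sk.sparse_design(X, cfg, SparseKernelSpec(0.4, seed=7))
        Q = sk.reconstruct_kernel(d)
        oracle = pinv_oracle(X, d.config, np.array(d.anchor_ids))
        err = np.linalg.norm(Q - oracle) / max(np.linalg.norm(oracle), 1e-12)
        assert err < 1e-7

    def test_singular_anchor_kernel_errors(self):
        X = np.zeros((6, 3))
        with pytest.raises(ValueError, match="singular"):
            sk.sparse_design(X, KernelConfig("linear"), SparseKernelSpec(0.5, seed=0))

    def test_rank_bounded_by_anchor_count(self, scaled_markers):
        d = sk.sparse_design(scaled_markers, KernelConfig("gaussian"),
                             SparseKernelSpec(0.5, seed=0))
        assert d.P.shape[1] <= d.m
        assert np.linalg.matrix_rank(sk.reconstruct_kernel(d)) <= d.m


class TestReconstruction:
    def test_psd_by_construction(self, scaled_markers):
        d = sk.sparse_design(scaled_markers, KernelConfig("arc_cosine"),
                             SparseKernelSpec(0.5, seed=4))
        Q = sk.reconstruct_kernel(d)
        w = np.linalg.eigvalsh(Q)
        assert np.allclose(Q, Q.T) and w.min() >= -1e-8 * max(w.max(), 1.0)

    def test_nested_anchor_error_is_monotone(self, rng):
        """||K - Q||_F is non-increasing as the anchor set grows along a
        fixed shuffled order (the compression-sweep design)."""
        X = sk.center_scale(rng.binomial(2, 0.3, (30, 25)).astype(float))
        cfg = KernelConfig("arc_cosine")
        K = compute_kernel(X, None, cfg)
        perm = rng.permutation(30)
        errs = []
        for prop in (0.5, 0.6, 0.7, 0.8, 0.9, 1.0):
            m = int(np.ceil(prop * 30))
            d = sk.sparse_design(X, cfg, anchor_ids=perm[:m].tolist())
            errs.append(np.linalg.norm(K - sk.reconstruct_kernel(d)))
        assert all(errs[i] >= errs[i + 1] - 1e-8 for i in range(len(errs) - 1))

    def test_ridge_on_full_anchor_design_matches_dense_sqrt(self, small_trial):
        """With m = n the compressed design spans the same feature Gram as
        the dense kernel square root, so ridge predictions coincide."""
        X, pheno, _ = small_trial
        Xs = sk.center_scale(X.to_numpy(float))
        y = pheno["Trait"].to_numpy()
        cfg = KernelConfig("linear")
        D_dense = kernel_sqrt(compute_kernel(Xs, None, cfg))
        P = sk.sparse_design(Xs, cfg, SparseKernelSpec(0.0)).P
        tr = np.arange(0, len(y), 2)
        te = np.arange(1, len(y), 2)
        p1 = Ridge(alpha=1.0).fit(D_dense[tr], y[tr]).predict(D_dense[te])
        p2 = Ridge(alpha=1.0).fit(P[tr], y[tr]).predict(P[te])
        assert np.corrcoef(p1, p2)[0, 1] > 0.999


class TestNystromApproximatorEstimator:
    def test_fit_transform_equals_sparse_design(self, scaled_markers):
        est = NystromApproximator(kernel="gaussian", compression_level=0.4, seed=2)
        P_est = est.fit_transform(scaled_markers)
        d = sk.sparse_design(scaled_markers, KernelConfig("gaussian"),
                            SparseKernelSpec(0.4, seed=2))
        assert np.allclose(np.abs(P_est), np.abs(d.P), atol=1e-8)

    def test_sklearn_pipeline_composition(self, small_trial):
        X, pheno, _ = small_trial
        y = pheno["Trait"].to_numpy()
        pipe = make_pipeline(
            sk.MarkerScaler(),
            NystromApproximator(kernel="gaussian", compression_level=0.5, seed=0),
            Ridge(alpha=1.0),
        )
        pipe.fit(X.to_numpy(float), y)
        preds = pipe.predict(X.to_numpy(float))
        assert preds.shape == y.shape
        assert np.corrcoef(preds, y)[0, 1] > 0.3

    def test_get_set_params_roundtrip(self):
        est = NystromApproximator(kernel="arc_cosine", compression_level=0.3)
        params = est.get_params()
        est2 = NystromApproximator(**params)
        assert est2.get_params() == params


class TestSerialization:
    def test_save_roundtrip(self, tmp_path, scaled_markers):
        d = sk.sparse_design(scaled_markers, KernelConfig("linear"),
                             SparseKernelSpec(0.5, seed=1))
        d.save(tmp_path / "design.csv")
        import json
        import pandas as pd

        frame = pd.read_csv(tmp_path / "design.csv", index_col=0)
        meta = json.loads((tmp_path / "design.json").read_text())
        assert frame.shape == d.P.shape
        assert len(meta["anchor_ids"]) == d.m
        assert meta["compression_level"] == 0.5
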