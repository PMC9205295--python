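# sparsekernels

Sparse (Nyström) kernel machines for genome-based prediction.

In genomic selection, a breeder predicts a line's phenotype (e.g. grain
yield) from genome-wide marker dosages in order to rank candidates without
phenotyping all of them. Kernel methods are a natural fit — the genomic
relationship matrix **K** = XX′/p *is* a kernel — but a dense n × n kernel
becomes expensive as the number of lines grows, and most machine-learning
libraries cannot consume a kernel directly.

`sparsekernels` addresses both problems:

- **Seven kernels** on centered/scaled marker matrices: linear, polynomial,
  sigmoid, gaussian, exponential and arc-cosine of depth L (the
  infinite-width-network kernel, applied recursively).
- **The kernel square-root trick**: any learner becomes a kernel machine by
  training on Z K^{1/2}, where Z is the observation-to-line incidence
  matrix.
- **Sparse (compressed) kernels**: from m anchor lines, the Nyström
  approximation Q = K_nm K_mm⁻¹ K_nm′ yields a projected design
  P = K_nm U S^{−1/2} with at most m columns (K_mm = U S U′), so training
  cost shrinks with the *compression level* 1 − m/n at little cost in
  accuracy.
- **Learners** behind one `fit(model_name, X, y)` interface: boosted
  machines (xgboost), penalized linear models, SVMs, random forests
  (scikit-learn), plus in-package Gibbs samplers for **Bayesian ridge
  regression** (y = μ1 + Xβ + e, β ~ N(0, σ_β²I)) and **Bayesian GBLUP**
  (y = μ1 + Zu + e, u ~ N(0, σ_u²K)) — equivalent in prediction when
  K = XX′/p.
- **Tuning** by nested inner k-fold CV: exhaustive grid search or Bayesian
  optimization (Gaussian-process surrogate, expected improvement).
- **Metrics**: MSE, RMSE, NRMSE (by sd/mean/range/IQR), MAE, MAAPE, and a
  full classification suite (accuracy, sensitivity, specificity, kappa,
  Brier, MCC, precision/recall, ROC-AUC, PR-AUC, F1, confusion matrix).
- **Benchmarking**: random 80/20 partitions stratified by environment,
  per-environment and Global mean ± SE summaries, and the percent-
  outperformance comparison arithmetic.
- **Synthetic data**: SNP dosages at configurable MAF with additive or
  epistatic architectures, a target heritability h² = σ_u²/(σ_u²+σ_e²) and
  environment main effects, so every stage is testable with known truth.

Core components are scikit-learn estimators (`MarkerScaler`,
`NystromApproximator`, `BayesianRidgeGibbs`, `GBLUPRegressor`) and compose
with sklearn pipelines; module-level functions wrap them.

## Worked example

```python
import pandas as pd
import sparsekernels as sk

# a synthetic 200-line x 300-marker trial over 4 environments, h2 = 0.5
cfg = sk.SimConfig(n_lines=200, p_markers=300, h2=0.5, n_env=4, seed=7)
X, pheno, truth = sk.simulate_dataset(cfg)
Xs = sk.center_scale(X.to_numpy(float))

# arc-cosine kernel compressed at level 0.5 (half the lines as anchors)
design = sk.sparse_design(Xs, sk.KernelConfig("arc_cosine"),
                          sk.SparseKernelSpec(compression_level=0.5, seed=7),
                          line_ids=list(X.index))
print("sparse design:", design.P.shape)

# benchmark: random forest on the compressed design vs Bayesian GBLUP on
# the linear kernel, 5 random 80/20 partitions
K = pd.DataFrame(Xs @ Xs.T / Xs.shape[1], index=X.index, columns=X.index)
preds_rf = sk.run_benchmark(pheno, design.to_frame(), ["random_forest"],
                            reps=5, seed=7, kernel_for=())
preds_gb = sk.run_benchmark(pheno, K, ["bayesian_gblup"], reps=5, seed=7)
summary = sk.summaries(pd.concat([preds_rf, preds_gb], ignore_index=True))
print(summary[(summary.env == "Global") & (summary.metric == "MSE")])
```

prints

```
sparse design: (200, 100)
         model metric    env     mean       SE
 random_forest    MSE Global 2.597316 0.059351
bayesian_gblup    MSE Global 2.122862 0.058372
```

i.e. a 100-column compressed design in place of the 200 × 200 kernel, and
Global MSE averaged over the five test partitions with its standard error
(the phenotypic variance here is ≈ 2 because environment main effects with
sd 1 sit on top of a unit-variance genetic-plus-residual signal). The
comparison arithmetic

```python
sk.percent_outperformance(2.597316, 2.122862)   # -> 18.26
```

says GBLUP outperforms the random forest by 18.26% in Global MSE.

A CLI mirrors the four workflows:

```sh
sparsekernels simulate --out-dir sim --n-lines 200 --p-markers 300
sparsekernels kernelize --markers sim/markers.csv --kernel arc_cosine --compression 0.5 --out P.csv
sparsekernels benchmark --markers sim/markers.csv --phenotypes sim/pheno.csv --models bayesian_gblup
sparsekernels summaries --predictions benchmark_run/predictions.csv --out summary.csv
```

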