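# hemopipe

A decision-support toolkit for classifying acute lymphoblastic leukemia
(ALL) in stained blood-smear microscopy, built as four composable stages:

1. **Contrast enhancement** — a neighborhood pixel transform on the HSI
   intensity channel,
   `f(m,n) = (δ·μ/(σ_p+β))·(I − γ·μ_p) + μ_p^α`,
   whose parameters (α, β, γ, δ) are tuned per image by greedy
   differential evolution maximizing an edge/entropy objective
   `F = log(log(G+e))·n_e·H/(M·N)`.
2. **Deep-feature extraction and fusion** — pooled activations of
   InceptionV3 (2,048-dim) and DenseNet201 (1,920-dim) concatenated into
   a 3,968-dim fused vector. A deterministic, content-sensitive mock
   extractor makes the whole pipeline runnable without model weights or
   downloads; real CNN inference is an optional `cnn` extra.
3. **Wrapper feature selection** — a binary Grey Wolf optimizer over
   column masks minimizing `Γ = 0.99·e + 0.01·(q_s/q_t)`, where `e` is
   the stratified-holdout error of an inner k-NN (k = 5) and `q_s/q_t`
   penalizes mask size; a genetic-algorithm baseline runs on the same
   fitness for convergence comparison.
4. **Classification and metrics** — floor-rule 70:30 stratified splits,
   k-NN/SVM/tree/MLP presets, and confusion-matrix reporting with
   per-class TPR/FNR/precision and macro-averaged accuracy, sensitivity,
   precision, recall and F1.

It is aimed at researchers studying metaheuristic feature selection and
enhancement for hematology imaging who need a reproducible, fixture-driven
reimplementation of this pipeline rather than a clinical tool. Synthetic
generators (low-contrast cell images, planted-signal feature matrices,
count-matched augmentation) stand in for the clinical datasets.

## Worked example

Feature selection on a planted fixture — 10 informative columns with
3σ class separation hidden among 90 noise columns (see
`examples/select_features.py`; all examples are narrative scripts you can
run directly):

```python
from hemopipe import (GWOConfig, GAConfig, PlantedFeatureSpec,
                      gwo_select, ga_select, make_feature_dataset)

features, truth = make_feature_dataset(PlantedFeatureSpec(
    classes=2, per_class=60, dims=100, informative=10, effect=3.0, seed=0))
gwo_mask, gwo_hist = gwo_select(features, GWOConfig(n_pop=20, t_max=50), seed=0)
ga_mask, ga_hist = ga_select(features, GAConfig(n_pop=20, t_max=50), seed=0)
```

prints

```
GWO: Gamma 0.0035 -> 0.0034, selected 34/100 features, informative hit rate 0.40, noise hit rate 0.33
GA : Gamma 0.0035 -> 0.0003, selected 3/100 features, informative hit rate 0.20, noise hit rate 0.01
```

Γ near `0.01·q_s/q_t` means the holdout k-NN error is zero and only the
parsimony term remains; the informative hit rate exceeding the noise hit
rate shows the wrapper retains signal columns preferentially while
pruning. In this zero-error regime the GA's free bit-flips prune harder
than the GWO update (whose OR-with-leader step cannot clear a bit once
all three leaders carry it) — see `docs/methods.md` for the analysis.

Enhancement on a low-contrast synthetic smear
(`examples/enhance_cell_image.py`):

```
input image objective      F = 4.237 (G=491.3, n_e=1873, H=5.08)
enhanced image objective   F = 12.490 (G=1570.1, n_e=3827, H=6.70)
tuned parameters: alpha=1.600 beta=0.057 gamma=0.800 delta=0.500
intensity range stretched from 0.28 to 0.68
```

The tuned transform roughly doubles the edge count and adds 1.6 bits of
histogram entropy — cell boundaries that were nearly invisible now carry
gradient.

The same stages are available from the shell:

```bash
hemopipe simulate features --dims 100 --informative 10 --seed 1 --out feat
hemopipe select --features feat --algo gwo --seed 1 --out mask.txt
hemopipe evaluate --features feat --mask mask.txt --clf knn-fine --seed 1 --out report.json
hemopipe run-all --config pipeline.yaml
```

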