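# evoslide

Supervised evolutionary dimensionality reduction for whole-slide-image (WSI)
classification.

Distinguishing the two main non-small-cell lung cancer subtypes —
adenocarcinoma (AC) and squamous cell carcinoma (SCC) — from H&E-stained
whole-slide images is a standard but non-trivial task in computational
pathology. WSIs are processed patch-wise: tiles are gated by tissue and
tumor content, featurized with a backbone network, and aggregated into a
slide-level prediction. High-dimensional patch features are expensive to
aggregate and are not organized for class separability.

`evoslide` addresses this with a *supervised* linear dimensionality
reduction: an evolutionary algorithm searches for a projection matrix
**W** ∈ ℝ^(d_in × d_out) that maximizes the silhouette score of the
projected patch features against the known slide labels,

    S = (1/n) Σᵢ (bᵢ − aᵢ) / max(aᵢ, bᵢ)

where aᵢ is the mean distance from sample *i* to its own class and bᵢ the
smallest mean distance to another class. The search is a real-valued
evolutionary loop: Gaussian-initialized population, silhouette fitness,
top-k selection, parent-averaging crossover (rate ρ), additive Gaussian
mutation (rate μ, scale σ), and worst-replacement with elitism. Unlike PCA
(variance-maximizing, label-blind) or LDA (fixed parametric form, at most
C−1 dimensions), the evolutionary search optimizes class separability
directly in an unconstrained space of linear maps.

The projection is embedded in a complete pipeline:

1. **Tissue masking** — Sobel gradient → Otsu threshold → morphological
   opening → hole filling (plus small-fragment removal).
2. **Patch gating** — sliding-window tiles kept iff tissue fraction > 10%
   and tumor likelihood > 50% (pluggable tumor scorer).
3. **Featurization** — deterministic 96-D histogram extractor built in;
   adapter for pretrained CNN backbones (e.g. a 1024-D DenseNet121
   embedding).
4. **Projection** — the evolved **W** (default d_out = 2), with PCA/LDA
   baselines.
5. **Spatial graphs** — per-slide node features padded to a fixed size,
   radius-neighbor edges from patch centers (KD-tree), symmetric
   normalization Â = D^(−1/2)(A+I)D^(−1/2).
6. **Classifier heads** — 1D-CNN (reference), 2D-CNN, graph-convolutional
   network, gated-attention MIL, a TransMIL-style transformer head, and
   classical heads (DT/RF/SVM/XGBoost) on mean-aggregated features; all
   trained with Adam, categorical cross-entropy, balanced batches, and
   early stopping on validation loss.

Because the original patient cohorts are not public, the package ships a
first-class synthetic data module: labeled feature sets whose class signal
sits on low-variance axes (the regime where PCA fails and supervised
search succeeds) and miniature textured "slides" with ground-truth tissue
and tumor masks, so every pipeline stage runs end to end with no
downloads. The neural heads run on a small built-in NumPy autodiff engine.

## Worked example

```bash
python examples/01_optimize_projection.py
```

```
initial best fitness : +0.0148
final best fitness   : +0.7416
EA 2-D silhouette    : +0.7416
PCA 2-D silhouette   : -0.0014
```

The feature family has 400 samples in 20 dimensions; the class signal is a
mean shift of 6 on one axis of spread 0.5, buried under 19 nuisance axes
of spread 5. PCA's two components follow the nuisance variance and carry
no class information (silhouette ≈ 0); the evolved projection (population
5, 300 generations, μ = 0.8, ρ = 0.4, σ = 0.1) reaches a silhouette of
about 0.74 — clearly separated classes in 2-D.

The full pipeline on 24 synthetic slides (12 AC-like / 12 SCC-like,
16/4/4 stratified split):

```bash
python examples/05_full_pipeline.py
```

```
EA train silhouette    : 0.894
tissue mask mean Dice  : 0.955
train accuracy         : 1.000
test accuracy          : 1.000
```

Each `examples/` script exercises one capability (projection search,
masking and gating, graph construction, classifier heads, full pipeline).
A thin CLI chains the same stages through artifact directories:

```bash
evoslide all --config demo.yaml --out run1 --seed 1
```

## Layout

- `src/evoslide/` — library (`silhouette`, `evolve`, `projections`,
  `synthetic`, `preprocess`, `features`, `graphs`, `heads`, `nn`,
  `training`, `pipeline`, `cli`)
- `examples/` — one narrative script per capability
- `docs/methods.md` — models, parameters, and design notes
- `tests/` — pytest suite including acceptance checks
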