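# Methods

## The projection search

The core method is a supervised linear dimensionality reduction. Given
patch features X ∈ ℝ^(n×d_in) and per-patch class labels y (each patch
inherits its slide's label), we seek W ∈ ℝ^(d_in×d_out) maximizing the
silhouette score of X·W against y.

**Silhouette.** For sample *i*, aᵢ is the mean Euclidean distance to the
other members of its class and bᵢ the smallest mean distance to any other
class; sᵢ = (bᵢ − aᵢ)/max(aᵢ, bᵢ) and S is the mean over samples. Two
degenerate cases need conventions because the zero matrix is reachable
during the search: a singleton-class sample contributes sᵢ = 0, and if
max(aᵢ, bᵢ) = 0 (all points involved coincide, e.g. W = 0) then sᵢ = 0.
So the zero projection has fitness 0 rather than raising an error.

**Evolutionary loop.** Population of P matrices with i.i.d. N(0, 1/d_in)
entries; each generation: evaluate fitness, keep the top ⌈P/2⌉ as parents,
breed ⌊P/2⌋ offspring by cycling over ordered parent pairs — elementwise
parent mean with probability ρ, else a copy of the first parent — then
perturb each offspring with additive N(0, σ²) noise with probability μ,
and replace the worst ⌊P/2⌋ candidates. With at least one elite retained
and fitness computed on the full data, the best fitness is non-decreasing
by construction; this invariant is asserted in the tests.

Defaults follow the reference protocol: P = 5, μ = 0.8, ρ = 0.4, and a
generation limit of 30,000 for production-scale runs (the demo pipeline
and tests use 200–300 generations, which suffices at the sizes involved
here). σ is a free parameter of this implementation (default 0.1, about
10% of the initial weight scale); `subsample_fraction` < 1 scores every
candidate of a generation on one shared random subsample, mirroring
per-generation patch sampling at scale, and defaults to 1.0 so runs are
strictly monotone and reproducible. d_out defaults to 2; the output
dimension is chosen manually, which is a known limitation of the method.

**Baselines.** PCA via SVD of the centered feature matrix with a
deterministic sign convention (largest-magnitude loading positive); LDA
via the generalized symmetric eigenproblem S_b v = λ S_w v with an
optional ridge on S_w, yielding at most C − 1 dimensions.

## Pipeline stages

**Tissue masking.** Sobel gradient magnitude → Otsu threshold on the
gradient → morphological opening (disk, radius 2 thumbnail pixels) → hole
filling → removal of components of 64 pixels or fewer. The last step is a
refinement added here: opening leaves occasional boundary crumbs of a few
dozen pixels that would otherwise appear as spurious tissue islands. A
constant thumbnail (degenerate Otsu) yields an empty mask and a warning.
The method assumes a slide with visible background; on a frame entirely
filled with tissue, Otsu splits within-texture gradients and the mask
degrades.

**Patch gating.** Sliding-window boxes (half-open, row-major, 0-based,
windows fully inside the slide). A patch is retained iff its tissue
fraction exceeds 0.10 *strictly* and the tumor scorer's probability
exceeds 0.50 strictly — boundary values drop. The tumor scorer is an
interface; the shipped scorer is a synthetic oracle returning the
tumor-mask fraction of the box. Patch size and stride default to the
patch grid of the synthetic slides (32 px); against real slides they are
configuration values (the reference setup resizes patches to 224 px
anyway).

**Features.** The built-in extractor computes a 64-bin intensity
histogram plus a 32-bin gradient-orientation histogram (magnitude
weighted), each L1-normalized — d_in = 96, deterministic, no downloaded
weights. A pretrained backbone can be plugged in as a callable mapping a
patch batch to a feature matrix. Augmentation is restricted to
label-preserving pixel permutations (flips, right-angle rotations), which
leave the intensity histogram exactly invariant.

**Graphs.** Nodes are retained patches in raster order, trimmed to the
first N_max or zero-padded; N_max is the largest training-slide node count
and is persisted with the model. Edges connect patch centers within
radius stride × 1.05 (inclusive), i.e. a 4-neighborhood on a regular
tiling; built with a KD-tree and validated against all-pairs search.
Normalization Â = D^(−1/2)(A+I)D^(−1/2) is computed over real nodes only;
the padded block of Â is the identity so batched tensors stay well-formed
and padded content cannot leak into real nodes. Graphs persist as
versioned JSON containers with a sha256 payload checksum.

**Heads.** All neural heads run on a small reverse-mode autodiff engine
over NumPy (float64, deterministic). Reference widths, absent from any
external specification, are fixed small defaults: 1D-CNN convolutions of
32 and 64 filters (kernel 3) along the node axis, max-pool 2, global
average pool over the *full padded axis* (plain zero padding), dense
softmax; 2D-CNN with 8/16 filter 3×3 blocks on the (N_max, d_out, 1)
"image"; GCNN with two Â-propagated layers (16, 32) and mask-aware mean
pooling; gated-attention MIL with eₖ = wᵀ(tanh(V hₖ) ⊙ σ(U hₖ)) and
masked softmax weights; TransMIL-style head with a learnable class token,
trainable positional embedding, and two single-head transformer encoder
blocks (width 64, FFN 128) with padding-mask-aware attention — the
original TransMIL's Nyström attention and pyramid position encoding are
deliberately not reproduced. Classical heads (decision tree, random
forest, SVM, XGBoost) consume the mask-aware mean of node features and
delegate to scikit-learn / xgboost.

**Training.** Adam (lr 0.001), categorical cross-entropy, up to 400
epochs, batch size 8, early stopping with patience 20 on validation loss,
restoring the best epoch's weights. Every batch holds exactly half of
each class; the larger class is covered once per epoch in shuffled order
and the smaller is oversampled with replacement. Slide prediction
thresholds P(class 1) at 0.5 strictly (the boundary goes to class 0).
Metrics: accuracy at 0.5, rank AUC with half credit for ties, macro-F1;
Dice = 2|A∩B|/(|A|+|B|) with the both-empty case defined as 1.

## Synthetic data: what it emulates and what it does not

`gen_feature_set` draws two Gaussian classes whose mean offset
(`separation_delta`, default 6) lies on designated low-variance axes
(spread 0.5) under high-variance nuisance axes (spread 5). This is the
regime the method targets: class-discriminative directions that
variance-based projections discard. It does not emulate feature
correlations, heavy tails, or batch effects of real CNN embeddings.

`gen_slide` renders miniature slides: uniform gray background at level
230 (zero gradient — excluded by masking), and per-patch textures on
tissue — class 0 gets isotropic Gaussian blobs (contrast 140), class 1
oriented stripes (period patch/2, contrast 40, mean level lowered by 50).
A two-axis sinusoidal carrier (period 8 px, amplitude 30) rides on all
tissue so the gradient magnitude is high at essentially every tissue
pixel; without it, threshold speckle would not survive the morphological
opening. Tumor regions are random subsets (~75%) of tissue; the tumor
scorer oracle reads them directly. Passing tests on these slides
demonstrates the pipeline's mechanics (masking, gating, graph building,
training) and the projection's behavior, not histological realism:
staining variation, artifacts, scanner differences, and inter-patient
heterogeneity are out of scope.

The demo study conditions are 24 slides (12 per class) on 8×8 grids of
32-px patches, split 16/4/4 stratified; the evolutionary stage runs 200
generations on the training split's patches. These sizes were chosen as
the smallest at which every stage is exercised meaningfully.

## Numerical and design notes

- All randomness flows from explicit `numpy.random.Generator` seeds; the
  pipeline derives one seed per stage from the global seed via
  `SeedSequence([global_seed, stage_index])`, so stages are independently
  reproducible and a rerun is byte-identical.
- Selection ties break toward the lower candidate index; the crossover
  fallback when the ρ-coin fails is a copy of the first parent.
- Matrix files store a JSON header plus a text payload written with
  `repr`, so save/load round-trips are bit-exact.
- The spatial graph boundary is inclusive: nodes at distance exactly
  equal to the radius are connected.
- The LDA ridge is opt-in; a singular within-class scatter without a
  ridge raises rather than silently regularizing.
- Known limitations: linear projections only (no nonlinear transform
  family); d_out fixed by hand; the MIL/TransMIL bags in the demo contain
  one embedding per graph; no interpretability maps.
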