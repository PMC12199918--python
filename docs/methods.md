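# Methods

`lmipredict` predicts lncRNA–miRNA interactions (LMIs) by fusing two views
of every RNA: a *graph view* built from multi-source similarity matrices and
a *sequence view* built from multiscale k-mer tokenizations. This note
documents the model, its assumptions, the tunable parameters, the synthetic
data it is validated on, and the numerical choices made where the design was
genuinely open.

## Model

### Similarity graphs and the GCN view

For each RNA class (lncRNA, miRNA) three entity–entity similarity matrices
are built:

- **Sequence similarity** `1 − lev(s_i, s_j) / max(|s_i|, |s_j|)`, where
  `lev` is the Levenshtein edit distance. Max-length normalization is the
  standard bounded variant; it keeps values in [0, 1] for sequences of very
  different lengths.
- **Expression similarity** `(1 + r_ij) / 2` with `r_ij` the Pearson
  correlation of expression profiles. The affine map guarantees
  non-negative edge weights — required by the symmetric graph
  normalization below — while preserving the ordering of correlations.
  An absolute-value map was rejected because it conflates positive and
  negative co-expression. Zero-variance profiles get similarity 0 off the
  diagonal (correlation is undefined there; treating such entities as
  unrelated is the conservative choice).
- **GIP kernel similarity** `exp(−γ‖IP_i − IP_j‖²)` over binary interaction
  profiles (rows/columns of the training adjacency), with
  `γ = 1 / mean_k ‖IP_k‖²` — the standard interaction-profile kernel
  construction. Only *training* positives enter the adjacency, so
  validation interactions never leak into the features.

Each matrix is sparsified by a **mutual p-nearest-neighbour** rule
(default p = 10, config-exposed): an edge keeps its weight if both
endpoints select each other among their top-p neighbours, half weight if
only one does, and is dropped otherwise. The mutual/one-sided weighting
preserves symmetry, which the GCN's symmetric normalization requires; ties
are broken deterministically by lower index.

A two-layer GCN runs independently on each refined graph with the
renormalized propagation matrix `D^{−1/2}(I + S)D^{−1/2}` and ReLU. Two
layers and width 64 follow the method's parameter study; the initial node
features are the refined similarity rows themselves — a parameter-free
choice that makes layer-0 width equal the entity count and keeps entities
with similar neighbourhood profiles close from the start. The three graph
channels per class form the GCN view.

### k-mer Transformer view

Sequences (T normalized to U) are tiled-and-truncated to a common length
and tokenized into overlapping stride-1 k-mers at k = 2, 3, 4 (base-4 token
ids, A=0 C=1 G=2 U=3). One-hot encoding is realized as an embedding lookup
(mathematically one-hot × weight matrix) to avoid materializing 4^k-wide
tensors. Sinusoidal positional encodings are added, and a two-layer
post-norm Transformer encoder (4 heads, FFN width 128) processes each scale
with its own weights; mean pooling over positions yields one 64-d vector
per entity per scale. Nothing is shared across scales or RNA classes.

Two layout choices that do not change the math:

- Scale k aligns sequences to `P + k − 1` nucleotides so that all three
  scales emit exactly `P` tokens. One shared position axis lets the three
  per-scale weight sets be evaluated as a single batched computation (they
  remain separate parameters), and one positional table serves all scales.
- Multi-head projections fold the head axis into one matrix product before
  splitting heads out, which is the usual efficient attention layout.

### Channel attention and fusion

Each view's three channels pass through squeeze-excitation channel
attention: global average pooling per channel, a two-layer ReLU/sigmoid
gate (no bottleneck — with t = 3 channels a reduction ratio is
meaningless), rescaling, and a learnable 1×1 cross-channel convolution
(weighted channel sum) that produces a single entities × 64 matrix per view
per class. The per-class GCN and Transformer outputs are concatenated
GCN-first into 128-d entity embeddings `L*` and `M*`.

### Cross-view contrastive loss

The two views of the same entity form a positive pair; all other vectors in
both views (including the other RNA class) are negatives. Each of the
2·(n_l + n_m) vectors anchors one term

    −log  exp(z_r·z_p / T) / Σ_{n ≠ r} exp(z_r·z_n / T)

on L2-normalized linear projections of the channel-fused features
(temperature T = 0.5 by default, config-exposed). The mean over anchors is
used; anchors are drawn from both views symmetrically. A linear projection
per view decouples the contrastive geometry from the classifier features.
The denominator always spans the full entity set — at desk scale there is
no need to subsample it.

### KAN scoring head and objective

Pair scores are `σ(KAN(concat(L*_i, M*_j)))` with a two-layer
Kolmogorov–Arnold network (widths 256 → 32 → 1). Each KAN layer computes
`W_base·SiLU(x) + W_spline·B(x)` where `B` is the cubic B-spline basis over
a uniform 5-interval grid on [−2, 2]; inputs are clamped to the grid range
so the basis always has support (no runtime grid adaptation). Spline
weights start at 0.1× their Glorot draw so training begins near the smooth
base path. A score above 0.5 is called an interaction.

The objective is the unweighted sum of the contrastive loss and the binary
cross-entropy of the pair scores (probabilities clamped at 1e-7). All
parameters — GCN, Transformer, channel attention, projections, KAN — train
jointly with Adam at learning rate 1e-3 for 100 epochs, in minibatches of
128 pairs; the entity-level forward pass is recomputed every step and the
contrastive term is evaluated on the full entity set each step. Training is
implemented on a small reverse-mode automatic-differentiation engine over
numpy written for this package; its gradients are pinned against central
differences in the test suite.

Batch size matters here: with one full-batch step per epoch the optimizer
takes only 100 steps and stalls on the initial plateau where the
contrastive term dominates; ~400 minibatch steps reliably cross it. This
was measured, not assumed, and is why minibatch training is the default.

## Evaluation protocol

- **Hot start**: stratified pair-level k-fold CV (label proportions within
  ±1 pair per fold). Stratification keeps per-fold class ratios stable on
  imbalanced 1:5 / 1:10 datasets.
- **Cold start**: the centred entity class is partitioned into k groups;
  each fold's validation set is *every* pair touching that group's
  entities, the training set is the rest. No pair is dropped, and
  `check_cold_start` verifies that no centred-class entity occurs in both a
  training and a validation pair of any fold.
- **Negative sampling**: uniform over unobserved cells of the interaction
  matrix, once per dataset (the ratio-controlled datasets are fixed before
  splitting), with the seed recorded in the run manifest.
- Metrics: ACC, recall, precision, F1 at threshold 0.5; ROC-AUC
  (trapezoidal, rank-averaged ties) and AUPR (precision-recall step
  integration), via scikit-learn, cross-checked in the tests against
  hand-rolled rank statistics.

## Synthetic data

The generator emulates the statistical structure the model assumes, at desk
scale (defaults: 80 lncRNAs × 40 miRNAs, lncRNA length 400, miRNA length
22, 50 expression conditions, 10% positive density):

- **Sequence signal.** Every miRNA has a seed region (positions 2–8 for the
  default motif length 7). For each interacting pair the reverse complement
  of the seed is implanted at a random position of the lncRNA, with
  per-base substitution at rate `noise`. Implants within one lncRNA are
  placed without overlap so every partner keeps an intact site. This
  mimics seed-site complementarity without modelling thermodynamics.
- **Module structure.** Interactions are planted within matched
  lncRNA × miRNA co-regulation modules (default 8), and each module shares
  a latent expression factor mixed at weight √ρ. Interacting pairs then
  have expected Pearson correlation ≈ `expr_rho` (default 0.8). Modules
  are not a convenience: an entity of degree d cannot be strongly
  correlated with d mutually independent partners (squared correlations
  with orthogonal factors sum to at most 1), so *some* shared structure is
  mathematically forced, and co-expressed interaction modules are the
  biologically natural form.

What the generator does **not** emulate: realistic transcript length and
composition distributions, secondary structure, expression count noise,
database biases, or hub-degree distributions. Passing the end-to-end tests
shows the pipeline recovers planted structure of this kind at this scale;
it does not certify performance on real corpora.

`difficulty_report` summarizes separability: the positive-vs-negative gap
in best seed-site complementarity (via infix edit distance of the
reverse-complemented seed) and in pairwise expression correlation.

## Desk-scale problem sizes

The shipped evaluation profile trains the full model on the default
synthetic corpus with sequences aligned to 16 nt per scale
(13 tokens per scale), batch 128, 100 epochs — small enough that the whole
five-fold, three-seed protocol runs on one CPU core in minutes, large
enough that the planted structure is recovered (hot-start AUC ≈ 0.93–0.99).
The alignment length is deliberately the strongest scale reduction in the
package: at 400 nt (the real-data default) the Transformer sees whole
transcripts, at 16 nt it sees a fixed-length excerpt; the graph view, which
carries most of the desk-scale signal, is unaffected. All lengths are
config-exposed.

## Numerical choices

- float32 parameters and activations for training (float64 throughout the
  oracle and gradient-check tests); Adam moments in float64.
- Probability clamp 1e-7 in the BCE; attention softmax is max-shifted; the
  contrastive log-sum-exp subtracts a detached row max.
- p-NN ties: higher similarity first, then lower index — deterministic.
- Zero-variance expression profiles: similarity 0 off-diagonal (see above).
- An all-zero adjacency makes the GIP bandwidth undefined and is rejected
  as degenerate input.
- Glorot-uniform initialization everywhere; per-component seeding from a
  single `random_state` makes same-device runs bit-reproducible.

## Known limitations

- Full dense similarity matrices and dense attention: O(n²) memory in
  entities and tokens; the implementation targets desk scale (hundreds of
  entities), not the tens of thousands where sparse message passing would
  be needed.
- Benchmarks on real corpora (thousands of entities assembled from
  GENCODE/LNCipedia/miRbase/NONCODE/lncRNASNP2) require those database
  downloads; loaders for the formats are provided but results on them are
  out of scope here.
- Sequence-view contribution at desk scale is modest: with long lncRNAs
  truncated to short aligned windows, most planted sites fall outside the
  window, and the graph view dominates. Ablations reflect this.
- Training cost scales linearly in epochs × minibatches × entity count;
  there is no early stopping (the protocol fixes 100 epochs).
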