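# lmipredict

Multimodal contrastive representation learning for predicting
lncRNA–miRNA interactions (LMIs).

Long non-coding RNAs regulate transcription and chromatin state; miRNAs
silence transcripts post-transcriptionally. Their direct interactions —
e.g. a lncRNA sponging a miRNA — shape disease-relevant regulatory
networks, but testing candidate pairs experimentally is slow. This package
predicts interacting pairs computationally by fusing two complementary
views of every RNA and scoring pairs with a learned classifier. It is
aimed at computational biologists who have sequences, expression profiles,
and a partial interaction catalogue, and want ranked candidate pairs plus a
rigorous cross-validation harness (including cold-start protocols for
entirely unseen RNAs).

## The model

For each RNA class, three entity–entity similarity matrices are built —
normalized Levenshtein sequence similarity, Pearson expression similarity
mapped to `(1+r)/2`, and the Gaussian interaction-profile (GIP) kernel
`exp(−γ‖IP_i − IP_j‖²)` over the training adjacency — then sparsified by a
mutual p-nearest-neighbour rule. A two-layer GCN with renormalized
propagation `D^{−1/2}(I+S)D^{−1/2}` encodes each graph (**graph view**,
three channels). In parallel, sequences are tokenized into overlapping
k-mers at k = 2, 3, 4, embedded with sinusoidal positional encodings, and
passed through a per-scale Transformer encoder with mean pooling
(**sequence view**, three channels).

Squeeze-excitation channel attention fuses each view's channels into one
64-d embedding per entity; the per-class concatenations `L*` and `M*`
(128-d) feed a two-layer Kolmogorov–Arnold network (KAN),
`KAN(x) = W_base·SiLU(x) + W_spline·B(x)` with a cubic B-spline basis, and
a sigmoid turns the logit of `concat(L*_i, M*_j)` into an interaction
probability (threshold 0.5). Training jointly minimizes

    L_total = L_con + L_BCE

where `L_con` is a cross-view supervised contrastive loss (the two views
of the same entity are positives; every other vector in either view,
including the other RNA class, is a negative; cosine similarities at
temperature T = 0.5) and `L_BCE` is the binary cross-entropy of the pair
scores. Everything — GCN, Transformer, attention gates, projections, KAN —
trains end to end with Adam (lr 1e-3, 100 epochs, minibatches of 128
pairs) on a small numpy reverse-mode autodiff engine included in the
package. See `docs/methods.md` for assumptions, parameter defaults, and
numerical details.

Because real corpora require external database downloads, the package
ships a first-class synthetic generator (`lmipredict.synthetic`) that
plants the structure the model assumes: miRNA seed regions whose reverse
complements are implanted in interacting lncRNAs (with tunable substitution
noise), and module-structured expression profiles whose correlation for
interacting pairs targets a chosen ρ.

## Worked example

Generate a synthetic corpus (80 lncRNAs × 40 miRNAs, 10% interaction
density, 1:1 negative sampling) and run five-fold hot-start
cross-validation:

```bash
lmipredict simulate --seed 1 --ratio 1 --out demo_corpus
cat > train.yaml <<EOF
aligned_len: 16
batch_size: 128
epochs: 100
EOF
lmipredict evaluate --data demo_corpus --config train.yaml \
    --seed 1 --mode hot --folds 5 --out demo_eval
```

`simulate` prints the generator's separability report — with the default
noise-free motifs every interacting lncRNA carries an exact
seed-complement site (positive-pair sequence affinity 1.0 vs 0.806 for
random pairs) and interacting pairs are expression-correlated at ≈ 0.80 vs
≈ 0.04 for non-interacting pairs:

```json
{
  "n_positives": 320,
  "mean_seq_affinity_pos": 1.0,
  "mean_seq_affinity_neg": 0.8058035714285715,
  "mean_expr_corr_pos": 0.7971487546952085,
  "mean_expr_corr_neg": 0.039160740620332576,
  ...
}
```

`evaluate` writes per-fold metrics and prints the fold summary:

```json
{
  "acc_mean": 0.95,
  "recall_mean": 0.9625,
  "precision_mean": 0.9390453174276704,
  "f1_mean": 0.950527050468911,
  "auc_mean": 0.98642578125,
  "aupr_mean": 0.9821782960420331
}
```

So on held-out folds the model ranks interacting above non-interacting
pairs with AUC ≈ 0.986 and calls 95% of pairs correctly at the 0.5
threshold. `lmipredict train` fits a final model and writes a checkpoint;
`lmipredict predict` scores an arbitrary pair list with it, sorted by
descending score (the ranking used for candidate prioritization);
`lmipredict evaluate --mode cold_lnc|cold_mir` runs the entity-exclusion
cold-start protocols; `lmipredict build-features` exports all six
similarity matrices and their refined variants as TSV.

The same things are available as a library: `InteractionPredictor` is a
scikit-learn-style estimator (`fit(X, y)` on an `(n_pairs, 2)` array of
entity indices, `predict_proba`, `get_params`/`set_params`, works with
`sklearn.base.clone`), and `lmipredict.model.cross_validate` executes a
`SplitPlan` end to end.

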