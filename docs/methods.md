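# Methods

## The model

`geneso` classifies expression profiles (bulk samples by tissue/status, or
cells by type) and attributes the classification to individual genes by
*symmetrical occlusion* — simulating each gene's gain and loss of function
and measuring how much the classifier's softmax scores move.

### Normalization

Three per-sample count normalizations are implemented: NRC (reads for a
gene over total mapped reads of the sample; columns sum to 1), TPM (columns
sum to 1e6) and RPKM. "Total mapped reads" is always the column sum of the
supplied matrix; upstream multimapper policy is out of scope. NRC is the
recommended network input: the in-network z-score makes TPM/RPKM's
multiplicative constants redundant, and gene length scales all samples of a
gene identically, so it contributes nothing to between-sample
classification. No batch correction is applied anywhere.

### Network

The classifier is a peephole LSTM stack implemented in numpy (forward pass,
exact backpropagation through time, Adam), wrapped as a
scikit-learn-compatible estimator:

1. **Z-score input layer.** Per-gene mean/std, fit on the training split
   only (population std, `ddof=0`, configurable) and frozen; zero-variance
   genes map to 0. The layer is *bounded*: |z| is clipped at
   `zscore_clip=10`. On-manifold inputs are untouched (training data rarely
   exceed a few σ); the bound exists because occlusion grids reach the same
   absolute expression range for every gene, which for a low-variance gene
   is tens to hundreds of σ — without the bound the network is evaluated
   in a regime it has never seen and its arbitrary extrapolation there,
   proportional to 1/σ, dominates the attribution scores. Set
   `zscore_clip=None` for the unbounded layer.
2. **Sequence layout.** The length-G vector is zero-padded and reshaped to
   T timesteps × F features; T defaults to ceil(sqrt(G)). T is a free
   choice with real consequences: all genes sharing a feature slot across
   timesteps share input weights, which is only learnable with enough
   samples. The scaled-down studies below use `timesteps=1`, where each
   gate reads the full z-scored vector at once — the cell equations are
   unchanged.
3. **Two LSTM layers** (default 120 and 80 cells; studies use 32/16), each
   followed by 30% inverted dropout during training only. The cell follows
   the peephole equations (input and forget gates peek at c_{t−1}, the
   output gate at c_t); peephole weights are full matrices, zero (and not
   updated) when `peephole=False`, which recovers the standard cell.
4. **FC + softmax.** Prediction = argmax; ties break to the lowest class
   index. A sample whose maximum score stays below a threshold (default
   0.7) can be flagged as a candidate *novel class* — unseen classes tend
   to produce flat score vectors.

Training: Adam (lr 1e-3), minibatch 32, cross-entropy, fixed epoch count by
default; optional early stopping on a stratified validation split
(`early_stopping=True`, patience 10) restores the best weights. L2 weight
decay (default 1e-3, biases excluded) is always on: at small sample sizes
the unregularized network memorizes high-dimensional noise and the
attribution then ranks noise. An optional input-occlusion augmentation
(`augment_fraction`) replaces a random subset of genes per training sample
with uniform draws over the occlusion range; it is off by default because
it teaches invariance to *all* single-gene perturbations and thereby
flattens the attribution signal itself.

All randomness (init, shuffling, dropout, augmentation) flows from one
seeded generator; a fixed seed reproduces training bit-for-bit on the same
platform.

### Symmetrical occlusion

For gene g in reference sample r (values on the normalized input scale,
before the in-network z-score):

- **Gain branch:** values original + k·step, step = original/10 by default
  (`step_fraction` configurable; `absolute_step` available), ascending
  while ≤ 2 × max(r) (`max_multiplier`). For a zero-expression gene the
  step falls back to `step_fraction` × max(r).
- **Loss branch:** descending by the same step, ending at exactly 0.
- Grid points outside the gene's observed range are flagged *imaginary*
  but score identically — they are an intended part of the simulation.
- `max_steps` (default 1000) bounds each branch: genes with near-zero but
  positive expression would otherwise generate 1e4–1e5 grid points. When
  the bound binds, the step is enlarged to cover the same range in
  `max_steps` even steps. Note the step-halving refinement property
  (finer grids are supersets, so scores never decrease) holds only while
  the bound is slack.

Every grid point yields a pseudo sample differing from r in g alone; all
pseudo samples are batched through the network. The occlusion score of
(g, c) is the |max − min| of class c's score over the combined trace,
averaged over class-c reference samples (default: all validation samples
of c, subsampled to `reference_cap` with the config seed). A cross-class
variant (`reference_scope="all"`) tracks class c's curve on every
reference. The mean occlusion score averages a gene's per-class scores and
is the global ranking key (ties break by gene id).

Gain/loss *sweeps* apply one branch across many samples at once and record
the predicted label per step — the heat-map view used to validate a marker
(raising a true marker pulls foreign samples into its class; a null gene
changes nothing). Grids are sample-specific, so shorter grids hold their
final prediction.

### Selection and comparison

Top-fraction subsets of the ranking (grid default {0.1, 0.2, 0.33, 0.5,
0.75, 1.0}) are retrained with repeated stratified 5-fold CV; the most
accurate subset wins, ties to the smaller panel. Also provided: a per-class
"top fraction unique" union; a mean-OR-std threshold filter; a per-class
|in-class median − out-class median| top-k selector (k = 40 by default, a
"widened" variant is just larger k); and a depletion study (accuracy with a
subset minus accuracy after removing a gene set from it). When a class has
fewer samples than k, folding degrades to the class size with a warning.

### Tissue specificity

Per-gene specificity is log2(N) − H(p) where p is the gene's per-class
median-expression profile normalized to proportions (0·log 0 := 0). It is
0 for uniform expression and log2(N) — 4.8074 bits for N = 28 — for
single-class expression; a [0,1]-normalized variant is available. Pearson
or Spearman correlation against mean occlusion scores asks whether
occlusion simply rediscovers specificity.

## Synthetic data

The generator emulates the minimal statistical structure the method
assumes: G genes with log-normal baseline means (σ = 1), per-sample
log-normal library factors (σ = 0.2), negative-binomial counts with a
common dispersion r (default 2; variance μ + μ²/r), and m marker genes per
class whose mean is multiplied by a fold change (default 8) in their own
class. Markers are placed at random positions (a `block` placement option
exists; contiguous markers all land in one timestep of the sequence layout,
which is both unrealistic and pathological for recurrent processing). The
scRNA-like variant adds zero-inflation (default 0.6), small baseline means
and one cell type with an *exclusive* marker (zero expression elsewhere).
What it does not model: batch effects, doublets, compositional shifts
beyond the marker boost, tumor heterogeneity, gene–gene correlation. A
passing recovery study therefore shows the pipeline works when its
assumptions hold, not that it is robust to real-data confounders.

## The scaled-down study

The end-to-end study run by the test suite uses 4 classes × 30 samples,
600 genes, 5 markers per class at fold 8, NRC input; a 75/25 stratified
split; a reduced network (hidden [32, 16], `timesteps=1`, 300 epochs,
weight decay 1e-3); occlusion over all genes with 3 validation references
per class and `max_steps=100`. These sizes keep the full study at roughly
two minutes on one CPU while leaving the conclusions stable across seeds:
≥80% of the planted markers rank in the top 20 by mean occlusion score, a
gain sweep of the top-ranked marker pulls ≥50% of foreign validation
samples into its class while a bottom-ranked null gene flips ≤5%, and
retraining on the top-20 panel loses no more than 2 accuracy points
versus all 600 genes (it typically gains).

## Numerical choices and edge cases

- Grid counts use a 1e-12-relative tolerance so spans that are exact
  multiples of the step (e.g. 30/0.1) do not lose their endpoint.
- Zero-variance genes: z = 0, never NaN; an all-zero sample column is a
  degenerate-sample error under NRC; an all-zero profile row is an
  undefined-specificity error; correlation with a zero-variance vector is
  an undefined-correlation error rather than NaN.
- Missing values are never imputed; readers fail instead.
- Model persistence is a directory: `weights.npz` plus `metadata.json`
  (gene order, z-score stats, class labels, architecture), so a reloaded
  model reproduces predictions bit-for-bit and inconsistent directories
  are rejected.
- Occlusion scores are softmax differences, hence always within [0, 1];
  the mean column is recomputed from the per-class matrix, never stored.

## Known limitations

- Occlusion attributions are relative to one trained network; retraining
  changes scores more than it changes ranks.
- The |max − min| statistic cannot distinguish a gene that helps a class
  from one that hurts it; direction lives in the traces, not the table.
- With redundant markers (several per class), knocking out a single marker
  barely moves its own class's score; recovery rests mostly on the gain
  branch and on cross-class effects.
- Per-gene grids scale with 1/expression; the `max_steps` guard changes
  the effective step for near-silent genes, trading the strict step rule
  for bounded runtime.
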