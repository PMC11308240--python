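# geneso

LSTM classification of bulk and single-cell RNA-seq expression profiles,
with **Symmetrical Occlusion** — a perturbation-based attribution method
that quantifies each gene's importance for the classifier by simulating its
gain and loss of function — and an occlusion-rank-driven gene-subset
selection loop.

It is aimed at computational biologists who want to (a) classify samples by
tissue of origin / disease status or cells by type from read counts, (b)
extract the marker genes the classifier actually relies on, and (c) shrink
the gene panel without losing accuracy.

## Method

**Normalization.** Read counts are normalized per sample; the preferred
network input is NRC (normalized read counts),

```
NRC  =        reads_mapped / total_mapped_reads
TPM  = 1e6 · (reads/length) / Σ_genes(reads/length)
RPKM = 1e9 ·  reads / (total_reads · gene_length)
```

NRC drops the constant and the gene-length term: the network's z-score
input layer makes constants redundant, and gene length affects every sample
of a gene identically.

**Classifier.** A per-gene z-score input layer (statistics frozen on the
training split, |z| bounded at 10), the expression vector reshaped to T
timesteps × F features, two LSTM layers (default 120 and 80 cells) each
followed by 30% dropout during training, and a fully connected softmax
head. The LSTM cell includes peephole connections:

```
i_t = σ(W_xi x_t + W_hi h_{t−1} + W_ci c_{t−1} + b_i)
f_t = σ(W_xf x_t + W_hf h_{t−1} + W_cf c_{t−1} + b_f)
c_t = f_t ⊙ c_{t−1} + i_t ⊙ tanh(W_xc x_t + W_hc h_{t−1} + b_c)
o_t = σ(W_xo x_t + W_ho h_{t−1} + W_co c_t + b_o)
h_t = o_t ⊙ tanh(c_t)
```

The whole stack is plain numpy (exact backpropagation through time, Adam),
exposed as a scikit-learn-compatible estimator, `LSTMClassifier`.

**Symmetrical Occlusion.** For a gene g in a reference sample, a grid of
occlusion values replaces its normalized expression: upward ("gain of
function") in steps of one tenth of the original value until the grid would
pass twice the sample's maximum expression, and downward ("loss of
function") to exactly 0. Each grid point is a pseudo sample differing from
the reference in g alone; grid points outside the observed expression range
are flagged "imaginary" but score like any other. The occlusion score of
(g, class c) is the |max − min| of c's softmax score along the combined
trace, averaged over class-c reference samples; the **mean occlusion
score** averages over classes and ranks genes globally. Subsets of
top-ranked genes are then retrained with repeated stratified 5-fold
cross-validation and the most accurate subset wins.

A Shannon-entropy tissue-specificity score, `log2(N) − H(p)` over the
per-class median profile, is provided to ask whether occlusion merely
rediscovers tissue specificity (it does not — the correlation is weak).

## Worked example

```python
import geneso as gs

# 4 classes x 30 samples, 600 genes, 5 planted markers per class (fold 8)
cm, truth = gs.simulate_counts(gs.SyntheticConfig(seed=1))
nrc = gs.compute_nrc(cm)

cfg = gs.NetworkConfig(hidden_sizes=(32, 16), timesteps=1, epochs=300,
                       weight_decay=1e-3, seed=1)
model = gs.train(nrc, cfg, seed=1)

occ = gs.OcclusionConfig(reference_cap=3, max_steps=100, seed=1)
table = gs.score_all_genes(model, nrc, occ)
ranking = gs.rank_by_mean_occlusion(table)

markers = {g for genes in truth.values() for g in genes}
top20 = set(ranking.gene_ids[:20])
print(f"planted markers recovered in top 20: {len(top20 & markers)}/20")
print(f"best gene {ranking.gene_ids[0]} "
      f"mean occlusion score {ranking.scores[0]:.3f}")
```

Output:

```
planted markers recovered in top 20: 19/20
best gene g0235 mean occlusion score 0.008
```

19 of the 20 planted markers occupy the top 20 ranks. The absolute scores
are small here because the model is very confident on its own training
samples, so even the most influential gene only moves the class
probabilities by ≈0.008 on average — but that is still ~25× the score of a
typical null gene (≈0.0003), and it is the *ranking* that drives gene
selection. Training on a split and occluding validation references (the
recommended workflow, used by `tests/conftest.py::run_study`) yields larger
absolute swings.

The same pipeline is available from the shell:

```sh
geneso simulate --seed 1 --out data/
geneso train   --counts data/counts.tsv --labels data/labels.tsv --out model/
geneso occlude --model model/ --counts data/counts.tsv \
               --labels data/labels.tsv --out scores.tsv
geneso select  --strategy occlusion-mean --scores scores.tsv \
               --fraction 0.33 --out panel.txt
```

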