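# Methods

This note documents the models and procedures the package implements, the
choices made where the design was open, and what the synthetic benchmarks
do and do not demonstrate.

## Problem setting

Cross-tissue cell-type annotation for scRNA-seq: given a cell × gene raw
count matrix and per-cell metadata (cell-type ontology term, donor, assay),
train a classifier over the observed cell-type labels that generalizes to
*unseen donors*, and evaluate it in a way that is fair to differing
annotation granularity. Donor-based splitting (70/15/15 of donors, every
cell following its donor) is used throughout; random cell-level splits
would leak donor identity and overstate performance.

## Corpus construction

Six filters are applied in order: (1) primary data only, to avoid
duplicated cells in meta-atlases leaking across splits; (2) 10x Genomics
assays only; (3) the label must be a subtype of the root term
("native cell"); (4) ≥ 5,000 cells per cell type; (5) ≥ 30 donors per cell
type; (6) ≥ 7 ontology ancestors, a heuristic against overly broad labels.
Criteria 4–6 remove all cells of a failing type and are re-applied until a
fixed point, so all thresholds hold in the final corpus. The three
type-level thresholds are dataset-dependent and configurable
(`FilterParams`); the defaults are the full-scale values. "Parent nodes"
in criterion 6 is read as *transitive* ancestors (direct-parent counts
rarely reach seven in the Cell Ontology); this is configurable. Cells
whose label is missing from the ontology are dropped and itemized in the
filter report. Zero-count cells are kept but flagged (configurable drop).

Expression is size-factor normalized to 10,000 counts per cell and log1p
transformed; `expm1` of a normalized row sums back to the size factor.
Normalizing an already-normalized layer is an error, never a silent
double application.

Split rounding: `floor(fraction·n)` donors go to validation and test, the
remainder to train. This preserves the 70-15-15 intent while being
deterministic at small n (10 donors → 8/1/1). Donor assignment is a seeded
uniform shuffle without stratification — a deliberate simplification.

Incremental subsampling (cell- or donor-level) takes prefixes of a single
seeded permutation, so smaller fractions are strict subsets of larger
ones. The on-disk chunk store is Parquet with fixed-size row chunks; the
batch streamer reads whole chunks in seeded order, shuffles inside a
buffer, and yields every row exactly once per epoch — the access pattern
required for bigger-than-memory corpora.

## The classifier

scTab is a TabNet-style feature-attention network with a single decision
step, implemented here in numpy with hand-written backpropagation (no deep
learning framework is a dependency of this package):

1. input: normalized expression, then a plain batch-norm layer;
2. feature transformer 1: `n_shared` GLU blocks (fully-connected →
   ghost batch norm → gated linear unit) followed by `n_independent`
   invocation-specific blocks, residual connections scaled by √0.5;
3. the last `n_a` latent units feed a linear layer + batch norm whose
   output passes through 1.5-entmax, giving a sparse per-cell probability
   vector over genes (the feature attention mask);
4. the mask multiplies the normalized input element-wise; feature
   transformer 2 (sharing the fully-connected weights of the shared blocks
   with pass 1, but owning its batch-norm layers) embeds the masked input;
5. logits come from a linear layer on ReLU of the first `n_d` units.

1.5-entmax maximizes `p·z + H_1.5(p)` over the simplex, with
`H_1.5(p) = (4/3) Σ_j (p_j − p_j^1.5)`. The maximizer is
`p_i = max(0, z_i/2 − τ)²` with τ fixed by `Σ p = 1`; τ is found by
bisection (64 iterations, sum error < 1e-8), and the closed-form Jacobian
`diag(s) − s sᵀ/Σs`, `s = √p`, backs the gradient. Unlike softmax, entries
can be *exactly* zero, which is what makes the attention interpretable as
gene selection.

The loss is class-weighted cross-entropy with
`weight_c = n_samples / (n_classes · n_c)` (so Σ_c weight_c·n_c =
n_samples), computed on the training split only, plus
`λ_sparse · mean(−M log(M + 1e-15))`, the entropy regularizer on the mask
(λ_sparse = 1e-5). Optimization is Adam with decoupled weight decay
(decay on weight matrices only; biases and normalization parameters
exempt), learning rate 0.005 decaying ×0.9 per epoch, batch 2048, ghost
batch size 256 at full scale. Early stopping tracks validation macro F1
(patience 10, min-delta 1e-4) and the best-epoch parameters are returned.

Two implementation choices deserve emphasis:

- **Weight sharing excludes batch norm.** The shared GLU blocks reuse only
  their fully-connected weights across the two passes. The two passes see
  activations on very different scales (raw vs. attention-masked input);
  sharing normalization statistics between them degrades eval-mode
  predictions catastrophically.
- **Precise batch-norm statistics.** After each epoch the running
  statistics are recomputed in one train-mode pass with the current
  weights ("precise BN") instead of trusting the exponential moving
  average. At toy scale the weights move fast enough within an epoch that
  EMA statistics describe a mixture of stale networks; validation scores
  computed from them are noisy and the selected "best epoch" arbitrary.
  At full scale this costs one extra forward pass per epoch and is
  harmless.

Baselines share the training loop, loss, and normalization: a linear
model (one weight matrix + bias; lr 5e-4, weight decay 0.01) and an MLP
(8 hidden layers × 128, ReLU, dropout 0.1, lr 0.002).

Model objects follow a construct-then-`fit()` pattern; `fit(seed)` returns
a results object holding parameters, per-epoch history, prediction
methods, attention masks, and `summary()`. Checkpoints serialize
parameters, config, gene vocabulary, class list, and normalization
statistics into one `.npz` file.

## Donor-difference augmentation

Augmentation vectors are centroid differences of the same cell type
between two donors, computed on the training split only: subsample with
equal per-type quotas (without replacement unless a type is smaller than
its quota); centroids per (type, donor) with ≥ 10 supporting cells (the
support threshold is our choice; unsupported pairs give noise centroids);
all ordered donor-pair differences per type (keeping both signs makes the
later ± sampling symmetric by construction); zero every entry in
[−0.25, 0.25]; clamp to [−1.5, 1.5]; k-means with 50 clusters (seeded,
10 restarts, tolerance 1e-4) and retention of vectors only from clusters
with > 2,000 members — the large clusters carry cell-type-*independent*
donor directions, which is what allows applying a random vector to any
cell — then uniform sampling of 5,000 vectors without replacement. All
size parameters scale proportionally for toy corpora
(`AugmentationConfig.scaled`).

During training each batch row gets one uniformly drawn vector with a
fair random sign, and the result is clamped to [0, 9] in normalized
space. Augmentation is never applied at evaluation.

The variance diagnostic fits, per gene, ordinary least squares of
normalized expression on intercept + one-hot(cell type) + one-hot(donor)
(drop-first encoding keeps the design full rank) and averages per-gene R²
uniformly across genes. Augmentation should lower R² somewhat (the added
vectors are not attributable to the real labels) while leaving cell type
the dominant variance source.

## Ontology-corrected evaluation

A prediction is right if it equals the annotated term or is its subtype;
predicting an ancestor, or anything else, is wrong. Confusion bookkeeping
credits a right-by-subtype prediction to the *truth* class (preserving
per-class support); a wrong prediction is a false positive for the
predicted class and a false negative for the truth class. Per-class
F1 = 2tp/(2tp+fp+fn) with 0/0 → 0; macro F1 averages over classes with
support in the truth set. Classes that appear only among predictions are
excluded from the macro mean (documented choice; the alternative would
let a single stray prediction of a rare class dominate the average).
With an edgeless graph the metric reduces exactly to conventional macro
F1.

Coarse evaluation maps both predictions and truths through the
information-content (IC) coarse map and re-scores. IC is a [0, 100]
specificity score; when no precomputed table is supplied we use
`IC(t) = 100·(1 − log(1+n_descendants)/log(1+n_terms))`, which matches
the required properties (count-based, leaf = 100, monotone along edges);
externally computed scores can be loaded as an override table. Coarse
labels are the terms with IC ≤ 60; each observed term goes to its
highest-IC candidate ancestor-or-self, ties broken by lexicographic term
id.

## Uncertainty

Deep ensembles: average softmax probabilities of (default) 5 replicas
differing only in initialization/shuffle seed; uncertainty = 1 − max of
the averaged probabilities. Test cells split into Group 1 (correct under
the ontology-corrected rule), Group 2 (incorrect, trained type), Group 3
(truth absent from the training label universe — by default also not a
subtype of any trained label, since such cells are still classifiable
under the corrected metric; configurable). Separation of G2/G3 from G1 is
the ROC-AUC of the uncertainty score, pooled over all test cells.

## Synthetic corpora

The generator draws, per cell type, a log-mean program (baseline N(0, 0.5)
plus a marker boost on disjoint marker-gene sets) and, per donor, an
additive shift in log-mean space touching a configurable fraction of genes
(batch effects concentrate on subsets of transcripts; a dense shift on
every gene is unrealistic and would defeat the band-zeroing step of the
augmentation). Counts are negative-binomial with mean
`L · softmax(program + shift)` and a gene-shared dispersion, `L`
log-normal. A fraction of cells can be relabeled to a random proper
ancestor (mixed annotation granularity), and chosen types can be flagged
as absent from the training universe.

Preset conditions (fixed seeds, regenerated identically at every use):

| preset | genes | types | donors | cells | key features |
|---|---|---|---|---|---|
| separable-small | 2,000 | 8 | 20 | 20,000 | strong markers, mild shift |
| donor-shift | 400 | 5 | 16 | 4,000 | strong sparse donor shift |
| granularity-mixed | 300 | 6 | 10 | 2,000 | 30% coarsened labels |
| holdout-type | 400 | 6 | 16 | 4,000 | 1 unseen type, confusable types |
| filter-edge | 20 | 6 | — | 31,599 | 4,999/5,000 cells, 29/30 donors, shallow term |

What the generator does **not** emulate: zero-inflation beyond NB,
ambient RNA, doublets, gene–gene correlation structure beyond the shared
program, per-gene dispersion, or realistic ontology topology (trees with
optional diamonds, not the full Cell Ontology). Passing benchmarks on
these corpora therefore demonstrates the *mechanics* (optimization,
attention, augmentation arithmetic, metric correctness, uncertainty
ranking) and the *directional* claims (augmentation helps under donor
shift; unseen types score as uncertain), not real-data performance
levels.

### Attention–marker alignment at toy scale

The feature attention masks are about 1% sparse. At full gene-space scale
(19,331 genes) a 1% support is ~200 genes, so a top-200 attention ranking
can in principle cover a cell type's full marker program. At 2,000 genes a
1%-sparse mask holds only a few dozen genes, and a type's mean mask is
zero almost everywhere — a top-200 list is then mostly arbitrary
zero-ties. The scale-appropriate statement of the mechanism, and what the
test suite asserts, is *enrichment*: attention mass on planted markers is
several-fold that of background genes, overall and per type, and top-list
marker recovery is well above the chance rate. Complete top-k recovery of
all markers should only be expected at full gene-space scale.

## Benchmark problem sizes

The benchmark protocols run a reduced classifier (n_d=32/n_a=16 on
separable-small; n_d=16/n_a=8 elsewhere; batch 256–512, ghost batches
128) and scaled augmentation parameters (2,000-cell subsample, 8
clusters, >20-member cluster retention, 200 vectors). These are the
package's documented toy-scale conditions; the full-scale hyperparameters
remain the config defaults.

## Numerical details and edge cases

- entmax bisection: 64 iterations on τ ∈ [max(z)/2 − 1, max(z)/2], final
  exact renormalization; NaN input is an error.
- Argmax ties in prediction break to the lowest class index.
- Ghost batch norm normalizes the final remainder group on its own; eval
  mode uses the (recalibrated) running statistics.
- Validation cells whose label the model cannot express are excluded from
  validation scoring (relevant when coarsened labels appear only outside
  the training split).
- Gene-vocabulary mismatches at prediction time: shared genes reordered,
  missing genes zero-filled, warning below 80% coverage.
- Zero-total-count cells normalize to all-zero rows and are counted in a
  warning.

## Known limitations

- The numpy implementation is CPU-bound and single-threaded apart from
  BLAS; it is meant for method-level correctness and desk-scale corpora,
  not 10⁷-cell training runs.
- Full-scale donor splits are not bit-reproducible against any external
  corpus because the shuffle seed of the original corpus is unknown.
- The surrogate IC formula reproduces the stated properties of the
  published ontology scores but not their exact values; use the override
  table for full-scale comparisons.
- `n_steps` is fixed at 1; multi-step TabNet is out of scope.
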