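# Methods

This note documents the models and procedures implemented in `dcgn`, the
defaults and the reasoning behind the genuinely open design choices, and
what the synthetic benchmarks do and do not demonstrate.

## Data model

The pipeline currency is a samples × genes real matrix with integer
subtype labels coded `0..C−1`. Label strings are recoded in lexicographic
order, so the coding is a deterministic bijection that survives
save/load. Loaders reject missing values by default (per-gene-mean
imputation is available behind a flag) and report non-numeric cells with
row/column coordinates. Matrices are samples-in-rows; a `--transpose`
flag handles gene-major files.

## SMOTE balancing

Classes whose sample count is **strictly** below `threshold × n`
(default threshold 0.15) are treated as minorities. For each minority
class, synthetic rows are drawn as `x_new = x_i + (x_n − x_i)·r` with
`r ~ Uniform(0,1)`, where `x_n` is sampled uniformly from the `k` nearest
same-class neighbours of `x_i` under Euclidean distance (default `k = 5`,
the customary SMOTE setting; clamped with a warning to class-size − 1 for
very small classes). Seeds `x_i` are cycled in row order so coverage over
the class is even, and generation continues until the class reaches
`target_count` (default: the majority-class count, i.e. full
equalization; any integer can be configured). Original rows are never
modified or dropped, and synthetic rows carry a `synthetic_mask` flag.

Choices worth making explicit:

* **Neighbour search is within-class only**, matching the definition of
  the minority sample set; distances are computed on raw (unstandardized)
  features because balancing precedes normalization in the pipeline
  order.
* **Ties among equidistant neighbours** break by original row index
  (stable sort), so results are reproducible across platforms.
* By default SMOTE is applied to the **whole dataset before splitting**,
  reproducing the published pipeline order. This lets synthetic test
  samples share information with training data; `leakage_safe=True`
  restricts SMOTE to the training partition and is the right choice for
  honest generalization estimates. Random undersampling to a common count
  is provided as an alternative balancing strategy.

## Standardization and splitting

Per-gene standardization uses the **population** standard deviation
(divide by *n*, not *n* − 1). Parameters are fitted once — on the
training partition by default, on the full balanced matrix in
paper-literal mode — and reapplied to validation, test and future data.
Columns whose standard deviation is numerically zero (below
`1e−12·max(1, |mean|)`, guarding against float summation noise) map to
zeros rather than dividing by ~0: constant genes carry no information and
must not produce infinities.

Splitting is a random 80/10/10 partition (floor for train and validation,
remainder to test — 4221 samples give 3376/422/423), optionally
stratified per class, deterministic under its seed.

## Network architecture

Input width `G` (number of genes), then:

| stage | shape (defaults) | parameters |
|---|---|---|
| FC, gelu | `G → 1024` | W, b |
| reshape | `1024 → (32,32,1)` | — |
| conv2D, 128 kernels 3×3, stride 2, same | `(16,16,128)` | kernels, bias |
| max-pool 2×2, stride 2 | `(8,8,128)` | — |
| BiGRU, 64 units per direction | `(8, 128)` | 2 × (W_z, W_r, W, biases) |
| conv2D, 64 kernels 3×3, stride 2, same | `(4,64,64)` | kernels, bias |
| flatten + classifier 128→64→32→C | logits | 4 × (W, b) |

* **"Same" padding** means output size `ceil(input/stride)` with zero
  padding, the extra row/column on the bottom/right. Convolution is
  cross-correlation (no kernel flip), the convention of all modern
  frameworks.
* **BiGRU input construction**: the pooled `(8,8,128)` map is read as a
  sequence of its 8 spatial rows, each row flattened to a 1024-long
  feature vector. This preserves spatial ordering and gives the recurrent
  layer a nontrivial sequence; reading columns instead is available via
  `bigru_sequence_axis="columns"`. Hidden width is 64 **per direction**
  (concatenated output 128).
* **Second convolution**: the BiGRU output `(8,128)` is treated as a
  single-channel map and convolved with 64 kernels of 3×3 at stride 2.
* **Dropout placement**: rates 0.6 after classifier layers 1–2 and 0.7
  after layer 3, none on the output layer (inverted dropout, active only
  in training).
* **Activation**: the tanh approximation of gelu,
  `0.5x(1 + tanh(√(2/π)(x + 0.044715x³)))`, is the network default; the
  exact form `x·Φ(x)` is kept as an oracle (they differ by < 5·10⁻⁴ on
  [−5,5]). relu, elu (α = 1) and tanh are available for comparison runs.
* **Initialization**: uniform Glorot (fan-based) for all weight matrices
  and kernel banks, zero biases (including GRU gate biases), all drawn
  from a generator seeded by `config.seed`, so two builds with the same
  config are bitwise identical.

The shape chain is computed symbolically at build time and a build fails
with a description of the broken link if any stage is inconsistent (e.g.
a non-square FC width).

All forward and backward passes are numpy; the backward pass of every
layer (including backpropagation through time in both GRU directions and
the strided-convolution scatter) is validated against central-difference
gradients to < 10⁻⁴ relative error in the test suite.

## Training

Sparse categorical cross-entropy with softmax folded into the loss
(logits-out network, numerically stable log-sum-exp). Adam with
β₁ = 0.9, β₂ = 0.999, ε = 10⁻⁸ and learning rate 10⁻³; batch size 256
with the final partial batch kept (datasets here are small); per-epoch
shuffling from the run seed. Epoch count is capped at 100 with early
stopping on validation loss (patience 10); the returned weights are a
snapshot of the best validation epoch. Single-threaded execution is
bitwise deterministic given the seed; this is the contract the tests
enforce.

## Evaluation

Predictions are the argmax over logits, ties to the lowest class index.
From the C × C confusion matrix (rows = truth):

* accuracy = trace / n; Hamming distance = 1 − accuracy for single-label
  data (both are computed and the identity is asserted);
* weighted precision/recall: per-class one-vs-rest scores multiplied by
  the class's share of samples and summed; classes never predicted get
  precision 0 with a warning so the sum stays total; F1 is the harmonic
  mean of the two weighted scores;
* Cohen's kappa = (P₀ − P_e)/(1 − P_e) with P_e from the product of the
  marginals; undefined (raises) when P_e = 1.

A `paper_literal` mode additionally divides the weighted precision and
recall sums by the class count L. That variant is preserved for
auditability of the printed formula it mirrors, but it cannot be the
operational definition — under it a perfect classifier scores 1/L — so
the standard weighted average is the default.

## Synthetic data

The generator draws each class from a Gaussian whose mean is shifted by
`effect_size` (in units of `noise_sd`) on a class-specific, disjoint
block of informative genes and is zero elsewhere; optional equicorrelation
across informative genes via a shared per-sample factor, and an optional
log-normal transform for RNA-seq-like positive values. A Gaussian
class-conditional model was chosen because the target inputs are
continuous normalized expression values. Presets: `tiny` (3 × 40 samples,
256 genes, effect 3 — the fast test workload), `brca_like` (6 classes,
2133 samples with the characteristic 721/202/150 imbalance, 20,000
genes) and `blca_like:<system>` (3/5/7/10 classes at the four
bladder-cancer labeling systems' cohort sizes).

What this emulates: dimensionality, class imbalance, sparse informative
signal, additive noise. What it does not: realistic gene–gene
co-expression networks, batch effects, heavy-tailed count noise, or label
noise. Passing the recovery benchmarks therefore shows the pipeline is
correctly implemented and can learn a separable multiclass signal at
realistic dimensionality — not that it attains any particular accuracy on
real cohorts.

## Problem sizes and expected variation

The test suite and the acceptance script run the full pipeline on the
`tiny` preset with the FC width narrowed to 64 (a 256-gene input does not
support a 1024-wide map) and every other hyperparameter at its default.
The resulting 96-sample training set is smaller than one 256-sample
batch, so an epoch is a single Adam step, and the held-out test set has
12 samples — each worth 8.3 accuracy points. Recovery results on this
preset consequently vary with the simulation seed (roughly 0.75–0.92
accuracy); the benchmark seed is fixed and the runs are deterministic.
Gradient checks use a 16-gene, ~700-parameter network where central
differences are cheap and float cancellation is controlled.

## Known limitations

* CPU-only numpy execution: fine at the tested scales, slow for
  20,000-gene cohorts with thousands of samples (a full `brca_like` run
  is minutes per epoch, not seconds).
* The default pipeline order (balance before split) inflates test
  metrics by construction; use `leakage_safe=True` for honest estimates.
* Early stopping selects on a validation set that is small at these
  scales, making the chosen epoch noisy.
* No learning-rate schedules, hyperparameter search or cross-validation
  orchestration; repeated runs with different seeds are the supported way
  to average over split/initialization randomness.
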