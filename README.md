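# dcgn

Cancer-subtype classification from high-dimensional gene expression
matrices with SMOTE class balancing and a hybrid CNN + bidirectional-GRU
network ("DCGN"), plus the weighted multiclass evaluation suite used to
score such classifiers.

Molecular subtype labels (PAM50 breast-cancer subtypes, the bladder-cancer
MDA/TCGA/CIT-Curie/Lund systems, ...) are routinely predicted from
samples × genes expression tables with two awkward properties: tens of
thousands of features against at most a few thousand samples, and severe
class imbalance — one subtype may have 721 samples while another has 150.
This package implements the full pipeline for that setting:

1. **SMOTE balancing** — classes holding less than 15% of the samples are
   grown by interpolating each member toward one of its *k* nearest
   same-class neighbours: `x_new = x_i + (x_n − x_i)·r`, `r ~ U(0,1)`.
2. **Standardization** — per-gene centering/scaling to zero mean and unit
   variance, with the population (÷n) standard deviation
   `σ = sqrt(Σ(x_i − u)² / n)`.
3. **The DCGN network** — `FC(1024, gelu) → reshape (32,32,1) →
   conv2D(128 kernels, 3×3, stride 2, same) → max-pool(2×2) → BiGRU(64
   units/direction over spatial rows) → conv2D(64, 3×3, stride 2) →
   flatten → 128 → 64 → 32 → C` with dropout 0.6/0.6/0.7 in the
   classifier and logits out. The GRU cell is the standard
   update/reset-gate form `z = σ(W_z·[h,x])`, `r = σ(W_r·[h,x])`,
   `h' = tanh(W·[h⊙r, x])`, `h_t = (1−z)⊙h' + z⊙h`. Forward pass,
   backpropagation (verified against central differences) and Adam are
   implemented in numpy — no deep-learning framework required.
4. **Evaluation** — confusion matrix, accuracy, weighted precision /
   recall / F1 (per-class scores weighted by class share), Cohen's kappa
   `(P₀ − P_e)/(1 − P_e)`, and the multiclass Hamming distance
   (misclassification fraction).

A synthetic-data module generates imbalanced Gaussian-mixture expression
matrices with a known sparse set of informative genes, so the whole
pipeline is testable without downloading any cohort.

## Worked example

```python
import dcgn

# 3 subtypes x 40 samples, 256 genes, strongly informative signal
data = dcgn.simulate_dataset(dcgn.preset("tiny", seed=1))

cfg = dcgn.DCGNConfig(fc_nodes=64, seed=1)   # narrow FC for the small input
result = dcgn.run_pipeline(data, cfg)        # SMOTE -> split -> standardize -> train -> evaluate
r = result.report
print(f"accuracy {r.accuracy:.3f}  kappa {r.kappa:.3f}  hamming {r.hamming:.3f}")
print(r.confusion)
```

prints

```
accuracy 0.917  kappa 0.875  hamming 0.083
[[3 1 0]
 [0 4 0]
 [0 0 4]]
```

i.e. 11 of the 12 held-out samples are assigned the correct subtype
(accuracy 0.917), agreement beyond chance is strong (kappa 0.875), and the
Hamming distance is the complementary error fraction 1/12. The same
pipeline is available from the shell:

```bash
dcgn --seed 1 simulate --preset tiny --out-prefix sim
dcgn train --matrix sim_matrix.csv --labels sim_labels.csv \
           --config config.json --model-out model --report report.json
dcgn evaluate --model model --matrix test_matrix.csv \
              --labels test_labels.csv --report eval.json
```

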