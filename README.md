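# cmapfusion

Cross-modal fusion of medical images and laboratory time series with
dynamic feature pruning — a desk-scale, fully inspectable implementation
of the *encode → align → prune → fuse → predict* pipeline, together with
its metric suite and experiment protocols, exercised end to end on a
bundled synthetic paired-data generator.

## The problem

Clinical diagnosis increasingly combines an imaging study (a chest X-ray,
a dermoscopic photograph) with a short multivariate laboratory series
(blood counts, inflammatory markers over a few days). The two modalities
are heterogeneous — spatial versus temporal, dense versus tabular — and
their naive concatenation is redundant: many feature dimensions carry no
signal but still cost computation and hurt generalisation. This package
implements a classifier that (i) encodes each modality into a shared
`d`-dimensional space, (ii) prunes uninformative dimensions of the joint
feature with an adaptive threshold, and (iii) fuses the surviving
branches with cross-modal attention.

## The model

For an image `X_I` and a lab series `X_L ∈ R^{T×K}`:

* `F_I ∈ R^d`: class-token output of a patch-token transformer encoder
  (non-overlapping `P×P` patches, linear embedding, learnable class token
  and position embedding, `L` pre-norm blocks).
* `F_L ∈ R^d`: per-time-step MLP `ReLU(W_2 ReLU(W_1 x_t + b_1) + b_2)`
  with `W_1 ∈ R^{K×d/2}`, `W_2 ∈ R^{d/2×d}`, mean-pooled over `t`.
* **Pruning gate**: scores `S = σ(W_s [F_I;F_L] + b_s) ∈ (0,1)^{2d}`,
  threshold `τ = mean(S) + λ·std(S)` (per sample, population std,
  `λ = 0.3`), binary mask `M_j = 1{S_j ≥ τ}`, gated feature
  `F_prune = F_cat ⊙ M`. A guard keeps the top-scoring entry when the rule
  would empty the mask. Training uses a straight-through estimator
  (hard mask forward, sigmoid relaxation backward).
* **Fusion**: `Q = W_Q F'_I`, `K = W_K F'_L`, `V = W_V F'_L`,
  `Attn = softmax(QKᵀ/√d_k)V`, then
  `F_fusion = LayerNorm(Attn + F'_I)` and a bottleneck + softmax head.
* **Objective**: `L = L_cls + 0.1·(1 − cos(F_I, F_L)) + 0.05·mean(M)` —
  classification, cross-modal alignment, and sparsity pressure.

Training follows AdamW with linear warmup to 1e-4 and cosine annealing to
1e-6, batch size 32, early stopping on validation macro-F1. Everything is
seeded and bit-reproducible. The neural layers run on a small in-package
reverse-mode autograd engine (numpy, float64) whose gradients are tested
against finite differences.

Because no real paired image+lab corpus is distributable, the package
ships a generator of synthetic paired datasets with planted class motifs
in both modalities, a shared cross-modal latent, and a configurable
fraction of pure-noise lab dimensions — every mechanism (gate
selectivity, alignment loss, ablations, robustness) is measurable against
known ground truth. See `docs/methods.md` for the generator's design and
its limits.

## Worked example

`python examples/03_train_toy.py` trains the full toy model (d = 64,
depth 2) on the strong-signal preset (600 samples, 4 classes, 32×32
images, T = 10, K = 8 with 4 pure-noise dims) and prints:

```
trained 30 epochs; best validation macro-F1 1.0000 at epoch 29
test accuracy      1.0000
test macro-F1      1.0000
test macro AUC     1.0000
Cohen's kappa      1.0000
feature sparsity   65.6%  (share of gated feature entries pruned to exact zero)
cross-modal cosine 0.234  (alignment of the two modality embeddings)
parameters         183,108  forward FLOPs 1,506,020
```

The planted signal is fully recoverable, so the classifier reaches the
ceiling; the interesting numbers are the mechanism read-outs: the gate
prunes about two thirds of the 128 joint feature dimensions to exact
zeros, and the alignment term holds the two modality embeddings at a
positive cosine. The other scripts in `examples/` walk through dataset
generation, the per-sample gate anatomy, the λ sweep, the robustness
curves, and the module ablation, each printing what its numbers mean.

## Library and CLI

The primary interface is the Python API (`cmapfusion.generate_dataset`,
`train`, `evaluate`, `run_ablation`, `sweep_lambda`, `run_robustness`,
`cross_validate`, ...). A thin CLI mirrors the protocols:

```bash
cmapfusion generate --seed 0 --out runs/      # write images/ + labs.csv + labels.csv
cmapfusion train    --seed 0 --out runs/      # train + checkpoint + JSON report
cmapfusion ablate   --seed 0 --out runs/      # seven-row module ablation (CSV + JSON)
cmapfusion sweep    --seed 0 --out runs/      # lambda sensitivity table
cmapfusion robustness --seed 0 --out runs/    # noise / missingness curves
cmapfusion cv -k 5 --n-repeats 3 --out runs/  # repeated stratified k-fold CV
```

All commands accept `--config <yaml>`; re-running any command with the
same seed reproduces its JSON output byte for byte.

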