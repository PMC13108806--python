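# Methods

## The model

`cmapfusion` implements a bimodal classifier for paired medical-style data:
one image and one short multivariate laboratory time series per subject.
The pipeline is *encode → align → prune → fuse → predict*:

1. **Image encoder.** The image `X_I ∈ R^{H×W×C}` is cut into
   non-overlapping `P×P` patches (row-major, top-left origin). Each
   flattened patch is linearly embedded to dimension `d`, a learnable class
   token is prepended, a learnable position embedding is added, and the
   sequence runs through `L` pre-norm transformer blocks (multi-head
   self-attention + GELU MLP with expansion 4, residual connections). The
   final class-token state is the image feature `F_I ∈ R^d`. No final layer
   norm is applied after the block stack, so depth 0 returns the embedded
   class-token row unchanged.
2. **Lab encoder.** The series `X_L ∈ R^{T×K}` is mapped per time step
   through a two-layer ReLU MLP with weights `W_1 ∈ R^{K×d/2}`,
   `W_2 ∈ R^{d/2×d}` and mean-pooled over the `T` axis:
   `F_L = mean_t ReLU(W_2 ReLU(W_1 x_t + b_1) + b_2)`. The printed weight
   shapes only define a per-time-step map, so the reduction of the `T` axis
   is a design choice; per-step-then-pool keeps the shapes literal
   (flattening `T·K` would not). The outer ReLU makes `F_L ≥ 0`
   elementwise — which also means the concatenated feature has a natural
   nonzero rate of exact zeros even before any pruning (see below).
3. **Dynamic pruning gate.** The concatenation `F_cat = [F_I ; F_L] ∈ R^{2d}`
   is scored by a dimension-preserving sigmoid layer
   `S = σ(W_s F_cat + b_s)`, and gated by the per-sample mask
   `M_j = 1{S_j ≥ τ}` with the adaptive threshold `τ = mean(S) + λ·std(S)`.
   `std` is the population standard deviation over the sample's own `2d`
   scores; `λ` (default 0.3) is the pruning-pressure coefficient — larger λ
   raises τ and retains fewer dimensions, monotonically. If a score
   distribution satisfies `(max−mean)/std < λ` the raw rule yields an empty
   mask; a guard then retains the single highest-scoring entry (lowest
   index on ties) so the fusion stage never receives an all-zero vector.
4. **Cross-modal fusion.** The gated vector splits back into image and lab
   branches. Queries come from the image branch, keys and values from the
   lab branch: `Attn = softmax(QKᵀ/√d_k)V`. Applied to one vector per
   branch the softmax is over a single key and the rule collapses to
   `Attn = W_V F'_L` exactly; this degenerate "vector mode" implements the
   written equations literally and is pinned by a test rather than hidden.
   The toy preset instead uses a token-split variant (`fusion.tokens = 8`):
   each projected branch vector is reshaped into 8 tokens of dimension
   `d/8` and standard scaled dot-product attention runs across tokens,
   making the attention weights input-dependent. One attention block, one
   head. The output is residually combined with the image branch and layer
   normalised (`ε = 1e-5`, affine initialised to identity), then a
   bottleneck head (`d → d/2`, ReLU, minimum width 4) and a softmax
   classifier produce the class probabilities.

## Training objective

`L_total = L_cls + α·L_cm + β·L_sparse` with `α = 0.1`, `β = 0.05`:

* `L_cls`: batch-mean cross-entropy `−log Ŷ[y]`, probability clamped at
  1e-12 before the log.
* `L_cm = 1 − cos(F_I, F_L)`: pulls the two modality embeddings toward a
  shared direction. Cosine of a zero vector is an error in the metric
  suite, not a silent 0.
* `L_sparse`: the mean of the mask entries. Since the hard mask is not
  differentiable, training uses a straight-through estimator — the forward
  pass applies the hard mask, the backward pass uses the relaxation
  `σ((S − τ)/temperature)` with temperature 0.1 — and `L_sparse` is
  computed on the relaxed mask during training but on the hard mask for
  reporting. Note that a smaller mean mask always reduces this term, so β
  acts purely as pruning pressure; the retention side of the trade-off
  comes from the classification loss.

Optimisation: AdamW (β₁ = 0.9, β₂ = 0.999, decoupled weight decay 1e-5),
batch size 32, learning rate warming linearly over 5 epochs to 1e-4, then
cosine-annealed to exactly 1e-6 at the final epoch. Early stopping monitors
validation macro-F1 with patience 10 counted from the last strict
improvement; among epochs tied at the best value the *latest* weights are
restored (the longer-trained model has larger margins at equal validation
score). Custom modules are Xavier-uniform initialised. All randomness
derives from one run seed; per-epoch shuffle generators are derived from
`(seed, epoch)`, so variants sharing a seed see identical data order and
any re-run is bit-identical.

## Synthetic study conditions

The generator emulates paired clinical corpora whose laboratory arm is
simulated: per class it plants (a) an image motif — a Gaussian intensity
blob at a class-specific location (ring layout; quadrant centres for 4
classes), amplitude `signal_strength` over unit pixel noise — and (b) a
lab profile on the informative dimensions consisting of a class-specific
*level offset* plus a smooth class-specific temporal shape, jointly
unit-RMS and scaled by `signal_strength`. Level shifts dominate real
between-disease laboratory differences (elevated inflammatory markers,
deranged counts), and they are also the component a pooling encoder can
recover; a purely zero-mean temporal shape would be largely annihilated by
the mean over `T`. A per-sample scalar latent is injected into both
modalities (fixed unit-RMS loading patterns, weight
`cross_modal_coupling`), giving the alignment loss a genuinely shared
factor. Exactly `round(redundant_fraction·K)` trailing lab dimensions are
pure N(0,1) noise.

Defaults (the desk-scale study conditions, frozen): 600 samples, 4 balanced
classes, 32×32×3 images, T = 10, K = 8, `signal_strength = 3.0`,
`coupling = 0.8`, `redundant_fraction = 0.5`, toy model d = 64, patch 16,
depth 2, 4 heads, 30 epochs. With these settings a nearest-class-mean
classifier on raw lab features alone exceeds 90% accuracy — the planted
signal is strong and the lab modality is sufficient by construction.

What the generator does **not** emulate: anatomical structure, scanner
artefacts, inter-feature correlation of real lab panels, missingness that
is informative rather than random, class imbalance, label noise. Passing
tests therefore demonstrate that the machinery is implemented correctly
and behaves as the method intends on recoverable signal; they say nothing
about clinical performance.

Two consequences of these conditions are worth stating plainly. First,
because either modality alone supports near-perfect classification,
removing modules in the ablation protocol costs little — most stripped
variants sit at the accuracy ceiling, and the full model (whose lab
information reaches the head only through the attention values, and whose
hard per-sample gate adds forward-pass variance) can trail the stripped
variants by a percentage point or two on unlucky seeds. The ablation table
should be read as "all rows complete and behave mechanically as designed",
not as reproducing relative orderings that require genuinely
complementary, partially-insufficient modalities. Second, training-time
image augmentation is implemented (flip p=0.5 → crop with area ratio
U[0.8, 1.0] → 3×3 Gaussian blur with sd U[0, 0.1], in that order) but
disabled in the toy preset: the class signal is position-coded, and a
horizontal flip maps one class's blob location onto another's, so flips
and crops are label-destroying on this synthetic family.

## Preprocessing

Images: resize to the model input size (anti-aliased), optional
augmentation as above, then per-image per-channel z-scoring; a constant
channel standardises to all zeros. Labs: statistics are fitted on the
training split only and frozen — (1) values outside mean ± 3·sd are marked
missing (removal would change T, so outliers are masked and imputed
instead), (2) missing values are imputed with the training median,
(3) min–max scaling to [0, 1] with training min/max (constant features map
to 0.5), (4) linear interpolation along time to the target length,
clipping to [0, 1]. The robustness perturbations act on the preprocessed
inputs: Gaussian image noise with variance `intensity·v_max`
(`v_max = 1.0`, the variance of a standardised image), and masking of
exactly `round(fraction·T·K)` uniformly chosen lab entries re-imputed with
the scaled training median.

Splits are stratified with largest-remainder rounding: global split sizes
are exact, per-class allocations start from floors, and leftovers go to
the (class, split) cells with the largest fractional remainder subject to
the global totals. Repeated cross-validation uses scikit-learn's
`StratifiedKFold` per repeat, refits per fold, and carves a stratified 15%
validation set out of the training folds for early stopping.

## Metrics and accounting

Accuracy, macro-F1 (0 for a class with no true positives), Cohen's κ
(`(P_o−P_e)/(1−P_e)`; 1 when both rates are 1), and macro one-vs-rest AUC
computed as the Mann–Whitney rank statistic (ties count ½; classes absent
from the labels are skipped; single-class input is an error). All four are
cross-checked against scikit-learn to 1e-9 in the test suite. Feature
sparsity is the percentage of *exactly* zero entries in the gated feature
— mask zeros are exact by construction, but the lab half also contributes
natural ReLU zeros, so an ungated model reports its natural zero rate
(≈13–18% under the default conditions) rather than 0. Cross-modal
similarity is the mean per-sample cosine between `F_I` and `F_L`.
Parameter counts include trainable arrays only. FLOPs count the forward
pass at the configured input size with the multiply-accumulate = 2
convention (bias adds counted once per output); attention contributes its
projections plus `2·N²·d` MACs for the two matrix products; layer-norm and
softmax element operations are not counted. The convention is frozen so
numbers are comparable across configurations of this package.

## Numerical choices

* All computation is float64 on a small in-package reverse-mode autograd
  engine; gradients are validated against central finite differences.
* Mask rule is inclusive (`S_j ≥ τ`); argmax ties (guard and prediction)
  break toward the lowest index.
* Population (divide-by-2d) standard deviation in the threshold, so the
  worked values are exactly reproducible.
* Log clamp 1e-12 in the cross-entropy; ε = 1e-24 under the square root of
  the cosine denominator; layer-norm ε = 1e-5.
* The λ-sweep, ablation, and robustness protocols share seeds (and hence
  splits and batch order) across their variants; robustness level 0
  bypasses the noise draw entirely, so it equals the clean evaluation
  bit-exactly.

## Known limitations

* Vector-mode cross-modal attention is mathematically degenerate (softmax
  over one key); the token-split variant exists precisely because the toy
  scale has one vector per branch rather than a token sequence.
* The gate masks *features*, not parameters: it cannot reduce the
  parameter count, and reported `Params` are identical across λ.
* Full-scale geometry (224×224, d = 768, depth 12) is constructible but
  unexercised by the test suite; no pretrained weights are loaded.
* The experiment protocols run at desk scale (minutes on one CPU); their
  statistical power for orderings between near-ceiling variants is low,
  as discussed above.
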