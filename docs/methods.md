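# Methods

This note documents the models and procedures `ulcerstage` implements,
the choices made where the design was open, and what the synthetic-data
experiments do and do not demonstrate.

## Problem and taxonomy

Pressure-ulcer staging from RGB wound photographs is a six-class ordinal
problem: healthy tissue (`he`), Stages 1–4 (`s1`–`s4`), and undetermined
cases (`un`). Clinical collections are small and heavily imbalanced —
advanced stages are rare but clinically the most urgent — and adjacent
stages are visually similar, so the pipeline combines class-adaptive
augmentation, a reweighted focal loss, and ensembling rather than relying
on the classifier alone. Class index order is fixed (`he`=0 … `un`=5) in
every matrix and report.

## Preprocessing

Images are decoded to RGB in [0, 1], resized to a square target
(default 224 px) with bilinear, anti-aliased interpolation — no center
crop, so wound margins are kept — and normalized per channel with the
ImageNet statistics μ = (0.485, 0.456, 0.406), σ = (0.229, 0.224, 0.225).
Upstream wound segmentation and photographic-artifact correction are
exposed only as a no-op hook (`segment_background`): no published
algorithm underlies them, so nothing is guessed.

## Class-adaptive augmentation

Minority classes (`s3`, `s4`, `un` by default) receive an aggressive
policy: horizontal/vertical flips with p = 0.7/0.5, rotations up to 30°,
affine transforms (translation 0.2, scale 0.8–1.2, shear 15°),
brightness/contrast jitter 0.3, perspective distortion p = 0.3,
autocontrast p = 0.5, random erasing p = 0.3. Majority classes use the
same pipeline with all probabilities and magnitude half-widths halved.
Order is geometric before photometric: flip → rotate → affine → jitter →
perspective → autocontrast → erase. Erased rectangles are filled with
the per-channel class mean. Each class is expanded to a target count;
when the input matches the reference clinical training distribution
(54/60/73/39/15/14) the targets are that study's post-augmentation
column (392/476/589/315/129/126), otherwise every class is raised to the
maximum class count. Per-class random streams are derived from one run
seed plus the class index, so adding a class never perturbs another.
Evaluation splits are never augmented. The reported minority expansion
factor is computed from the actual counts ((315+129+126)/(39+15+14) ≈ 8.38
for the reference tables), never asserted as a constant.

Mixup blends a batch with a permuted copy of itself using a single
λ ~ Beta(0.2, 0.2) per batch; labels blend convexly, so one-hot rows stay
on the simplex.

## Architecture

The encoder is a BEiT-family vision transformer: 16 px patch embedding,
a learned CLS token, pre-norm residual blocks with bidirectional
attention (q/v-biased projections, no key bias), per-block decomposed
relative-position bias tables ((2·14−1)² + 3 rows × heads at 224/16
resolution), layer-scale residual gains, and GELU MLPs (ratio 4). At
full scale: 12 blocks, width 768, 12 heads.

Three staging-specific pieces sit on top:

* **Hierarchical fusion.** Outputs of intermediate blocks (6, 9, 12 at
  full depth) are mean-pooled over tokens, passed through per-tap linear
  projections to the model width, and summed with the attention-refined
  CLS vector. Summation (not concatenation) keeps the 768-dim interface.
* **Enhanced attention.** An additional 8-head self-attention module
  (four d×d projections: Q, K, V, output) computes
  softmax(QKᵀ/√d_k + R_pos)·V over the final token sequence and takes the
  CLS row as the feature. A lone CLS token cannot attend over space, so
  the module runs on the full sequence — the only reading under which
  relative positional encoding is meaningful. R_pos is an additive score
  bias at post-scaling score scale; by default it is a non-trainable zero
  buffer, so the module's trainable size is exactly 4·d·(d+1)
  (2,362,368 at d = 768).
* **Staged head.** f(x) = W₃·Drop(LN(GELU(W₂·Drop(LN(GELU(W₁·x))))))
  with dims 768 → 768 → 384 → 6, dropout 0.3, Kaiming-normal weights.

Counting trainable scalars gives 86,654,022 for the standard variant
(encoder + final and pre-head LayerNorms + head) and 89,016,390 with the
enhanced-attention module. Hierarchical-fusion projections are a
switchable add-on excluded from both counted variants, which is the only
decomposition consistent with the published enhanced−standard delta
equalling one attention module exactly.

The same wiring instantiates a miniature encoder (depth 2, width 32,
4 heads, 8 px patches on 32 px inputs, taps at every block) for
desk-scale training and testing. Pretrained weights are out of scope;
the full-scale model is instantiated only to count parameters.

### Numerics

All forward/backward computation runs on a small reverse-mode autodiff
engine over numpy arrays (float64 by default; a mixed-precision flag
switches to float32). GELU uses the exact erf form. Stochastic depth
drops a residual branch for the whole batch with probability increasing
linearly over blocks from 0 to the configured maximum, rescaling kept
branches by 1/(1−p); rate 0 reproduces the deterministic pass bit-for-bit.
Dropout is inverted. Every primitive's gradient is verified against
central finite differences in the test suite.

## Loss and schedule

The class-balanced focal loss is
w(n_y)·(1−p_t)^γ·(−log p_t), with w(n) = (1−β)/(1−βⁿ), β = 0.9999,
γ = 3.0. The printed formulation omits the conventional minus sign;
losses here are ≥ 0. Weights are normalized to mean 1 across classes
(switchable) so the loss scale is comparable across β. n_y defaults to
post-augmentation training counts — the distribution the optimizer
actually sees — and probabilities are clamped at 1e-12, below any
float32 gradient signal. With soft (mixup) labels the loss is the
label-weighted sum of per-class focal terms, which reduces to the
hard-label form on one-hot rows.

The learning rate is a linear warmup over T_warmup epochs into a cosine
decay: η(t) = η_max·t/T_warmup for t < T_warmup, else
η_min + ½(η_max−η_min)(1+cos(π(t−T_warmup)/(T_total−T_warmup))).
Full-scale defaults: η_max = 2×10⁻⁵, η_min = 0 (the conventional cosine
floor; no value is published), T_warmup = 3, T_total = 50, evaluated per
epoch.

## Training protocol

Stratified k-fold cross-validation (k = 5) deals each class round-robin
to folds after a seeded per-class shuffle: deterministic, per-class fold
counts differ by ≤ 1, and classes smaller than k raise a warning rather
than being duplicated. Optimization is AdamW (β₁ = 0.9, β₂ = 0.999,
ε = 1e-8, decoupled weight decay 0.04) on micro-batches of 8 with
gradient accumulation over 2 steps (effective batch 16; a trailing
partial window is flushed). Early stopping monitors validation macro F1
with patience 7. Parameter snapshots are kept at the ensemble epochs
E = {15, 20, 25, 30} (full scale) plus the best-F1 epoch. If a fold
stops before an epoch in E, the temporal ensemble simply averages the
checkpoints actually reached. Per-fold augmentation targets come from
that fold's training portion only; validation folds are never augmented
(the alternative reading of the source protocol would leak augmented
validation data and is deliberately not followed).

## Two-tier ensemble

P_temporal(y|x) = (1/|E|) Σ_{e∈E} P_e(y|x) within each fold, then
P_final(y|x) = (1/|K|) Σ_k P^k_temporal(y|x) across folds. Averaging
operates on post-softmax probabilities; it is permutation-invariant,
idempotent on identical members, never sharpens a row beyond its
sharpest member, and composes to a flat mean over all |E|·|K| members.
Argmax decoding breaks ties toward the lower class index.

## Evaluation

* Accuracy; precision/recall/F1 per class and macro/weighted averages
  (zero convention when P + R = 0); confusion matrices row-normalized by
  true class.
* One-vs-rest ROC per class with trapezoidal AUC (equal to the
  Mann–Whitney concordance, ties counting ½), Hanley–McNeil standard
  errors SE = √[(A(1−A) + (n₊−1)(Q₁−A²) + (n₋−1)(Q₂−A²))/(n₊n₋)] with
  Q₁ = A/(2−A), Q₂ = 2A²/(1+A), 95% CIs clipped to [0, 1], and
  interpretation bands (≥0.90 excellent, then 0.10-wide bands down to
  0.50). Macro AUC is the unweighted mean of defined per-class AUCs;
  micro AUC pools every (item, class) decision into one binary problem.
  Degenerate classes are reported as undefined, never dropped silently.
* Calibration: ECE on 10 uniform right-closed bins over (0, 1] (the
  first bin also contains 0; empty bins contribute 0), computed per class
  one-vs-rest and overall on top-label confidence; per-class Brier
  scores; grades excellent (< 0.05), good ([0.05, 0.10)), fair
  ([0.10, 0.15)), poor (≥ 0.15), lower edges belonging to the upper band.
* Severity weighting: Σ_{i≠j} W_ij·C_ij / ΣC with a default cost matrix
  of squared ordinal stage distance over (he, s1…s4) and unit cost for
  any confusion involving `un` — a package default standing in for
  clinically elicited costs, fully configurable.
* Paired t-tests across folds: t = mean(d)/(sd(d)/√n), df = n−1,
  two-sided p, 95% CI; identically-zero differences report t = 0, p = 1
  rather than NaN.

## Synthetic data

The generator emulates the reference study conditions: six classes with
the clinical imbalance (training 54/60/73/39/15/14, test 7/8/9/5/2/2),
deterministic regeneration from a seed, and class-dependent morphology.
Each image is a skin-tone background with a class-specific tint plus
concentric darkened elliptical rings whose count and depth grow with
stage (he = 0 … s4 = 4); `un` draws a random ring count with speckle
occlusion. Pixels are quantized to 8 bits so PNG round-trips are exact.
Subject ids are assigned round-robin for subject-aware splitting tests.

What this shows: the pipeline's mechanics — augmentation bookkeeping,
optimization, checkpointing, ensembling, and the full metric stack — on
a task whose classes are genuinely separable (a logistic regression on
8×8 mean-pooled patches exceeds 0.9 macro F1). What it does not show:
clinical realism, robustness to photographic artifacts, or the published
real-data headline metrics, which require the private clinical dataset
and GPU-scale fine-tuning of the pretrained encoder.

## Desk-scale configuration

Tests and the acceptance script run the pipeline at reduced size chosen
as what this generator and backbone need, not as a statement about the
full-scale recipe: 32 px images, the tiny backbone, 12 epochs with
ensemble checkpoints at epochs {3, 6}, and 5 folds over 255 training
images. Because the tiny network trains from random initialization
(whereas the full-scale recipe fine-tunes a pretrained 86M-parameter
encoder), its run configuration differs deliberately: peak learning rate
6e-3 with a one-epoch warmup, mixup off, head dropout 0.1, stochastic
depth 0, and augmentation targets scaled 3× (the reference protocol's
own expansion was roughly eightfold) so the early ensemble checkpoints
are past the steep part of the learning curve. The full-scale defaults
(2×10⁻⁵/3-epoch warmup, mixup α = 0.2, dropout 0.3, stochastic depth
0.1) remain the library defaults in the loss/model/training modules.

## Known limitations

* No pretrained weights: full-scale instantiation is architectural only.
* The severity-cost matrix default is package-chosen, not clinically
  elicited.
* The numpy engine is single-threaded CPU code; it is built for the
  desk-scale models the tests use, not for 86M-parameter training.
* Background segmentation / artifact-correction hooks are no-ops.
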