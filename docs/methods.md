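# Methods

This note documents the model, the synthetic data generators, the training
and evaluation protocol, and the numerical choices made where the design was
genuinely open. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Problem setting and model

One patient's 3D volume is a bag X = {x₁, …, x_K} of K ordered 2D slices
(224×224, intensities in [0, 1]) with a single binary label Y; slice-level
labels are unobserved. K varies across patients (slice thickness varies), so
training processes one bag per optimization step.

**Stage I — feature extraction.** An encoder f_e maps the bag to
H ∈ ℝ^{K×L}. The encoder is pluggable behind a fixed contract (row k is the
embedding of slice k; identical inputs give identical embeddings in
evaluation mode). Three encoders ship with the package:

- *identity* — passes precomputed K×L features through (synthetic
  feature-space bags, or features exported from any external backbone);
- *projection* — flatten-then-project with an identity-initialized trainable
  linear map; the lightweight encoder for CPU-scale experiments;
- *conv* — two 3×3 convolution blocks (ReLU, max-pool) with global average
  pooling and a linear projection to L; trainable end to end, and its
  post-ReLU convolutional activations are the Grad-CAM target layers.
  `calibrate_output` folds a per-dimension standardization (computed on a
  reference slice sample) into the projection, which matters when the conv
  trunk is frozen: raw GAP features live on arbitrary scales that otherwise
  swamp the between-slice differences the attention must detect.

Grayscale slices are replicated to three channels when an encoder expects
RGB input. No deep-learning framework is used: the layers, Adam, and all
gradients are written directly in NumPy, and every analytic gradient is
checked against central finite differences in the test suite (relative error
< 1e-4; observed ~1e-9).

**Stage II — ranking-attention pooling.** Attention logits
s_k = wᵀ tanh(V h_kᵀ) (V ∈ ℝ^{D×L}, w ∈ ℝ^D) are softmax-normalized over
the bag (max-logit subtraction for stability), giving scores a_k with
Σ a_k = 1. Scores are sorted descending — ties broken by the lower original
index, a stable deterministic rule — and the top C' = min(C, K) instances
are gathered. The bag embedding is z = Σ a_c h_c over the selection with the
*original* scores: A_C is never renormalized, so Σ A_C ≤ 1 and with C ≥ K
the pooling is bit-identical to full attention pooling (an invariant the
tests assert exactly, not approximately).

Gradient flow: the softmax is computed over all K instances first and the
top-C gather is hard. Selected instances receive gradient directly through
z; every instance receives gradient through the shared softmax denominator.
Selection indices are recomputed from current scores on every forward pass.

**Stage III — classification.** A single linear unit with sigmoid,
q(X) = σ(u·z + b). No dropout.

**Baselines** share the head and differ only in pooling: column-wise mean,
column-wise max, full-bag attention (= ranking attention with C = K), and
gated attention with logits wᵀ(tanh(V h_kᵀ) ⊙ σ(U h_kᵀ)) aggregated over
the full bag.

## Loss and training protocol

Class-weighted binary cross entropy over bags:
L = β_P Σ_{Y=1} [−log q] + β_N Σ_{Y=0} [−log(1−q)], with β_P = N/(P+N) and
β_N = P/(P+N) computed from the *training-subset* counts, so the minority
class receives the larger weight and β_P + β_N = 1. Probabilities are
clamped at 1e-7 for log stability. If a degenerate training subset has one
class only, the loss falls back to unweighted BCE with a warning.

Defaults in `TrainConfig` follow the clinical training recipe: Adam with
learning rate 2e-5, β₁ = 0.9, β₂ = 0.999, weight decay 1e-4 (L2 added to
the gradient), batch size 1, at most 200 epochs. 10% of training patients
(nearest integer, at least one per class) form a validation split; training
stops after 20 consecutive epochs without a *strict* improvement of
validation AUC and restores the parameters of the first best-AUC epoch.
"Does not increase" is read as "no strict improvement over the best so far";
the plateau reading would never terminate on a saturated metric. The
validation split is stratified by label even though plain random splitting
would also be defensible: with ~40% positives and ~24 validation bags an
unstratified split risks degenerate AUCs.

Augmentation (training only, image bags): horizontal and vertical flips with
probability 0.5 each, rotation with probability 0.2 uniform in 0–40°
(bilinear, shape-preserving). One transform draw is applied to *all* slices
of a bag within a step — bag-coherent augmentation preserves inter-slice
anatomical consistency. All randomness (splits, initialization, shuffling,
augmentation) derives from one master seed.

Five-fold cross-validation uses stratified folds (per-fold positive counts
differ by at most one), patient-level and disjoint.

## Evaluation

Thresholded metrics (accuracy, precision, recall, specificity, F1) use the
fixed operating point 0.5, prediction positive iff q ≥ 0.5; 0/0 ratios are
reported as 0 with a warning. The threshold is a convention — all
threshold-free statements use AUC. AUC is computed by the rank
(Mann–Whitney) formulation with half-credit for ties and equals
U⁺/(n_pos·n_neg); the test suite checks it against brute-force pairwise
counting and against an independent library implementation. The AUC
confidence interval is a stratified percentile bootstrap (2000 resamples,
resampling within class). The Mann–Whitney U test for comparing models is
two-sided, exact for min(n) ≤ 8 without ties and otherwise the normal
approximation with tie correction. When pooling variants are compared, every
variant trains on identical splits and seeds, and the test compares the
per-bag probabilities assigned to the true class; which samples feed this
test is a reporting convention and is stated here because it is not uniquely
determined by the protocol.

## Synthetic witness bags

The generators emulate the core premise — only some slices of a positive
patient carry signal — with the weakest distributional assumptions that make
the pipeline testable:

- **feature_space** — background instances i.i.d. N(0, noise_sd² I) in ℝ^L;
  positive bags contain exactly m witness instances whose mean is shifted by
  the effect size along the fixed unit direction 1/√L (fixed so that train
  and test sets generated with different seeds share the same signal).
  Defaults: noise_sd 1, effect size 2 — a per-instance signal-to-noise of 2
  along the signal axis, deliberately not separable at bag level without
  instance selection.
- **image** — 224×224 slices of clipped Gaussian noise (sd 0.1) around gray
  level 0.2; witness slices add a Gaussian blob (σ = 12 px, peak
  0.25 × effect size) at a uniform interior location. Blob centers are kept
  as ground truth for localization checks.

Witness positions are uniform without replacement by default; a "centered"
option concentrates them mid-sequence to mimic the empirical tendency of
middle slices to be informative, which is treated as a property of real
data, not of the method. Labels satisfy Y = max(y_k) by construction, the
realized positive count is exactly round(n_bags · positive_fraction), and a
fixed spec + seed reproduces bags bit for bit.

What the generators do *not* model: MRI physics, anatomy, scanner and
center effects, intra-bag slice correlation, or ambiguous witnesses.
Passing the synthetic benchmarks therefore demonstrates that the
implementation recovers plantable signal and localizes it — not that any
particular clinical performance would be attained.

## Benchmarks and their configuration

Two standard study conditions live in `ramil.benchmark`:

- **Feature-space recovery** — 400 bags (prevalence 0.4, matching the
  motivating cohort's 39.4%), K = 20, m = 3, effect 2.0, L = 32, generator
  seed 1, split 300 train / 100 held out; ranking attention with C = 10
  trained from 5 restarts. Reported: per-restart held-out AUC and a
  one-sided sign test of witness-vs-background mean attention within
  positive test bags.
- **Image localization** — 60 training and 72 evaluation bags (the
  evaluation set weighted to 50 positives so attention statistics have
  usable support), K = 20, m = 3, effect 2.0, pixel noise 0.1; a frozen
  random conv encoder (32 features, output-calibrated) feeds the trainable
  attention model. Reported: the fraction of positive bags whose top-C
  selection contains all witnesses, the attention sign test, and mean
  Grad-CAM mass inside the true blob's 3σ disk versus an equal-area random
  control disk.

Benchmark training configuration: Adam lr 5e-4, weight decay 3e-2, D = 16,
C = 10, patience 20. The paper-style default lr of 2e-5 is a fine-tuning
rate for a large pretrained backbone; a small attention model trained from
scratch on 32-dimensional features needs a larger step, and the elevated
weight decay plus the narrow attention width are regularization sized for
~300 bags in 32 dimensions, where overfitting is the dominant failure mode.
The image benchmark additionally raises the learning rate to 3e-3 (an order
of magnitude fewer optimization steps per epoch) and the validation share to
0.2 (a 10% split of 60 bags is too small for AUC-based model selection).
These sizes keep the complete suite in the minutes range on one CPU.

On the feature-space condition the held-out AUC of a trained model is
bounded by the statistics of the task itself: the exact Bayes-optimal scorer
(true signal direction and likelihood ratio known) reaches ≈0.92 on this
test set, and estimating the 32-dimensional signal direction from 300 bags
costs a few further points. Observed medians across restarts land in the
mid-0.8s with individual restarts up to ≈0.88; the attention sign test is
decisive (p ≈ 1e-10). The acceptance script recomputes both.

## Interpretability

Attention scores are reported raw (never renormalized after selection) with
1-based slice numbers, rank order, and a selected flag. Grad-CAM uses the
bag logit (pre-sigmoid) as the backprop target — the standard choice for a
binary head — computed through the *full bag* forward pass so the attention
weighting participates in the gradient: selected slices receive direct
gradient, unselected slices only the softmax-denominator component. Channel
weights are the spatial mean of the gradient at the target layer (default:
the encoder's last post-ReLU convolutional activation), the map is the ReLU
of the weighted activation sum, bilinearly upsampled to slice size, and
normalized to max 1 for display (normalization is optional for quantitative
use). A slice with no gradient path yields an all-zero map with a warning.

## Numerical conventions and edge cases

- Center crop: floor convention for odd remainders; inputs smaller than the
  crop are zero-padded symmetrically first (with a warning). Crop is
  idempotent.
- DICOM ordering: slices sort by ImagePositionPatient projected on the slice
  normal (cross product of the ImageOrientationPatient row vectors);
  fallback InstanceNumber; mixed series UIDs are an error. Intensities are
  min-max scaled per volume; a constant volume maps to all zeros. Per-volume
  min-max is a package decision — no normalization standard exists for raw
  MRI intensities.
- Indices are 0-based internally; all human-facing reports use 1-based
  slice numbers.
- D (attention width) defaults to 128 with config override; C defaults to
  10 and is clamped to K for small bags.
- Softmax stability by max-logit subtraction; probability clamp 1e-7;
  non-finite embeddings or losses abort with the offending slice/epoch
  named.
- Checkpoints store all parameters (NPZ) plus a JSON sidecar with variant,
  C, D, L, encoder spec, and a config hash; evaluation refuses a checkpoint
  whose architecture disagrees with the configured expectations unless
  forced.

## Known limitations

- No pretrained backbone ships with the package; the conv encoder is a
  small reference CNN, and production-scale transfer learning would slot in
  through the encoder contract with features exported to the identity
  encoder.
- The image generator's blobs are far easier than clinical pathology;
  localization results bound correctness of the mechanics, not clinical
  utility.
- Attention scores are contribution estimates under the model, not
  probabilities of instance positivity; with C < K a positive bag whose
  witnesses all fall outside the selection is invisible to the classifier —
  the known failure mode of hard top-C selection for very small lesions.
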