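# Methods

## Model

The diagnostic model is a set-input transformer over per-feature tokens.
A record's observed features are embedded to width `d_model` (default 256;
the desk-scale configurations in the examples and tests use 32 or less) by
modality:

* **numeric** — z-scored with training-split mean/sd frozen at fit time,
  then an affine map `x·w + b`.  Standardization is required because affine
  embeddings are scale-sensitive; the statistics live in the checkpoint.
* **categorical** — a per-feature lookup table, one independent row per
  category.  A missing categorical is handled by the mask, not by an
  "unknown" category, keeping missingness semantics identical across
  modalities.
* **imaging** — either a precomputed 256-vector (projected to `d_model`;
  the projection initializes to the identity when `d_model` = 256) or an
  encoder-output grid of shape 768×4×4×4 reduced to 256 by four
  convolutional blocks (two stride-2 kernel-2 blocks collapsing the 4³
  spatial grid, then two 1×1×1 blocks narrowing channels
  768→512→384→320→256).  The upstream 3D encoder that produces grids from
  volumes is a pluggable external interface, not part of this package.

Tokens carry no positional encoding: the feature set is unordered and each
feature is identified by its own parameters; permuting features together
with their masks provably leaves the logits unchanged (tested).

The encoder is pre-norm multi-head attention + GELU feed-forward with
residuals (defaults: 4 layers, 4 heads, FFN width 4·d_model, dropout 0.1).
Masked features are removed as attention keys in every layer via the
softmax mask, and a row with no visible key yields an all-zero attention
context rather than NaN.  Pooling is a learned classification token by
default (a masked-mean alternative sits behind `ModelConfig.pooling`); an
affine head maps the pooled vector to 13 logits and probabilities are
elementwise sigmoids.  Because masked tokens are excluded both as keys and
from pooling, any perturbation of a masked token's value leaves every logit
bit-identical — the property the masking-soundness tests assert exactly.

## Losses and training

`L = L_FL + λ·L_RL + β·‖w‖²` with defaults γ = 2, ε = 0.25, λ = 0.005,
β = 0.0005, N = 128, lr = 0.001, 256 epochs, cosine warm restarts with
first restart at 64 epochs and period multiplier 2.  Choices where the
design was genuinely open:

* **Normalization under label masking** divides by the batch size N with
  masked terms zeroed — the literal double sum — not by the unmasked count;
  `LossConfig.normalize_by="unmasked"` switches conventions.
* **Equal-label ranking pairs** contribute the constant ε exactly as the
  hinge formula dictates; their gradient is identically zero (tested), so
  the constant only offsets the reported value.
* **‖w‖² scope**: all trainable weights except biases and normalization
  parameters, matching the AdamW decay exemption rule; the L2 term is
  carried in the loss (so its gradient flows through backprop) and the
  optimizer's decoupled decay is left at zero to avoid double counting.
* **Probability clamping** to [1e-7, 1−1e-7] before logarithms.
* **Feature masks are redrawn per batch** (per-epoch redraw would expose
  the model to fewer patterns for the same compute); masking permutes only
  features observed in the record, so structural and simulated missingness
  compose into one mask and at least one feature always survives.
* **Epoch selection** maximizes validation micro-AUROC by default
  (`selection_metric` is configurable); validation is scored with dropout
  off and no feature masking.
* **Seeding**: one master seed fans out via `numpy.random.SeedSequence` to
  weight initialization, shuffling, feature-mask sampling and dropout;
  identical seeds reproduce loss trajectories exactly.

The numerical substrate is a small tape-based reverse-mode autodiff engine
(float64 numpy) with AdamW and the warm-restart schedule implemented in the
package; gradient correctness is pinned by central-difference checks.

## Shapley attribution

Each subject is a game over its observed features; the payoff of a
coalition is the model output for the chosen label with exactly that
coalition visible to attention.  The payoff scale is the predicted
probability by default (logit behind a flag) — probabilities are what the
clinical consumer reads.  The empty coalition is evaluated in a no-feature
mode where only the CLS pathway is active, making payoff(∅) a
record-independent constant.  The permutation estimator is unbiased;
enumerating all |S|! orderings reproduces the 2^|S| coalition brute force
to 1e-10 (tested), and absent features are assigned exactly zero.  Global
rankings filter to cases with a positive logit for the target label, keep
the `n_cases` with the most observed features (ties broken by subject id),
and average per-feature values with absent-feature zeros included.

## Evaluation protocol

AUROC uses the midrank tie convention (equal to the tie-corrected
Mann–Whitney statistic); AUPR is average precision.  Micro averaging pools
all (score, label) pairs into one curve, macro is the unweighted mean,
weighted weighs labels by positive count.  Single-class labels are
reported as undefined, never as 0.  Confusion statistics default to a 0.5
threshold; MCC is NaN on degenerate margins.  The co-occurrence evaluation
admits an etiology combination only when its joint-positive count n
satisfies 1/(4n) ≤ bound (bound 0.01 ⇒ n ≥ 25), the distribution-free
maximum of the empirical-AUROC variance in the limiting class count; a
combination's scalar score is the mean of its labels' probabilities
(min/product behind a flag), its negatives are all subjects not jointly
positive with every combination label known.  Clinician fusion rescales
the 0–100 confidence by 1/100 before averaging with the probability.
Standard significance machinery (rank tests, bootstrap CIs) is delegated
to scipy and is not re-implemented here.

## Synthetic cohorts

The generator emulates the *structure* the framework assumes, not any real
cohort's marginals: a three-way cognitive status (defaults NC 0.30 / MCI
0.30 / DE 0.40), etiologies drawn conditionally on DE with pairwise
co-occurrence boosts (AD+VD ×2.0, LBD+PSY ×1.8), every DE case forced to
carry ≥ 1 etiology and NC cases none, and 25% of MCI cases carrying an AD
label.  Fourteen features across clinically named groups (demographics,
NP tests, FAQ, GDS, NPIQ, UPDRS, MRI, plus a pure-noise group for
planted-irrelevance checks) are linear in the label vector with Gaussian
noise; effect sizes are set to plausibly strong clinical contrasts (e.g.
MoCA −8 points under dementia against an s.d. of 1.8) so that recovery is
expected, and the true effect matrix is returned for tests.  The optional
image-embedding feature is a label-shifted Gaussian 256-vector.
Missingness is MCAR per feature group (an MAR hook exists but is off by
default, matching a sweep protocol that masks features irrespective of
values), with named profiles at rates 0.05 / 0.69 / 0.94 mimicking the
sparsity contrast between a well-characterized reference cohort and two
progressively sparser external cohorts; per-label UNKNOWN injection is
separate.  A subject's last observed feature is never removed.

Because features are conditionally Gaussian given labels and missingness
is (by default) ignorable, passing tests demonstrate that the machinery
recovers planted signal under the stated conditions — not that the model
attains any particular performance on real clinical cohorts, whose feature
dependencies, label noise and informative missingness the generator does
not emulate.

## Problem sizes

The test suite trains desk-scale models: the end-to-end recovery check uses
a 4,000-subject cohort (2,800 train / 600 validation / 600 test), a 2-layer
32-wide encoder, and 24 epochs with a single cosine cycle — sizes chosen so
the full suite runs comfortably on one CPU while leaving the planted-signal
labels clearly recoverable (held-out AUROC ≥ 0.9) and the mask-training
robustness margin visible under 50% test-time feature removal.

## Known limitations

* The transformer depth/width and pooling of the original clinical-scale
  setting are configuration choices here, not reproductions.
* The generator's MCAR missingness cannot probe robustness to informative
  missingness; use the MAR hook for that.
* Shapley values are estimated per label head independently; no
  interaction indices or kernel/regression variants are provided.
* Training is single-device float64; large cohorts (≫10⁵ subjects) or wide
  imaging stacks would need a GPU-backed engine behind the same API.
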