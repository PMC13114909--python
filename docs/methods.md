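# Methods

This note documents the models, procedures, numerical choices and known
limitations behind `enoseda`.  It is written for a reader who wants to know
exactly what the package computes and what passing its tests does and does
not demonstrate.

## Input model and preprocessing

A measurement is a 10-sensor × 120-time-step conductance matrix.  Two
normalisations appear in the pipeline:

* **Per-feature standardisation** (`Standardizer`): z-scoring of flattened
  1200-dimensional inputs (or of any feature matrix) with statistics fitted
  on a training set only — the source training set for the transfer
  pipeline, so no test or target-test information leaks into preprocessing.
  Standard deviations are floored at 1e-8 before division, so constant
  features map to zero.
* **Instance normalisation** (inside the network): each channel of each
  measurement is z-scored over its own 120 time steps with population
  statistics, a variance floor of 1e-5, and no learnable affine map.  The
  purpose is to remove per-sensor offset and scale variability; a learnable
  affine map would reintroduce exactly that variability, so none is used.
  A constant channel maps to all zeros.

An important consequence of instance normalisation: any transformation of a
channel that is affine in time (baseline shifts, multiplicative gains —
including per-day session gains) is removed exactly.  Only features of the
temporal *shape* of a channel survive.  This drives several generator design
choices below.

## The network

Architecture constants: branch width d = 128, fused width 256, attention
model width d_m = 64 with 4 heads (d_k = 16), 2 pre-layer-norm encoder
layers with feed-forward width 256, classifier hidden width 128.

Choices the architecture description leaves open, fixed as follows:

* Convolutions use "same"-style padding (kernel 5 → pad 2, kernel 3 →
  pad 1), stride 1, max-pool kernel 2 stride 2, so the temporal ladder is
  120 → 60 → 30 → 15 → (adaptive average pool) 1.
* The fusion gate's hidden width is 64 and its output layer is
  zero-initialised, so every run starts at α = 0.5 and learns to deviate.
* The attention branch's output projection maps the 64-dimensional pooled
  encoder state to 128 so both branches emit the same width.
* Encoder dropout is 0.1, discriminator dropout 0.3, classifier dropout 0.5.
* Parameter initialisation is fan-in uniform; every weight draw, dropout
  mask and batch order derives from the experiment seed through a
  keyed hash (`derive_seed(master, tag)`), so runs are bit-reproducible.

The network is implemented on a small reverse-mode autodiff engine
(`enoseda.nn`) over numpy, in float32 by default (float64 switchable for
verification); every primitive's gradient is tested against central finite
differences.

## Losses and schedules

* Classification: label-smoothed cross-entropy, ε = 0.05, log-sum-exp
  stabilised.
* Center loss: mean squared distance of the classifier's penultimate
  feature to its class center, weighted by λ_c = 0.01 in the total loss.
  The centers themselves are updated by a separate plain-SGD step (lr 0.5)
  on the *unweighted* center loss — standard practice for center-loss
  training; with lr 0.5 and a single-sample class batch, the center lands
  exactly on the feature, which the tests exploit as a closed form.
* Domain loss: binary cross-entropy on discriminator logits (source = 0,
  target = 1) through the gradient reversal layer, evaluated in the stable
  softplus form; probabilities are never explicitly clamped.
* Reversal intensity: λ(e) = λ_max(2/(1 + e^{−10e/E}) − 1), advanced once
  per epoch with e counting completed epochs from 0; maxima 0.2 (local) and
  0.1 (global).
* Cosine annealing decays each stage's learning rates to zero at the
  stage's final epoch; it is applied in all three stages.

## Three-stage protocol

Defaults follow the full-scale protocol: epochs 200/200/300; Adam with
lr 1e-3 (stage 1), 2e-4 extractor + 1e-3 discriminators (stage 2), and
3e-5/5e-5/1e-4 for branches/fusion/head (stage 3); batch size 32;
20% stratified validation splits with best-validation checkpoint selection
in stages 1 and 3 and last-epoch checkpointing in stage 2 (best-validation
selection is specified only for the supervised stages).  Stage 2 draws
equal-size mini-batches from both domains, cycling the smaller side, for
ceil(max(n_s, n_t)/batch) steps per epoch, and never reads target labels.

Two deliberate implementation decisions:

* **Joint stage-2 forward.**  Source and target mini-batches are
  concatenated and passed through the network as one batch.  With separate
  per-domain forwards, batch normalisation would standardise each domain
  with its own batch statistics — implicitly pre-aligning the domains,
  starving the discriminators of signal, and making the adversarial
  gradients fight the normalisation.  Shared batch statistics make the
  discriminators see the true feature-distribution gap.
* **Source validation split.**  Stage 1 uses a stratified random 20%
  validation split of the source data (not a day-wise one); the day-wise
  discipline is reserved for the target domain, whose test days are never
  touched by any stage.

Batch-norm statistics are re-estimated during stage-3 fine-tuning by
default; a `freeze_bn` flag is exposed.

## Ablation variants

Each variant changes exactly one component: `cnn_only` / `attn_only` drop a
branch (the remaining 128-d feature feeds a matching head, and only the
corresponding granularity's discriminator is active); `concat_fusion`
replaces the gated fusion by plain concatenation + projection; `no_da`
skips stage 2; `local_only_da` / `global_only_da` keep one discriminator;
`no_finetune` skips stage 3.

`no_finetune` needs a policy: after stage 2 the head still has the source
label space, so its raw predictions are meaningless on the target.  The
variant is evaluated as a **budget-matched linear probe**: a single linear
layer trained on frozen fused features with the stage-3 head optimizer
settings (Adam at the head learning rate, same epochs, batching and label
smoothing).  A fully-converged convex solver was rejected: at reduced scale
it is a strictly stronger learner than any short stage-3 run, so the
comparison would measure solver budget rather than the value of the
fine-tuning stage.  This policy is an interpretation, not an inference of
the original variant's mechanics.

## Synthetic data generator

The generator emulates metal-oxide-sensor exposure curves:

    r_s(t) = g_{d,s} · gain_s · [B_s + Ã_{k,s}(1 − exp(−t/τ_eff))]
             + offset_s + drift·t + noise,
    τ_eff = τ_s · shift_tau_s · classτ_k · dayτ_{d,s}

with per-sensor baselines B ~ U(0.8, 1.2), time constants τ ~ U(10, 40)
steps, class amplitude patterns A built from a shared 3-dimensional latent
structure (class prototypes times a common loading matrix, plus small
class-unique detail, made positive), i.i.d. Gaussian noise
(sd 0.02), per-day multiplicative session gains (sd 0.05), and a small
per-measurement linear drift (slope sd 1e-4).  Only the 120-step exposure
window is modelled; the cleaning/recovery phase is not recorded in the
emulated protocol.

Two generator features exist specifically because of instance
normalisation's affine invariance:

* **Class-dependent kinetics** (`class_tau_scale`, log-uniform in
  e^{±0.5}): classes must differ in response *shape*, not only amplitude,
  or the normalising network would see no class signal at all.  Physically,
  different volatile mixtures adsorb at different rates.
* **Per-day kinetic jitter** (`day_tau_jitter_sd` = 0.05): sessions must
  also perturb shape, or day-wise splits would be indistinguishable from
  random splits for the model.

The transfer benchmark (`make_transfer_benchmark`) draws a source and a
target that share baselines, time constants and the latent pattern
structure but differ by a `DomainShift`: channel gains (sd 0.25·difficulty),
offsets (sd 0.20·difficulty), a per-channel kinetic rescaling (mean
slowdown 1 + 0.6·difficulty times channel-specific log-normal jitter with
log-sd 0.7·difficulty), and a class-pattern perturbation
(sd 0.25·difficulty).  `difficulty` = 0 is the identity shift.  The kinetic
component carries most of the effective shift, again because affine channel
effects are normalised away.  The target task is deliberately
**fine-grained**: its class patterns and kinetic multipliers are shrunk
toward their common mean by a separation factor (default 0.35; the
benchmark suite uses 0.65), emulating adjacent commercial grades with
subtle aroma differences.  The shift-magnitude coefficients were calibrated
once — so that a strong, shape-level domain gap exists at high difficulty —
and then frozen.

What the generator does **not** emulate: compound-specific chemistry,
humidity/temperature covariates, sensor aging across weeks, recovery-phase
dynamics, or non-exponential kinetics.  Passing the directional tests shows
the pipeline behaves as designed under controlled shift of this kinetic
family; it is not evidence about any particular instrument or product
category.

## Metrics

All five metrics (overall accuracy, macro precision, macro recall, macro
F1, Cohen's kappa) are computed from one C×C confusion matrix.  Per-class
precision/recall/F1 with zero denominators are reported as 0.  Kappa with
expected agreement 1 (a single class on both axes) is undefined and raises.
The tests verify equivalence with a per-sample brute-force oracle and with
scikit-learn on random labelings, plus two exact single-error worked
examples.

## Feature-space analyses

* Steady-state features: per-channel mean over the final 20 time steps.
* PCA summaries standardise columns (std floored at 1e-8) before projection.
* Multi-kernel MMD: five Gaussian kernels with bandwidths
  {0.25, 0.5, 1, 2, 4} × the median pairwise squared distance of the pooled
  sample; combined value = mean of per-kernel MMD².  The biased V-statistic
  is the default so reported values are non-negative; an unbiased
  U-statistic variant is available behind a flag.  MMD is measured between
  source and target *training* features, in eval mode.

## Reduced-scale study conditions

Full-protocol runs (200/200/300 epochs on 1440 + 360 measurements) are far
beyond a desk-scale numpy build, so the directional experiment suite and
the reproduction script use one frozen reduced configuration
(`enoseda.config.REDUCED_SCALE`): a 12-class source with 2 samples per
class per day over 4 days (96 measurements), a 6-class fine-grained target
with 4 per class per day over 5 days (days 1–3 train, days 4–5 test),
benchmark difficulty 1.0 with target separation 0.65, stages of 15/12/30
epochs with batch sizes 16/16/8, and three seeds.  Smaller batches than the
full-scale default are part of the scaling-down: with tens of fit samples,
batch 8 in stage 3 gives the optimizer enough steps for the head to
converge within 30 epochs.  At this scale individual runs carry several
points of training noise; the directional tests therefore compare means
over the three seeds and assert orderings, not effect sizes.

## Known limitations

* Reduced-scale accuracies are not comparable to full-protocol results;
  only orderings and trends are meaningful at this scale.
* At the frozen reduced scale, the marginal benefit of aligning both
  feature granularities over the better single-granularity variant is
  smaller than the across-run training noise, so the corresponding ordering
  test can legitimately fail even though removing alignment altogether
  clearly hurts.  Resolving that small effect requires full-protocol epoch
  counts and sample sizes.
* The autodiff engine is single-threaded numpy: correct and reproducible,
  but one to two orders of magnitude slower than a GPU framework; the
  full-scale protocol is supported but slow.
* The no-fine-tuning probe policy is one defensible reading of an
  underdetermined variant; other readings (e.g., a fully-converged probe)
  change that variant's absolute numbers.
* Kappa's undefined case and the zero-division metric conventions follow
  explicit policies that other toolkits may implement differently.
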