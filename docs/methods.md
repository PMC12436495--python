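# Methods

## Problem setting

A light-adapted electroretinogram (ERG) is a ~120 ms voltage trace recorded
at the cornea or lower-lid skin after a brief flash. Group differences —
here a case group with reduced b-wave and oscillatory-potential (OP)
amplitudes versus controls — are subtle relative to between-subject
variability, and clinical cohorts are small. The package implements a
augmentation strategy: train a class-conditional generative adversarial
network (CGAN) on the training partition, synthesise additional waveforms
per class, and train classifiers on the composite (real + synthetic) set.
The claim under test is not a particular accuracy but the *direction* of
the effect: augmentation should not hurt, and typically helps, the balanced
accuracy of a classifier evaluated on untouched real data.

## Data model

Every record is a 235-sample trace on the fixed −20…100 ms grid
(dt ≈ 0.513 ms, fs ≈ 1950 Hz), a binary group label, a flash strength from
the nine-value protocol series (−0.367…1.204 log cd·s·m⁻²), and
subject/eye/replicate metadata. The bundled generator
(`ergan.fixtures`) produces populations with this structure:

* a-wave and b-wave as Gaussian lobes (defaults: −10 µV at 15 ms,
  +30 µV at 30 ms), multiplied by a half-cosine onset ramp that is exactly
  zero before the flash, so the pre-stimulus baseline carries only
  zero-mean drift and white noise;
* OPs as a raised-cosine-windowed sinusoid (120 Hz, window 10–35 ms) on
  the b-wave's ascending limb;
* flash-strength dependence via a saturating gain g(s) = I/(I + I₅₀) in
  linear flash energy I = 10^s, normalised to 1 at s = 1.204
  (semisaturation at 10^0.35 by default) — strictly increasing and bounded;
* a case-group effect multiplying b-wave and OP amplitudes by
  `group_effect` (default 0.8);
* lognormal per-subject and per-record amplitude effects (σ = 0.08),
  ±1 ms latency jitter, 2 µV measurement noise, 0.5 µV slow drift.

What the generator does **not** emulate: photoreceptor/bipolar biophysics,
a-wave/b-wave latency shifts between groups, heteroscedastic noise,
electrode artefacts, age/sex covariates, or realistic between-eye
correlation (eyes of a pseudo-subject share only the subject amplitude
effect). Tests passing on these fixtures therefore demonstrate that the
pipeline's machinery is correct and that the augmentation effect appears
when class structure is present — not that any particular clinical effect
size is recoverable.

The per-strength record counts of the study population are bundled
(`fixtures.STUDY_COUNTS`; totals 545 case / 487 control). The published
total row (560/498) disagrees with the published per-strength rows; the
package follows the rows, since the generator consumes per-strength counts.

## Partitioning protocol

`dataio.split_train_test` takes a stratified 75:25 hold-out **before** any
generative training, so synthetic waveforms cannot carry features of test
records. The train partition is tagged, and `cgan.train_cgan` refuses any
dataset not tagged as a train partition. Subject-grouped splitting is
available behind a flag (the default is record-level stratification, since
eye/replicate leakage control is not part of the protocol being mirrored).
Amplitude normalisation (dataset min–max to [−1, 1] by default) is fitted
on the training partition only and its constants are stored for the
inverse transform and for the test side.

## Conditional GAN

Generator and discriminator both use a bidirectional LSTM over the
235-step axis (256 hidden units per direction full-size; concatenated
width 512) followed by a fully connected trunk (1024→1024, LeakyReLU 0.2,
dropout 0.2) — the generator ends in 1024→235 with tanh output in
normalised units, the discriminator in 1024→512→1 with a sigmoid. The
class label enters both networks as a 2-wide one-hot vector concatenated
to every BLSTM input step and to the trunk input. The generator's latent
input is a 100-dimensional standard normal, projected to a per-step input
sequence. The BLSTM sequence output is **flattened** (not pooled) into the
trunk: in development the pooled variant learned class-conditional
amplitudes but not waveform shape (per-class mean-waveform correlation
r ≈ 0 after 100 scaled epochs), while the flattened variant reaches
r ≈ 0.99 under identical conditions.

Training is alternating Adam (lr 2·10⁻⁴, β = (0.5, 0.999)) on binary
cross-entropy, batch size 15; the generator uses the non-saturating
−log D(G(z|y)) objective by default (identical fixed points to the literal
log(1−D) form, which remains available). Scores are clamped by ε = 10⁻⁷
inside the logs. Full-size training is 10 000 epochs; `scale_factor`
shrinks layer widths and the epoch budget proportionally for CPU runs.

Sampling inverts the stored normalisation and applies a zero-phase
order-4 Butterworth low-pass at 300 Hz (forward–backward `filtfilt`,
DC gain 1) before the synthetic records enter any composite dataset;
filtering can be disabled. Augmentation adds round(n_real/ratio) synthetic
records per class (ratio 2:1 by default), flagged as synthetic, with flash
strength undefined (NaN) because conditioning is on class only.

## Wavelet scalograms

`cwt.cwt_transform` is the direct discretisation of the CWT integral,
X(a,b) = |a|^(−1/2) Σₙ x[n]·ψ̃((n−b)/a), with b on the sample grid and a in
sample units; per scale the Toeplitz structure of the kernel matrix makes
this exact evaluation cheap. Scale maps to frequency as f = fc/(a·dt) with
dt the grid's physical sampling period (the 235-sample/120 ms grid; an
alternative 120-sample reading of the grid would change dt by 2× and is
not used — the dt lives in one place, `TimeGrid`, and is overridable).

Three mother wavelets give the three image channels, in fixed order:
Ricker (Mexican hat), first derivative of a Gaussian, and complex Morlet
with ω₀ = 5. Centre frequencies are the analytic spectral peaks
(√2/2π, 1/π·√2/2, ω₀/2π cycles/sample). Coefficient magnitudes at integer
scales 1…128 are min–max scaled to [0, 1] per channel and bilinearly
resampled to 224×224. A constant channel (zero waveform) maps to zeros.

## Classifiers

**TST** — encoder-only transformer on the raw (normalised) series: linear
embedding of each sample, fixed sinusoidal positional encodings, pre-norm
encoder blocks (multi-head self-attention + two-layer MLP), mean-pool over
time, linear head. Class-weighted cross-entropy (inverse-frequency
weights normalised to mean 1), Adam with initial lr 10⁻⁴ full-size, batch
32, early stopping on validation loss (patience 10 evaluations, best
weights restored).

**ViT** — vision transformer on 3×224×224 scalograms: raster-order
flattened patches, linear patch embedding, learnable class token and
positional embeddings, the same encoder blocks, and either class-token or
global-average-pool readout. SGD (momentum 0.9) with initial lr 10⁻³
full-size. Externally pretrained hybrid backbones can be named in the
config; the weight file must exist or training raises — there is no
silent fallback, and no pretraining is bundled.

All networks run on the package's numpy reverse-mode autodiff core
(`ergan.nn`), float64 throughout, with the LSTM recurrence compiled by
numba (a pure-numpy reference implementation with identical operation
order is kept as the fallback and as the correctness oracle). Training is
bit-reproducible for a fixed seed.

## Metrics and the comparison experiment

Precision, recall/sensitivity, F1, specificity = TN/(TN+FP), balanced
accuracy = (sensitivity+specificity)/2, and rank-based ROC-AUC (ties
counted ½, average ranks). Zero-denominator ratios are reported as
undefined with a reason, never coerced to 0. A `literal_specificity` debug
flag computes TN/(TN+TP) for auditing a known typo in one published
formula; it is not used in any reported number because it violates the
balanced-accuracy identity.

`evaluate.run_experiment` runs the full protocol per cell: hold-out split,
CGAN on the train side, per condition (real only / real + synthetic) and
per flash-strength subset a stratified five-fold CV over the real training
records (synthetic records join every fold's fit set, never a validation
fold), each fold's model evaluated on the untouched test side, metrics
averaged over folds. Evaluating on the fold-validation split instead is
available (`eval_on="fold_val"`); the fixed-test default reflects the
separation of an untouched test set in the mirrored protocol. Cells with
fewer than 2×k records are marked insufficient.

## Desk-scale study conditions (`ergan.presets`)

All heavier checks run at fixed CPU-scale conditions:

| item | full-size | desk preset | note |
|---|---|---|---|
| CGAN widths | 512/1024 | ÷16 | ~70 ms/step on one core |
| CGAN epochs | 10 000 | 100 (60 for the fidelity battery) | |
| TST | d64, 2 layers, lr 1e-4 | d32, 1 layer, lr 1e-3, input pooled ×3 | pooled series ≈650 Hz, OP band intact |
| ViT | patch 16, width 128, SGD 1e-3 | patch 32, width 16, SGD 1e-2, mean readout | cls-token readout is seed-unstable at depth 1 |
| populations | clinical accession | fixtures: separable (effect 0.5), null (1.0), headline (0.85, 9 strengths, ~60/class train), fidelity (0.7) | |

The larger learning rates are a consequence of the much smaller models (the
full-size rates plateau for hundreds of epochs at these widths); they are
fixed here, not tuned per experiment. Problem sizes for the benchmark
batteries: ceiling/null use 96 fit + 24 validation records and 320 test
records with 20 training seeds per arm; the augmentation comparison uses
the headline population (~60 records/class train) with five protocol seeds;
the fidelity battery uses 10 GAN seeds on a 40-per-class population.

## Numerical and degenerate-input choices

* Normalisation of a constant dataset raises (undefined min–max/z-score).
* Discriminator outputs are strictly inside (0, 1) (sigmoid); loss clamps
  guard the logs at ε = 10⁻⁷.
* Early stopping needs a minimum improvement of 10⁻⁶ in validation loss.
* Stratified splitting guarantees the per-group test share within one
  record of the requested fraction; with subject grouping the guarantee is
  best-effort (whole subjects move together).
* k-fold uses scikit-learn's stratified folds with shuffling under the
  run seed.
* The Butterworth cutoff must lie strictly below the grid Nyquist
  (~975 Hz); the digital design attenuates at least as much as the analog
  prototype magnitude 1/√(1+(f/fc)^(2n)) at every checked frequency.
* Zero-length sampling requests return an empty, correctly-typed dataset.

## Known limitations

* The ~10⁶ trainable-parameter figure sometimes quoted for BLSTM GANs of
  this layout is not reproduced (the full-size BLSTM alone exceeds it);
  parameter counts are whatever the stated layer sizes imply.
* Desk-scale GAN training equilibria are noisy; the package asserts
  directional and distributional properties over seed batteries, not
  point values.
* Synthetic records carry no flash-strength metadata, so strength-specific
  cells are augmented with class-conditional (not strength-conditional)
  waveforms.
* The experiment runner is generic over families but ViT cells at the
  full nine-strength grid are computationally heavy on CPU; the bundled
  benchmarks exercise the pooled-strength TST cell.
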