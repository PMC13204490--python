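# Methods

`s2cfl` implements a two-stage classifier for multimodal wearable recordings
paired with experience-sampling affect reports, together with a synthetic
cohort generator that makes every stage testable without access to wearable
data. This note describes the models, the generator, the numerical choices,
and what the synthetic experiments do and do not show.

## Problem setting

Each observation is a 30-minute *episode*: three wearable streams — heart rate
(HR, derived from photoplethysmography), galvanic skin response (GSR, 40 Hz)
and triaxial accelerometry (ACC, 20 Hz) — ending at a questionnaire prompt
that yields binary depression, valence and arousal labels, one of ten
fine-grained emotion categories, and a self-report vector. Stage 1 predicts
the three binary affect dimensions from the signals; stage 2 refines them into
the ten emotion categories using the stage-1 representations plus the
self-reports.

## Synthetic cohort generator

Labels are generated first and signals are conditioned on them, so recovery
tests are well-posed. Per episode, an emotion category is drawn (mildly
non-uniform weights), a continuous valence/arousal pair is sampled around that
category's centroid in the circumplex plane (sd 0.12), and a depression score
combines a subject-level propensity with a small negative valence loading.
The binary labels are the signs of these scores, so they are exactly derivable
from `raw_scores`. Self-reports are noisy linear readouts of the scores plus a
random linear embedding of the one-hot emotion class (questionnaire items load
on the underlying affect factors).

Signal kernels (units: bpm, microsiemens, g):

- **HR** (1 Hz): baseline 68 bpm + subject offset, a slow sinusoidal drift
  (amplitude 5 bpm, period 10–20 min, random phase) and AR(1) noise
  (stationary sd 2.5 bpm, lag-1 correlation 0.9).
- **GSR** (40 Hz): tonic level ~4 uS with two slow sinusoidal drifts, plus
  Poisson-timed phasic skin-conductance responses (bi-exponential shape,
  rise 1.2 s / decay 6 s, exponential amplitudes with mean 0.3 uS, base rate
  1.2 per minute) and white measurement noise (sd 0.02 uS).
- **ACC** (20 Hz, 3 channels): a gravity offset, a small sensor-noise floor
  (sd 0.008 g) and Poisson-timed activity bouts (rate 1/min, mean duration
  8 s, band-limited noise under a sinusoidal envelope, amplitudes
  0.15–0.35 g).
- **PPG** (20 Hz): a Gaussian pulse train at the configured beat rate, used to
  exercise the PPG-to-HR conversion.

Planted, recoverable label effects (`CohortConfig.effect_sizes`):

- `hr_arousal_shift` (default 8 bpm): additive HR baseline elevation for
  high-arousal episodes. Because per-episode z-scoring erases purely affine
  effects, the same knob also scales the drift amplitude (+5 %/bpm) and tempo
  (+6 %/bpm) — a scale-free signature that survives normalization, standing in
  for the shape changes real sympathetic activation produces.
- `gsr_stress_rate` (default 1.5): multiplies the phasic response rate of
  high-depression episodes by (1 + value). Event counts are scale-free and
  survive z-scoring unchanged.
- `acc_valence_damping` (default 0.6): scales the activity-bout variance of
  low-valence episodes by (1 − value). After z-scoring this appears as a
  changed bout-to-noise-floor contrast.

The defaults are the study condition for recovery tests; a documented
"strongly separable" condition (`STRONG_EFFECT_SIZES`: 12 bpm / 2.0 / 0.8,
about 1.5x the defaults) represents pronounced affective responses and is used
by the supervised-separability and ablation experiments.

Recovery statistics are direct computations on the raw arrays: the HR shift
by a group mean difference, the ACC damping by a dynamic-variance ratio, and
the GSR rate by steep-rise counting with a non-paralyzable dead-time
correction r = m/(1 − m·tau), tau = 2 s (peak-prominence counting merges
overlapping responses and biases high-rate episodes low).

Missing data are NaN sentinels injected as contiguous runs, so duration
bookkeeping is unaffected and both "short" and "gappy" exclusion modes exist.

## Preprocessing

Streams are RMS-pooled on a sliding 10 s window evaluated at 1 Hz (the two
stated numbers imply a 9 s overlap; edge windows are truncated), with triaxial
ACC first collapsed to its vector magnitude. Each episode/channel is then
z-scored with population sigma — normalization is a per-device amplitude fix,
so no cross-episode state is used. Episodes are excluded when any modality
window is shorter than the nominal duration or contains missing samples
(default `max_missing_fraction = 0`). PPG-to-HR conversion detects pulse peaks
(with parabolic sub-sample refinement; a 20 Hz grid alone quantizes
instantaneous HR by several bpm), takes 60/inter-beat-interval, median-filters
over 5 beats and resamples to 1 Hz.

## Signal-to-image transforms

Three transforms render each conditioned stream as a fixed-size nonnegative
energy map (rows = frequency, columns = time):

- **MR-STFT**: Gaussian windows whose length follows L(f) = c·rate/f (c = 6
  cycles) clamped to [4 s, 60 s] — constant-Q behaviour with a usable clamp —
  evaluated as the squared modulus of the windowed Fourier integral on the
  (f, t) grid.
- **WPT**: complete wavelet-packet tree (default `db4`, 5 levels,
  periodization mode, so perfect reconstruction and Parseval's identity hold
  exactly); row j is the squared coefficient sequence of frequency-ordered
  leaf j, linearly resampled to the time grid.
- **Multiscale HHT**: the signal is smoothed and decimated to dyadic scales;
  each scale is EMD-decomposed; each mode's analytic-signal energy is binned
  by instantaneous frequency (centred differences of the unwrapped phase,
  clipped to [0, rate/2]) onto the shared grid, and scales are summed.

EMD sifting uses cubic-spline envelopes with two mirrored boundary extrema,
a normalized-energy stopping criterion (tolerance 0.05, at most 50
iterations), and two guards: extraction stops when the residue energy is
negligible, and a sift iteration is rejected if it would triple the mode's
energy (boundary-spline overshoot otherwise amplifies near-zero residues into
spurious low-frequency modes). The reconstruction identity — sum of modes plus
residue equals the input — holds by construction regardless.

Episode image stacks restrict the imaged band to [0, 0.12·rate]
(`band_fraction`): at a 1 Hz conditioned rate the physiological structure
(drifts at mHz, phasic responses and bouts below ~0.1 Hz) lives far below
Nyquist, and full-band axes would spend almost every row on noise. Maps are
log1p-compressed, min-max normalized to [0, 1] (all-zero maps pass through)
and resized to a common grid, default 64x64, 32x32 in the desk-scale
experiments.

## Raw-signal branch (triple-path encoder–decoder)

One encoder per modality: a 1-D conv stack (ReLU) followed by an LSTM; the
latent is the final recurrent state. Two design points matter at small scale:

- The latent is the *full* state [h; c/sqrt(L)]. The cell state carries
  unsquashed running integrals of the gated inputs; the output squashing
  h = o·tanh(c) destroys exactly the episode-wide integrals the
  reconstruction objective needs. Encoders start with a forget-gate bias of 3
  (long memory).
- For the reconstruction profile, the input is presented together with sin/cos
  positional channels and pointwise signal-basis products (the 1-D analogue of
  feeding a spectrogram): integrating a product channel over time yields the
  signal's projection onto that basis function — the sufficient statistic of
  the slow drifts. The basis spans 0.3–8 cycles per episode, dense at the low
  end where the drifts live.

Decoders mirror the encoders per modality: a dense layer, a recurrent unroll
over the coarse grid (fed the tiled latent plus the positional basis), and
transposed convolutions back to full length, plus a latent-conditioned
harmonic readout (a linear map from the latent to per-basis-function
amplitudes, initialized near zero) that reconstructs the harmonic part of the
signal directly. Reconstruction is per-modality from each modality's own
latent; the fused latent (concatenation then dense projection) feeds the
three softmax classification heads trained with summed cross-entropy.

Two width profiles are used: the reconstruction profile (conv 96/96,
latent 128, fused 128, the defaults) and a classification profile
(conv 8/16, latent 32, fused 64, positional features and full-state latent
off) — the label tasks generalize better without the phase-carrying extra
channels, which are label-irrelevant directions a small training set overfits
to. Both stages use Adam (default lr 1e-3, batch size 32 at full scale;
lr 2e-3 and smaller batches in the desk-scale experiments) with early stopping
on a validation split during pretraining.

## Image branch (dense pyramidal transformer grid)

A stem convolution over the image channels concatenated with broadcast
task-probability planes produces the first dense-column cell and feeds a
backbone of windowed self-attention (Swin-style) stages, one per row j at
resolution H/2^j. A mixed feature pyramid refines rows 1–3 from all three of
them (rows 4–5 pass through). Grid cell (j, i) — triangular occupancy
j ≤ 5 − i, 15 cells — is a transformer block over the concatenation of all
previous same-row features plus an upsampled 1x1 projection (Vq) of the
fusion output FF[j+1][i−1]. FF blocks (one per row) fuse each cell with
time-pooled projections of the raw branch's conv-stage taps. The dense
convolution column DC[0][k] consumes every earlier DC cell plus FF[1][k−1]
(strict dense fan-in). The DSQ head concatenates DC[0][1..5], adds a
projected task-probability embedding *and* a direct linear skip from the
probabilities to the logits (additive conditioning; without the skip the
conditioning is unusable at small epoch budgets), applies CBAM (channel then
spatial gating; attention weights initialized near-uniform — random gates at
init scramble the features they multiply and stall optimization), a 1x1
convolution to three channels, global average pooling and a sigmoid.

The forward pass records, for every named cell, the list of named inputs it
consumed; the test suite compares this trace against an independent
enumeration of the dense-grid argument lists, so the wiring is asserted
rather than trusted. Training uses summed binary cross-entropy on the three
logits with the raw branch frozen (its probabilities and taps enter as fixed
arrays).

At inference the DSQ complements rather than replaces the raw branch's
softmax heads: when both branches are active the default affect score is the
mean of the two probability streams (`affect_source="auto"`), a two-view
ensemble in the same spirit as the stage-2 weighting.

## Stage 2: attribution-weighted emotion ensemble

The feature table holds, per episode: the fused raw-branch latent, the three
DSQ scores, (mean, max, entropy) of each image channel, and the self-report
vector. Three heterogeneous tree learners are fit on the emotion label:
LightGBM, XGBoost and a random forest. Attribution matrices are per-row,
per-feature SHAP values of the predicted class — native margin-space
contribution outputs for the two boosters, and the package's own
path-dependent TreeSHAP (verified against a brute-force subset-enumeration
Shapley oracle) in probability space for the forest. Local accuracy (values
sum to the model output minus the base value) holds in each model's own
output space. Ensemble weights are the normalized absolute attribution
masses, w_k = Σ|A^k| / Σ_k Σ|A^k| — absolute values because signed sums can
cancel and break the simplex property — always computed on held-in validation
rows, never on test rows. Because the boosters attribute margins and the
forest attributes probabilities, the masses are not on a common scale; the
weights therefore express attribution mass per model's own output scale,
which in practice favours the boosters. The ensemble prediction is the
weighted sum of per-model class probabilities.

The explainability-regularized loss — classification cross-entropy plus N
times the L1 deviation of attributions from their cross-model mean — cannot
be a gradient objective for tree-fitting APIs; it is the model-selection
criterion (`select_configuration` grid search over validation folds) and a
monitored diagnostic.

## Evaluation

Metrics (accuracy, sensitivity, specificity, F1) are computed in exact
rational arithmetic; zero-denominator cases are reported as 0 and flagged
degenerate rather than NaN. Cross-validation is subject-independent (all of a
subject's episodes share one fold) and stratified best-effort by a greedy
assignment: subjects ordered by episode count and label composition, each
placed in the fold minimizing the deviation of fold class proportions from
the global proportions; the achieved deviation is recorded because the two
constraints can conflict. Paired comparisons use the two-sided paired t-test
on fold-wise metrics (df = k − 1), with a hard error on zero-variance
differences. The ablation harness runs all variants on shared folds and
seeds (the fold hash is recorded) and reports paired tests against the full
model.

## Problem sizes and what the experiments show

The test suite and the acceptance script run at desk scale, chosen as the
package's own study sizes: 600 s episodes (the generator's default nominal
episode is 1800 s), cohorts of 72–300 episodes, 32x32 image stacks, network
widths in the tens, and 8–32 training epochs. At these sizes:

- planted-effect recovery, transform identities, wiring, ensemble algebra and
  metric correctness are exact or statistically tight checks;
- the supervised results (arousal balanced accuracy, emotion macro-F1, the
  ablation ordering) demonstrate that the pipeline extracts the planted
  structure, not that it would reach any particular accuracy on real
  ambulatory data — the generator's episodes are far cleaner (no artifacts,
  no device drift, no circadian structure, exactly known label mechanisms)
  and its self-reports are honest noisy readouts of the true affect state,
  which real questionnaires are not;
- the permuted-label control uses balanced accuracy (any label-blind
  predictor scores 0.5 balanced accuracy; plain accuracy reflects the class
  imbalance of the cohort, not leakage).

## Known limitations

- The neural branches run on the package's own numpy autodiff engine:
  single-threaded, float64, fully deterministic under a fixed seed, and slow
  compared to a GPU framework; widths and epochs are sized accordingly.
- Episode-level min-max normalization of the energy maps discards absolute
  energy scale; class information must appear as within-image structure.
- The LightGBM/XGBoost attribution masses are margin-scale while the forest's
  are probability-scale, so the ensemble weights are scale-heterogeneous (see
  above).
- HR at 1 Hz is generated directly rather than derived from PPG beat-to-beat;
  the PPG-to-HR converter exists and is tested, but the cohort pipeline does
  not route through it.
- The generator does not emulate circadian structure, motion artifacts, or
  device calibration error.
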