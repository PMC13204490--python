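# s2cfl

Self-supervised compounded multimodal feature learning for wearable-sensor
affect and depressive-state classification — with a synthetic ambulatory
cohort generator, so the whole pipeline runs and is tested without any
wearable data.

## The problem

Ambulatory mental-health studies pair continuous wearable streams — heart
rate (HR), galvanic skin response (GSR) and triaxial accelerometry (ACC) —
with experience-sampling questionnaires. Each 30-minute episode preceding a
prompt carries binary labels for depressive state, valence and arousal, a
fine-grained emotion category (ten classes: upset, hostile, alert, ashamed,
inspired, nervous, determined, attentive, afraid, active), and a self-report
vector. The package implements a two-stage classifier over such episodes:

**Stage 1 — binary affect.** Two complementary branches. The *raw-signal
branch* (TP-EDN) runs one conv+LSTM encoder per modality, fuses the latents
by concatenation, h_fu = Den([h_HR, h_GSR, h_ACC]), and is trained in two
phases: self-supervised reconstruction pretraining (per-modality mirror
decoders minimize MSE against the input signals) followed by supervised
fine-tuning of three softmax heads, x̂_task = softmax(Den_task(h_fu)). The
*image branch* (DC2-PTN) renders each stream as three time-frequency energy
maps — multi-resolution STFT, wavelet-packet energies, multiscale
Hilbert–Huang — and processes the stack with a windowed-attention backbone, a
mixed feature pyramid, a triangular grid of 15 densely connected transformer
cells, a dense convolution column with strict fan-in, CBAM attention, and a
sigmoid head producing three depressive-state quantification (DSQ) scores,
conditioned on the raw branch's task probabilities.

**Stage 2 — fine-grained emotion.** A feature table (fused latents, DSQ
scores, image summary statistics, self-reports) feeds three heterogeneous
tree learners (LightGBM, XGBoost, random forest). Per-model SHAP attribution
matrices A^k are turned into ensemble weights on the probability simplex,

    w_k = Σ_ji |A^k_ji| / Σ_k Σ_ji |A^k_ji|,

and the ensemble prediction is the weighted sum of the per-model class
probabilities. An explainability-regularized loss, L = L_cls + N·Σ|A − E[A]|,
is the model-selection criterion.

The synthetic cohort generator plants label-dependent physiology with known
effect sizes (HR elevation under high arousal, elevated phasic GSR response
rates under high depression, damped ACC activity under low valence), so every
claim the pipeline makes can be checked against ground truth. See
`docs/methods.md` for the full model and generator description.

## Worked example

```bash
python examples/simulate_cohort.py
```

prints (numbers from this exact script):

```
generated 72 episodes from 12 subjects
episode duration: 600 s; corrupted episodes: 0

planted effect recovery (direct group statistics):
  HR arousal shift:  recovered   8.32 bpm   planted 8.0 bpm
  ACC variance ratio (low/high valence): recovered 0.424   planted 0.400
  GSR SCR-rate ratio (high/low depression): recovered 2.379   planted 2.5
```

Each recovered statistic sits within two standard errors of its planted
value: the mean HR of high-arousal episodes is ~8 bpm above low-arousal ones,
low-valence episodes carry ~40 % of the ACC activity variance of high-valence
ones, and high-depression episodes show ~2.4x the phasic GSR response rate.

The other examples walk the remaining capabilities, each printing what it
computes and what the numbers mean:

- `examples/signal_to_images.py` — the three time-frequency transforms and
  the per-episode image stack;
- `examples/pretrain_and_classify.py` — self-supervised pretraining (held-out
  reconstruction MSE falls to ~0.48 from an epoch-1 level of ~1.0 on unit-
  variance signals) and supervised affect heads (~94 % held-out arousal
  accuracy on a strongly separable cohort);
- `examples/emotion_ensemble.py` — SHAP attribution matrices, simplex
  ensemble weights, held-out macro-F1 of the ten-class emotion ensemble;
- `examples/crossval_ablation.py` — subject-independent shared-fold ablation
  of the pipeline variants.

There is also a thin CLI (`s2cfl simulate | preprocess | transform | run-all |
report | ablate | ttest`) over the same library functions; `s2cfl run-all
--out DIR` executes the staged workflow (simulate → preprocess → transform →
pretrain → fine-tune → image-branch training → feature table → emotion
ensemble → evaluation) with per-stage caching and a run manifest.

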