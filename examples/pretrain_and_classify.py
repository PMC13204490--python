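"""Two-stage training of the raw-signal branch on a small synthetic cohort.

Stage 1a: self-supervised pretraining — the triple-path encoder-decoder learns
to reconstruct each modality from its latent, without labels.  Stage 1b:
supervised fine-tuning — the encoders are transferred and three softmax heads
classify depression, valence and arousal.  Expect the reconstruction error to
drop well below its first-epoch level, and arousal (carried by the planted HR
effect) to be the best-classified task.
"""

import numpy as np

from s2cfl import CohortConfig, PreprocessConfig, TPEDNConfig, generate_cohort
from s2cfl.preprocess import preprocess_cohort
from s2cfl.synthetic import STRONG_EFFECT_SIZES
from s2cfl.tpedn import finetune_heads, predict_records, pretrain_ssl, reconstruction_mse, task_labels

cohort = generate_cohort(
    CohortConfig(n_subjects=8, episodes_per_subject=8, duration_s=600, seed=9,
                 effect_sizes=dict(STRONG_EFFECT_SIZES))
)
records, _ = preprocess_cohort(cohort, PreprocessConfig(min_duration_s=600))
train, held = records[:48], records[48:]

ssl_cfg = TPEDNConfig(input_length=600, batch_size=4, lr=2e-3, epochs=10, patience=10, seed=0)
model, history = pretrain_ssl(train, ssl_cfg)
held_mse = reconstruction_mse(model, held)
print(f"self-supervised pretraining ({len(history)} epochs):")
print(f"  epoch-1 train MSE {history[0]['train_mse']:.3f} -> held-out MSE {held_mse:.3f}")
print("  (z-scored signals have unit variance, so an MSE of 1.0 means 'learned nothing')")

clf_cfg = TPEDNConfig(
    input_length=600, conv_channels=(8, 16), lstm_width=32, fused_width=64,
    batch_size=16, lr=2e-3, seed=0, harmonic_features=False, full_state_latent=False,
)
clf, _ = finetune_heads(train, clf_cfg, epochs=20)
probs = predict_records(clf, held)
labels = task_labels(held)
print("\nsupervised fine-tuning, held-out accuracy per task:")
for attr, task in (("p_dep", "depression"), ("p_val", "valence"), ("p_aro", "arousal")):
    p = np.array([getattr(pr, attr)[1] for pr in probs])
    acc = float(((p >= 0.5).astype(int) == labels[task]).mean())
    print(f"  {task:<11} {100*acc:5.1f}%  (high-class rate {labels[task].mean():.2f})")
print("\nArousal should clearly beat its base rate: the generator plants a strong"
      "\nheart-rate signature for it.  Depression and valence are harder at this size.")
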