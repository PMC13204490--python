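"""Subject-independent cross-validation and a small ablation comparison.

Trains the pipeline variants (raw-signal branch only, both branches without
attention, full model) on shared subject-independent folds and compares their
held-out arousal accuracy.  Variants share fold assignments and seeds, so the
comparison is controlled; a paired t-test against the full model is attached.
This is a deliberately small run — expect a few minutes on one CPU.
"""

from s2cfl import CohortConfig, GridConfig, PreprocessConfig, TPEDNConfig, generate_cohort
from s2cfl.evalcv import ablation_suite
from s2cfl.pipeline import PipelineConfig, make_variant_factory, prepare_cohort
from s2cfl.synthetic import STRONG_EFFECT_SIZES

cohort = generate_cohort(
    CohortConfig(n_subjects=8, episodes_per_subject=8, duration_s=600, seed=2,
                 effect_sizes=dict(STRONG_EFFECT_SIZES))
)
prepared = prepare_cohort(cohort, PreprocessConfig(min_duration_s=600),
                          image_size=(32, 32), n_scales=2)

config = PipelineConfig(
    tpedn=TPEDNConfig(
        input_length=600, conv_channels=(8, 16), lstm_width=32, fused_width=64,
        batch_size=16, lr=2e-3, harmonic_features=False, full_state_latent=False,
    ),
    grid=GridConfig(
        image_size=(32, 32), in_channels=9, row_widths=(4, 4, 4, 4, 4), dc_channels=4,
        tap_dims=(24, 48), batch_size=16, lr=2e-3,
    ),
    tpedn_epochs=20,
    dc2_epochs=12,
)

table = ablation_suite(
    prepared.records,
    make_variant_factory(config, prepared),
    variants=("tp_edn_only", "plus_fusion", "full"),
    seeds=(0, 1),
    k=2,
)
print(table.to_string(index=False))
print("\nmean held-out arousal accuracy per variant:")
print(table.groupby("variant")["accuracy"].mean().round(3).to_string())
print("\nAll variants share fold assignments (equal fold_hash per seed), so the"
      "\ncomparison is controlled.  At this deliberately tiny size the variant"
      "\ndifferences sit within fold noise (see the accuracy_sd column); the"
      "\nnon-strict ordering full >= no-attention >= raw-branch-only emerges at"
      "\nthe package's documented study size (100+ episodes, 3 seeds, longer"
      "\nimage-branch training), which is what the test suite runs.")
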