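"""Raw-signal branch: shape contracts, fusion, reconstruction, training."""

import numpy as np
import pytest

from s2cfl import Modality, TPEDNConfig
from s2cfl.errors import DataError, MissingModalityError, ShapeError
from s2cfl.nn import Tensor
from s2cfl.tpedn import (
    TPEDN,
    TaskProbabilities,
    finetune_heads,
    load_checkpoint,
    predict_records,
    pretrain_ssl,
    reconstruction_mse,
    save_checkpoint,
    signals_to_arrays,
)

TINY = dict(
    input_length=120,
    conv_channels=(4, 8),
    stride=4,
    lstm_width=16,
    fused_width=24,
    batch_size=4,
    epochs=2,
    seed=0,
)


@pytest.fixture(scope="module")
def tiny_model():
    return TPEDN(TPEDNConfig(**TINY))


class TestEncoder:
    def test_latent_width_contract(self, tiny_model):
        x = Tensor(np.random.default_rng(0).normal(size=(3, 120)))
        latent, taps = tiny_model.encode_modality(Modality.HR, x)
        assert latent.shape == (3, 16)
        assert len(taps) == 2

    def test_identical_inputs_identical_latents(self, tiny_model):
        x = np.random.default_rng(1).normal(size=(1, 120))
        a, _ = tiny_model.encode_modality(Modality.HR, Tensor(x))
        b, _ = tiny_model.encode_modality(Modality.HR, Tensor(x.copy()))
        assert np.array_equal(a.data, b.data)

    def test_planted_shift_separates_latents(self, tiny_model):
        rng = np.random.default_rng(2)
        base = rng.normal(size=(1, 120))
        shifted = base + 1.0
        a, _ = tiny_model.encode_modality(Modality.HR, Tensor(base))
        b, _ = tiny_model.encode_modality(Modality.HR, Tensor(shifted))
        assert np.linalg.norm(a.data - b.data) > 0

    def test_wrong_length_rejected(self, tiny_model):
        with pytest.raises(ShapeError):
            tiny_model.encode_modality(Modality.HR, Tensor(np.zeros((2, 100))))


class TestFusion:
    def test_concatenation_length_and_order_sensitivity(self, tiny_model):
        rng = np.random.default_rng(3)
        lats = {
            m: tiny_model.encode_modality(m, Tensor(rng.normal(size=(2, 120))))[0]
            for m in tiny_model.config.modalities
        }
        fused = tiny_model.fuse_latents(lats)
        assert fused.shape == (2, 24)
        swapped = dict(lats)
        swapped[Modality.HR], swapped[Modality.GSR] = lats[Modality.GSR], lats[Modality.HR]
        fused_swapped = tiny_model.fuse_latents(swapped)
        assert not np.allclose(fused.data, fused_swapped.data)

    def test_missing_modality_is_hard_error(self, tiny_model):
        with pytest.raises(MissingModalityError):
            tiny_model.fuse_latents({Modality.HR: Tensor(np.zeros((1, 16)))})

    def test_zero_latents_through_zero_bias_projection_give_zero(self, tiny_model):
        zeros = {m: Tensor(np.zeros((2, 16))) for m in tiny_model.config.modalities}
        saved = tiny_model.fusion.bias.data.copy()
        tiny_model.fusion.bias.data[:] = 0.0
        try:
            fused = tiny_model.fuse_latents(zeros)
            assert np.allclose(fused.data, 0.0)
        finally:
            tiny_model.fusion.bias.data = saved


class TestReconstruction:
    def test_shapes_match_inputs(self, tiny_model):
        rng = np.random.default_rng(4)
        lats = {
            m: tiny_model.encode_modality(m, Tensor(rng.normal(size=(2, 120))))[0]
            for m in tiny_model.config.modalities
        }
        recons = tiny_model.reconstruct(lats)
        for m in tiny_model.config.modalities:
            assert recons[m].shape == (2, 120)
            assert np.all(np.isfinite(recons[m].data))


class TestTaskProbabilities:
    def test_softmax_heads_sum_to_one(self, tiny_model):
        rng = np.random.default_rng(5)
        xs = {m: rng.normal(size=(3, 120)) for m in tiny_model.config.modalities}
        probs = tiny_model.predict_proba(xs)
        for task, p in probs.items():
            assert np.allclose(p.sum(axis=1), 1.0, atol=1e-6)
            assert np.all(p >= 0)

    def test_invalid_probability_vector_rejected(self):
        with pytest.raises(ShapeError):
            TaskProbabilities(p_dep=[0.7, 0.7], p_val=[0.5, 0.5], p_aro=[0.5, 0.5])


@pytest.fixture(scope="module")
def short_records(small_cohort):
    from s2cfl.preprocess import PreprocessConfig, preprocess_cohort

    records, _ = preprocess_cohort(small_cohort, PreprocessConfig(min_duration_s=300))
    return records


class TestTraining:
    def test_ssl_loss_history_and_improvement(self, short_records):
        cfg = TPEDNConfig(**{**TINY, "input_length": 300, "epochs": 3, "patience": 3})
        model, history = pretrain_ssl(short_records, cfg)
        assert len(history) <= 3
        assert history[-1]["train_mse"] <= history[0]["train_mse"] + 1e-9
        untrained = reconstruction_mse(TPEDN(cfg), short_records)
        assert reconstruction_mse(model, short_records) < untrained

    def test_finetune_probabilities_and_determinism(self, short_records):
        cfg = TPEDNConfig(**{**TINY, "input_length": 300})
        m1, _ = finetune_heads(short_records, cfg, epochs=2)
        m2, _ = finetune_heads(short_records, cfg, epochs=2)
        p1 = predict_records(m1, short_records[:4])
        p2 = predict_records(m2, short_records[:4])
        for a, b in zip(p1, p2):
            assert np.allclose(a.p_aro, b.p_aro, atol=0)
            assert a.p_dep.sum() == pytest.approx(1.0, abs=1e-6)

    def test_heads_are_separable_given_frozen_trunk(self, short_records):
        """Permuting one task's labels must not move the other heads' outputs
        when only the heads train: each head owns its parameters and loss."""
        cfg = TPEDNConfig(**{**TINY, "input_length": 300})
        base, _ = finetune_heads(short_records, cfg, epochs=2, freeze_trunk=True)

        rng = np.random.default_rng(0)
        perm = rng.permutation(len(short_records))
        scrambled = [
            type(rec)(
                subject_id=rec.subject_id, episode_id=rec.episode_id, signals=rec.signals,
                labels=type(rec.labels)(
                    depression=short_records[j].labels.depression,  # permuted task
                    valence=rec.labels.valence,
                    arousal=rec.labels.arousal,
                    emotion=rec.labels.emotion,
                ),
                self_report=rec.self_report,
            )
            for rec, j in zip(short_records, perm)
        ]
        other, _ = finetune_heads(scrambled, cfg, epochs=2, freeze_trunk=True)
        xs = signals_to_arrays(short_records[:6], cfg)
        pa, pb = base.predict_proba(xs), other.predict_proba(xs)
        assert np.allclose(pa["arousal"], pb["arousal"], atol=1e-12)
        assert np.allclose(pa["valence"], pb["valence"], atol=1e-12)
        assert not np.allclose(pa["depression"], pb["depression"], atol=1e-6)

    def test_empty_training_set_rejected(self):
        with pytest.raises(DataError):
            pretrain_ssl([], TPEDNConfig(**TINY))

    def test_checkpoint_roundtrip(self, short_records, tmp_path):
        cfg = TPEDNConfig(**{**TINY, "input_length": 300})
        model, history = finetune_heads(short_records, cfg, epochs=1)
        save_checkpoint(model, tmp_path / "ck.npz", history)
        back = load_checkpoint(tmp_path / "ck.npz")
        xs = signals_to_arrays(short_records[:3], cfg)
        assert np.allclose(
            model.predict_proba(xs)["arousal"], back.predict_proba(xs)["arousal"], atol=0
        )
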