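"""Image branch: triangular occupancy, dense wiring, gradients, sensitivity."""

import numpy as np
import pytest

from s2cfl.dc2ptn import (
    DC2PTN,
    DSQOutput,
    GridConfig,
    build_grid,
    expected_wiring,
    load_checkpoint,
    save_checkpoint,
    train_dc2ptn,
    triangular_cells,
)
from s2cfl.errors import ConfigurationError, ShapeError
from s2cfl.nn.layers import bce_logits

TINY = dict(
    image_size=(32, 32),
    in_channels=4,
    row_widths=(4, 4, 4, 4, 4),
    dc_channels=4,
    tap_dims=(6, 10),
    batch_size=4,
    seed=0,
)


@pytest.fixture(scope="module")
def tiny_model():
    return DC2PTN(GridConfig(**TINY))


@pytest.fixture(scope="module")
def tiny_inputs():
    rng = np.random.default_rng(0)
    return (
        rng.random((3, 4, 32, 32)),
        rng.random((3, 3)),
        (rng.normal(size=(3, 6)), rng.normal(size=(3, 10))),
    )


class TestGridStructure:
    def test_triangular_occupancy_has_15_cells(self):
        cells = triangular_cells()
        assert len(cells) == 15
        assert all(1 <= j <= 5 - i for j, i in cells)
        by_column = {i: sum(1 for _, ci in cells if ci == i) for i in range(5)}
        assert by_column == {0: 5, 1: 4, 2: 3, 3: 2, 4: 1}

    def test_seeded_builds_are_identical(self):
        a = build_grid(GridConfig(**TINY), seed=5)
        b = build_grid(GridConfig(**TINY), seed=5)
        assert a.param_checksum() == b.param_checksum()

    def test_wrong_row_count_rejected(self):
        with pytest.raises(ConfigurationError):
            GridConfig(**{**TINY, "n_rows": 4})

    def test_backbone_pyramid_resolutions(self, tiny_model, tiny_inputs):
        images, probs, _ = tiny_inputs
        from s2cfl.nn import Tensor

        _, sw_prime = tiny_model.first_column_forward(Tensor(images), Tensor(probs))
        for j in range(1, 6):
            assert sw_prime[j].shape[-2:] == (32 // 2**j, 32 // 2**j)

    def test_shape_mismatch_rejected(self, tiny_model):
        from s2cfl.nn import Tensor

        with pytest.raises(ShapeError):
            tiny_model.first_column_forward(
                Tensor(np.zeros((1, 4, 16, 16))), Tensor(np.zeros((1, 3)))
            )


class TestWiring:
    def test_recorded_wiring_matches_dense_grid_equations(self, tiny_model, tiny_inputs):
        tiny_model.forward(*tiny_inputs)
        assert tiny_model.wiring == expected_wiring()

    def test_cell_1_3_consumes_exactly_its_prescribed_inputs(self, tiny_model, tiny_inputs):
        tiny_model.forward(*tiny_inputs)
        assert tiny_model.wiring["Sw[1][3]"] == [
            "Sw[1][0]",
            "Sw[1][1]",
            "Sw[1][2]",
            "Vq(FF[2][2])",
        ]

    def test_column_zero_cells_have_no_vq_term(self, tiny_model, tiny_inputs):
        tiny_model.forward(*tiny_inputs)
        for j in range(1, 6):
            assert not any("Vq" in src for src in tiny_model.wiring[f"Sw[{j}][0]"])

    def test_dense_column_strict_fanin(self, tiny_model, tiny_inputs):
        tiny_model.forward(*tiny_inputs)
        assert tiny_model.wiring["DC[0][1]"] == ["DC[0][0]", "FF[1][0]"]
        assert tiny_model.wiring["DC[0][5]"] == [
            f"DC[0][{p}]" for p in range(5)
        ] + ["FF[1][4]"]

    def test_dc_fanin_channel_arithmetic(self, tiny_model):
        c = tiny_model.config.dc_channels
        for k in range(1, 6):
            conv = tiny_model.dc_conv[k - 1]
            assert conv.weight.shape[1] == k * c + tiny_model.config.row_widths[0]


class TestSensitivity:
    def test_conditioning_is_live(self, tiny_model, tiny_inputs):
        images, probs, taps = tiny_inputs
        base = tiny_model.forward(images, probs, taps).data
        bumped = probs.copy()
        bumped[:, 2] += 0.2  # arousal plane
        out = tiny_model.forward(images, bumped, taps).data
        assert not np.allclose(base, out)

    def test_dense_path_is_live(self, tiny_model, tiny_inputs):
        images, probs, taps = tiny_inputs
        base = tiny_model.forward(images, probs, taps).data
        saved = tiny_model.stem.weight.data.copy()
        tiny_model.stem.weight.data[:] = 0.0  # kills DC[0][0] content
        try:
            out = tiny_model.forward(images, probs, taps).data
        finally:
            tiny_model.stem.weight.data = saved
        assert not np.allclose(base, out)

    def test_mfp_cross_scale_flow(self, tiny_inputs):
        from s2cfl.nn import Tensor

        model = DC2PTN(GridConfig(**TINY))
        images, probs, _ = tiny_inputs
        _, sw_prime = model.first_column_forward(Tensor(images), Tensor(probs))
        sw0_a = model.mixed_feature_pyramid(sw_prime)
        perturbed = dict(sw_prime)
        perturbed[3] = sw_prime[3] * 2.0 + 0.3
        sw0_b = model.mixed_feature_pyramid(perturbed)
        assert not np.allclose(sw0_a[1].data, sw0_b[1].data)  # row 3 reaches row 1
        assert np.array_equal(sw0_a[4].data, sw0_b[4].data)  # row 4 passes through

    def test_forward_is_finite_and_deterministic(self, tiny_model, tiny_inputs):
        a = tiny_model.forward(*tiny_inputs).data
        b = tiny_model.forward(*tiny_inputs).data
        assert np.array_equal(a, b)
        assert np.all(np.isfinite(a))


class TestDSQ:
    def test_scores_in_open_unit_interval(self, tiny_model, tiny_inputs):
        images, probs, taps = tiny_inputs
        scores = tiny_model.predict_scores(images, probs, taps)
        assert scores.shape == (3, 3)
        assert np.all((scores > 0) & (scores < 1))
        out = DSQOutput(dep=scores[0, 0], val=scores[0, 1], aro=scores[0, 2])
        assert 0 < out.aro < 1

    def test_all_parameters_receive_gradient(self):
        # default 64x64 geometry: every attention stage spans multiple tokens
        cfg = GridConfig(
            image_size=(64, 64), in_channels=4, row_widths=(4, 4, 4, 4, 4),
            dc_channels=4, tap_dims=(6, 10), batch_size=4, seed=1,
        )
        model = DC2PTN(cfg)
        rng = np.random.default_rng(2)
        logits = model.forward(
            rng.random((4, 4, 64, 64)), rng.random((4, 3)),
            (rng.normal(size=(4, 6)), rng.normal(size=(4, 10))),
        )
        loss = bce_logits(logits, rng.integers(0, 2, size=(4, 3)).astype(float))
        model.zero_grad()
        loss.backward()
        dead = [
            name
            for name, p in model.named_parameters()
            if p.grad is None or float(np.abs(p.grad).sum()) == 0.0
        ]
        assert dead == []

    def test_training_reduces_bce(self, tiny_inputs):
        rng = np.random.default_rng(3)
        images = rng.random((24, 4, 32, 32))
        probs = rng.random((24, 3))
        taps = (rng.normal(size=(24, 6)), rng.normal(size=(24, 10)))
        labels = {
            "depression": (probs[:, 0] > 0.5).astype(int),
            "valence": (probs[:, 1] > 0.5).astype(int),
            "arousal": (probs[:, 2] > 0.5).astype(int),
        }
        cfg = GridConfig(**{**TINY, "batch_size": 8, "lr": 3e-3})
        _, history = train_dc2ptn(images, probs, taps, labels, cfg, epochs=4)
        assert history[-1]["train_bce"] < history[0]["train_bce"]

    def test_checkpoint_roundtrip(self, tiny_model, tiny_inputs, tmp_path):
        images, probs, taps = tiny_inputs
        save_checkpoint(tiny_model, tmp_path / "dc.npz")
        back = load_checkpoint(tmp_path / "dc.npz")
        assert np.allclose(
            tiny_model.predict_scores(images, probs, taps),
            back.predict_scores(images, probs, taps),
            atol=0,
        )
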