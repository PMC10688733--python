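"""Architecture audit: shape chains, parameter counts, forward determinism."""

import numpy as np
import pytest

from capsoct.model_assembly import (
    ArchitectureConfig,
    LayerSpec,
    baseline_config,
    build_model,
    conv_output_shape,
    default_config,
    load_checkpoint,
    reconstruction_loss,
    save_checkpoint,
    tiny_config,
)


class TestConvOutputShape:
    @pytest.mark.parametrize(
        "in_hw,kernel,stride,padding,expected",
        [
            ((48, 48), (5, 5), 2, "valid", (22, 22)),
            ((22, 22), (3, 3), 2, "valid", (10, 10)),
            ((10, 10), (1, 1), 1, "valid", (10, 10)),
            ((10, 10), (1, 1), 1, "same", (10, 10)),
            ((10, 10), (9, 9), 3, "same", (4, 4)),
        ],
    )
    def test_printed_dimension_chain(self, in_hw, kernel, stride, padding, expected):
        assert conv_output_shape(in_hw, kernel, stride, padding) == expected

    def test_oversized_kernel_rejected(self):
        with pytest.raises(ValueError):
            conv_output_shape((4, 4), (5, 5), 1, "valid")


@pytest.fixture(scope="module")
def default_trace():
    _, trace = build_model(default_config(), seed=0)
    return trace


class TestDefaultArchitecture:
    def test_conv_stack_dimensions(self, default_trace):
        assert default_trace.out_shape("conv1") == (22, 22, 256)
        assert default_trace.out_shape("conv2") == (10, 10, 256)
        assert default_trace.out_shape("conv3") == (10, 10, 256)

    def test_clahe_layers_shape_preserving_zero_params(self, default_trace):
        assert default_trace.out_shape("clahe1") == (48, 48, 3)
        assert default_trace.out_shape("clahe2") == (10, 10, 256)
        assert default_trace.params_of("clahe1") == 0
        assert default_trace.params_of("clahe2") == 0

    def test_576_primary_capsules_8d(self, default_trace):
        assert default_trace.out_shape("primary_caps") == (576, 8)

    def test_class_capsules_16d(self, default_trace):
        assert default_trace.out_shape("class_caps") == (4, 16)

    def test_decoder_widths(self, default_trace):
        assert default_trace.out_shape("decoder1") == (512,)
        assert default_trace.out_shape("decoder2") == (1024,)
        assert default_trace.out_shape("decoder3") == (6912,)  # 48*48*3

    def test_param_count_reproducible(self, default_trace):
        _, again = build_model(default_config(), seed=99)
        assert again.total_params == default_trace.total_params
        per_layer = [(r[0], r[3]) for r in again.rows]
        assert per_layer == [(r[0], r[3]) for r in default_trace.rows]

    def test_removing_clahe_changes_no_shapes_or_params(self, default_trace):
        cfg = default_config()
        stripped = ArchitectureConfig(
            **{
                **{f: getattr(cfg, f) for f in cfg.__dataclass_fields__},
                "layers": tuple(l for l in cfg.layers if l.kind != "clahe"),
            }
        )
        _, trace = build_model(stripped, seed=0)
        kept = [r for r in default_trace.rows if not r[0].startswith("clahe")]
        assert [(r[2], r[3]) for r in trace.rows] == [(r[2], r[3]) for r in kept]

    def test_baseline_preset_single_conv_no_clahe(self):
        _, trace = build_model(baseline_config(), seed=0)
        names = [r[0] for r in trace.rows]
        assert names[0] == "conv1" and "clahe1" not in names
        assert trace.out_shape("conv1") == (40, 40, 256)
        assert trace.out_shape("primary_caps") == (16 * 16 * 32, 8)


@pytest.fixture(scope="module")
def toy():
    cfg = ArchitectureConfig(
        input_shape=(12, 12, 1),
        layers=(
            LayerSpec("conv", (3, 3), 2, "valid", out_channels=8, activation="relu"),
            LayerSpec("primary_caps", (3, 3), 2, "valid", capsule_types=2, capsule_dim=4),
        ),
        n_classes=2,
        class_capsule_dim=6,
        decoder_units=(16, 144),
    )
    return build_model(cfg, seed=3)


class TestForward:
    def test_toy_shape_chain_and_outputs(self, toy):
        model, trace = toy
        assert trace.out_shape("conv1") == (5, 5, 8)
        assert trace.out_shape("primary_caps") == (2 * 2 * 2, 4)
        x = np.random.default_rng(0).random((3, 12, 12, 1), dtype=np.float32)
        out = model.forward(x)
        assert out["lengths"].shape == (3, 2)
        assert out["recon"].shape == (3, 144)
        assert np.all(out["recon"].data >= 0) and np.all(out["recon"].data <= 1)
        assert np.all(out["lengths"].data >= 0) and np.all(out["lengths"].data < 1)

    def test_zero_weights_zero_lengths(self, toy):
        model, _ = toy
        saved = model.get_weights()
        model.set_weights([np.zeros_like(w) for w in saved])
        x = np.random.default_rng(1).random((2, 12, 12, 1), dtype=np.float32)
        assert np.all(model.forward(x)["lengths"].data < 1e-5)
        model.set_weights(saved)

    def test_identical_inputs_identical_outputs(self, toy):
        model, _ = toy
        x = np.random.default_rng(2).random((1, 12, 12, 1), dtype=np.float32)
        batch = np.concatenate([x, x], axis=0)
        out = model.forward(batch)["lengths"].data
        assert np.array_equal(out[0], out[1])

    def test_forward_bitwise_reproducible(self):
        x = np.random.default_rng(5).random((2, 48, 48, 3), dtype=np.float32)
        runs = []
        for _ in range(2):
            model, _ = build_model(tiny_config(), seed=11)
            runs.append(model.forward(x)["lengths"].data)
        assert np.array_equal(runs[0], runs[1])

    def test_input_clahe_precompute_is_equivalent(self):
        model, _ = build_model(tiny_config(), seed=4)
        x = np.random.default_rng(3).random((2, 48, 48, 3), dtype=np.float32)
        direct = model.forward(x)["lengths"].data
        pre = model.forward(model.preprocess_input(x), skip_input_clahe=True)[
            "lengths"
        ].data
        assert np.allclose(direct, pre, atol=1e-6)

    def test_shape_mismatch_rejected(self, toy):
        model, _ = toy
        with pytest.raises(ValueError):
            model.forward(np.zeros((1, 10, 10, 1), dtype=np.float32))


class TestGradientFlow:
    def _loss(self, model, x, y):
        from capsoct.capsule_ops import margin_loss

        out = model.forward(x, labels=y)
        onehot = np.eye(2)[y]
        loss = margin_loss(out["lengths"], onehot)
        return loss + reconstruction_loss(out["recon"], x.reshape(len(x), -1), 0.01)

    def test_all_trainable_tensors_receive_gradients(self, toy):
        model, _ = toy
        x = np.random.default_rng(0).random((4, 12, 12, 1), dtype=np.float32)
        y = np.array([0, 1, 0, 1])
        loss = self._loss(model, x, y)
        for p in model.params:
            p.grad = None
        loss.backward()
        for p in model.params:
            assert p.grad is not None and np.any(p.grad != 0), p.name

    def test_spot_check_against_finite_differences(self, toy):
        model, _ = toy
        saved = model.get_weights()
        # float64, and away from the zero-bias init (ReLU kinks break FD)
        wrng = np.random.default_rng(7)
        for p in model.params:
            p.data = wrng.normal(0.0, 0.1, size=p.data.shape)
        x = np.random.default_rng(1).random((2, 12, 12, 1)).astype(np.float64)
        y = np.array([0, 1])
        loss = self._loss(model, x, y)
        for p in model.params:
            p.grad = None
        loss.backward()
        rng = np.random.default_rng(2)
        for p in model.params:
            flat = p.data.ravel()
            i = rng.integers(len(flat))
            eps = 1e-5
            orig = flat[i]
            flat[i] = orig + eps
            hi = float(self._loss(model, x, y).data)
            flat[i] = orig - eps
            lo = float(self._loss(model, x, y).data)
            flat[i] = orig
            numeric = (hi - lo) / (2 * eps)
            analytic = p.grad.ravel()[i]
            denom = max(abs(numeric), abs(analytic), 1e-6)
            assert abs(numeric - analytic) / denom < 1e-3, p.name
        model.set_weights(saved)


class TestReconstructionLoss:
    def test_perfect_reconstruction_zero(self):
        x = np.random.default_rng(0).random((2, 10))
        assert reconstruction_loss(x, x, 1.0) == 0.0

    def test_zero_weight_contributes_nothing(self):
        r = np.random.default_rng(1).random((2, 10))
        assert reconstruction_loss(r, np.zeros_like(r), 0.0) == 0.0

    def test_unit_pixel_error_scales_with_weight(self):
        r = np.zeros((1, 10))
        t = np.zeros((1, 10))
        r[0, 3] = 1.0
        assert reconstruction_loss(r, t, 0.25) == pytest.approx(0.25)


class TestConfigAndCheckpoint:
    def test_decoder_size_must_match_input(self):
        with pytest.raises(ValueError):
            ArchitectureConfig(input_shape=(8, 8, 1), decoder_units=(16, 100))

    def test_config_dict_round_trip(self):
        cfg = tiny_config()
        assert ArchitectureConfig.from_dict(cfg.to_dict()) == cfg

    @pytest.mark.parametrize("name", ["cfg.yaml", "cfg.json"])
    def test_config_file_round_trip(self, tmp_path, name):
        from capsoct.model_assembly import load_config, save_config

        cfg = tiny_config()
        path = save_config(cfg, tmp_path / name)
        assert load_config(path) == cfg

    def test_checkpoint_round_trip(self, tmp_path):
        model, _ = build_model(tiny_config(), seed=7)
        x = np.random.default_rng(0).random((2, 48, 48, 3), dtype=np.float32)
        before = model.forward(x)["lengths"].data
        path = save_checkpoint(model, tmp_path / "m.npz")
        restored = load_checkpoint(path)
        after = restored.forward(x)["lengths"].data
        assert np.array_equal(before, after)
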