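import numpy as np
import pytest

from wavetap.nn import (
    Adam,
    DEFAULT_FIRES,
    Fire,
    FireSpec,
    ModelConfig,
    build_baseline_squeezenet,
    build_fire,
    build_model,
    softmax_cross_entropy,
)


def fire_param_count(c_in, squeeze, expand):
    """Closed-form: s(c+1) + e1(s+1) + e3(9s+1), e1 = ceil(e/2)."""
    e1 = (expand + 1) // 2
    e3 = expand - e1
    return (
        squeeze * (c_in + 1)
        + e1 * (squeeze + 1)
        + e3 * (9 * squeeze + 1)
    )


def conv_param_count(c_in, c_out, k):
    return c_out * (c_in * k * k + 1)


class TestFire:
    def test_table_sizes_output_channels(self):
        x = np.random.default_rng(0).random((2, 3, 16, 16)).astype(np.float32)
        fire = build_fire(3, FireSpec(24, 48))
        assert fire.forward(x).shape == (2, 48, 16, 16)

    def test_spatial_size_preserved(self):
        x = np.zeros((1, 5, 13, 9), dtype=np.float32)
        assert build_fire(5, FireSpec(4, 16)).forward(x).shape[2:] == (13, 9)

    @pytest.mark.parametrize("c_in,s,e", [(3, 24, 48), (48, 48, 96), (128, 64, 256), (7, 3, 9)])
    def test_parameter_count_closed_form(self, c_in, s, e):
        assert build_fire(c_in, FireSpec(s, e)).param_count() == fire_param_count(c_in, s, e)

    def test_odd_expand_rounds_1x1_branch_up(self):
        fire = Fire(4, 3, 9)
        assert fire.e1.cout == 5 and fire.e3.cout == 4

    @pytest.mark.parametrize("s,e", [(0, 8), (8, 8), (9, 8)])
    def test_invalid_spec_rejected(self, s, e):
        with pytest.raises(ValueError):
            FireSpec(s, e)


class TestModifiedSqueezeNet:
    def test_layer_inventory(self):
        model = build_model(ModelConfig())
        kinds = [type(l).__name__ for l in model.layers]
        assert kinds.count("Fire") == 7
        assert kinds.count("MaxPool2d") == 6
        assert kinds[0] == "BatchNorm2d"
        assert kinds[-2:] == ["GlobalAvgPool", "Linear"]

    def test_fire_sizes_match_default_table(self):
        model = build_model(ModelConfig())
        fires = [l for l in model.layers if isinstance(l, Fire)]
        got = [(f.squeeze_channels, f.expand_channels) for f in fires]
        assert got == list(DEFAULT_FIRES)

    def test_shape_propagation_240_to_3x3(self):
        model = build_model(ModelConfig())
        rows = model.summary((240, 240, 3))
        by_name = {r["layer"]: r["output_shape"] for r in rows}
        assert by_name["pool6"] == (96, 3, 3)
        assert by_name["fire7"] == (48, 3, 3)
        assert by_name["fc"] == (2,)

    def test_total_parameter_count_closed_form(self):
        model = build_model(ModelConfig())
        expected = 2 * 3  # input batchnorm gamma/beta
        c_in = 3
        for s, e in DEFAULT_FIRES:
            expected += fire_param_count(c_in, s, e)
            c_in = e
        expected += 2 * (c_in + 1)  # fc
        assert model.param_count() == expected

    def test_construction_is_pure(self):
        a = build_model(ModelConfig(seed=3)).summary((64, 64, 3))
        b = build_model(ModelConfig(seed=3)).summary((64, 64, 3))
        assert a == b

    def test_forward_finite_on_zero_image(self):
        model = build_model(ModelConfig(input_shape=(64, 64, 3)))
        out = model.forward(np.zeros((1, 3, 64, 64), dtype=np.float32), train=False)
        assert out.shape == (1, 2) and np.all(np.isfinite(out))

    def test_too_small_input_rejected(self):
        with pytest.raises(ValueError):
            ModelConfig(input_shape=(32, 32, 3))

    def test_one_adam_step_decreases_batch_loss(self):
        rng = np.random.default_rng(0)
        model = build_model(ModelConfig(input_shape=(64, 64, 3), seed=0))
        x = rng.random((4, 3, 64, 64)).astype(np.float32)
        y = np.array([0, 1, 0, 1])
        opt = Adam(model, lr=1e-3)
        loss0, d = softmax_cross_entropy(model.forward(x), y)
        model.backward(d)
        opt.step()
        loss1, _ = softmax_cross_entropy(model.forward(x), y)
        assert loss1 < loss0

    def test_checkpoint_roundtrip(self, tmp_path):
        model = build_model(ModelConfig(input_shape=(64, 64, 3), seed=1))
        x = np.random.default_rng(2).random((2, 3, 64, 64)).astype(np.float32)
        ref = model.forward(x, train=False)
        model.save(tmp_path / "w.npz")
        other = build_model(ModelConfig(input_shape=(64, 64, 3), seed=9))
        other.load(tmp_path / "w.npz")
        np.testing.assert_allclose(other.forward(x, train=False), ref, rtol=1e-6)


class TestBaselineSqueezeNet:
    def test_contains_eight_fires(self):
        model = build_baseline_squeezenet()
        assert sum(isinstance(l, Fire) for l in model.layers) == 8

    def test_forward_output_is_two_vector(self):
        model = build_baseline_squeezenet((128, 128, 3))
        out = model.forward(np.zeros((1, 3, 128, 128), dtype=np.float32), train=False)
        assert out.shape == (1, 2) and np.all(np.isfinite(out))

    def test_parameter_count_closed_form(self):
        model = build_baseline_squeezenet()
        fires = ((16, 128), (16, 128), (32, 256), (32, 256),
                 (48, 384), (48, 384), (64, 512), (64, 512))
        expected = conv_param_count(3, 96, 7)
        c_in = 96
        for s, e in fires:
            expected += fire_param_count(c_in, s, e)
            c_in = e
        expected += conv_param_count(c_in, 2, 1)
        assert model.param_count() == expected


class TestGradientsNumerically:
    def test_conv_backward_matches_finite_differences(self):
        from wavetap.nn import Conv2d

        rng = np.random.default_rng(0)
        conv = Conv2d(2, 3, 3, padding=1, rng=rng)
        x = rng.random((1, 2, 5, 5)).astype(np.float32)
        out = conv.forward(x)
        g = rng.random(out.shape).astype(np.float32)
        dx = conv.backward(g)
        eps = 1e-3
        for idx in [(0, 0, 2, 2), (0, 1, 0, 4)]:
            xp, xm = x.copy(), x.copy()
            xp[idx] += eps
            xm[idx] -= eps
            num = (np.sum(conv.forward(xp) * g) - np.sum(conv.forward(xm) * g)) / (2 * eps)
            assert dx[idx] == pytest.approx(num, rel=5e-2, abs=1e-3)
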