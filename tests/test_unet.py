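"""Architecture construction, shape audit, gradients, checkpoints."""

import numpy as np
import pytest

from sleepseg.errors import ConfigError, ShapeError
from sleepseg.nn import (
    UNetConfig,
    build_unet,
    forward_predict,
    load_checkpoint,
    save_checkpoint,
    summarize,
)


class TestConfigInvariants:
    @pytest.mark.parametrize("resolution,input_length", [
        ("full", 2 ** 23), ("half", 2 ** 22), ("eighth", 2 ** 20),
    ])
    def test_study_resolutions_share_layer_count_and_bottleneck(
        self, resolution, input_length
    ):
        config = UNetConfig.for_resolution(resolution)
        summary = summarize(config)
        assert config.input_length == input_length
        assert summary.conv_layer_count == 35
        assert summary.bottleneck_shape == (256, 480)

    def test_small_config_layer_count_formula(self):
        config = UNetConfig(input_length=2 ** 12, pooling_sizes=(4, 4, 4),
                            channel_schedule=(12, 16, 24))
        summary = summarize(config)
        assert summary.conv_layer_count == 2 * 3 + 2 + 2 * 3 + 1
        assert summary.bottleneck_shape == (64, 24)

    def test_inconsistent_pooling_product_rejected(self):
        with pytest.raises(ConfigError):
            UNetConfig(input_length=1024, pooling_sizes=(4, 4),
                       channel_schedule=(8, 16), bottleneck_length=32)

    def test_decreasing_channel_schedule_rejected(self):
        with pytest.raises(ConfigError):
            UNetConfig(input_length=1024, pooling_sizes=(4, 4),
                       channel_schedule=(16, 8))

    def test_even_kernel_rejected(self):
        with pytest.raises(ConfigError):
            UNetConfig(input_length=1024, pooling_sizes=(4, 4),
                       channel_schedule=(8, 16), kernel_size=6)

    def test_parameter_count_regression_small_config(self):
        # hand-computed from the layer inventory: conv W + b and batchnorm
        # gamma + beta per stage, kernel 3, schedule (2, 3), 2 input channels
        config = UNetConfig(input_length=64, in_channels=2,
                            pooling_sizes=(4, 4), channel_schedule=(2, 3),
                            kernel_size=3)
        assert summarize(config).parameter_count == 327

    def test_analytic_count_matches_built_network(self):
        config = UNetConfig(input_length=512, pooling_sizes=(4, 4, 4),
                            channel_schedule=(12, 16, 24))
        net, summary = build_unet(config, seed=0)
        assert summary.parameter_count == summarize(config).parameter_count
        assert summary.conv_layer_count == summarize(config).conv_layer_count


class TestForward:
    def test_output_length_and_range(self, rng):
        config = UNetConfig(input_length=512, pooling_sizes=(4, 4, 4),
                            channel_schedule=(8, 12, 16))
        net, _ = build_unet(config, seed=1)
        x = rng.normal(size=(13, 512))
        p = net.forward(x)
        assert p.shape == (512,)
        assert p.min() >= 0.0 and p.max() <= 1.0

    def test_inference_is_deterministic(self, rng):
        config = UNetConfig(input_length=256, pooling_sizes=(4, 4),
                            channel_schedule=(6, 8))
        net, _ = build_unet(config, seed=2)
        x = rng.normal(size=(13, 256))
        np.testing.assert_array_equal(forward_predict(net, x),
                                      forward_predict(net, x))

    def test_shape_mismatch_rejected(self, rng):
        config = UNetConfig(input_length=256, pooling_sizes=(4, 4),
                            channel_schedule=(6, 8))
        net, _ = build_unet(config, seed=2)
        with pytest.raises(ShapeError):
            net.forward(rng.normal(size=(13, 128)))

    @pytest.mark.parametrize("seed", range(6))
    def test_randomized_config_shape_audit(self, seed):
        # random valid configs: skip concatenation must be well-formed and
        # the output length must equal the input length
        rng = np.random.default_rng(seed)
        n_levels = int(rng.integers(1, 5))
        pooling = tuple(int(rng.choice([2, 4])) for _ in range(n_levels))
        bottleneck = int(rng.choice([4, 8, 16]))
        channels = tuple(
            np.sort(rng.integers(3, 12, size=n_levels)).tolist()
        )
        input_length = int(np.prod(pooling)) * bottleneck
        config = UNetConfig(
            input_length=input_length, pooling_sizes=pooling,
            channel_schedule=channels,
            kernel_size=int(rng.choice([3, 5, 7])),
            pooling_type=str(rng.choice(["max", "avg"])),
        )
        net, summary = build_unet(config, seed=seed)
        x = rng.normal(size=(13, input_length))
        p = net.forward(x)
        assert p.shape == (input_length,)
        assert summary.conv_layer_count == 4 * n_levels + 3
        assert summary.bottleneck_shape == (bottleneck, channels[-1])


class TestGradients:
    def test_backward_matches_finite_differences(self):
        from sleepseg.training import _loss_and_dlogits

        config = UNetConfig(input_length=64, in_channels=2,
                            pooling_sizes=(4, 4), channel_schedule=(3, 4),
                            kernel_size=3)
        net, _ = build_unet(config, seed=1, dtype=np.float64)
        rng = np.random.default_rng(2)
        x = rng.normal(size=(2, 64))
        y = (rng.random(64) < 0.3).astype(np.int8)

        def loss():
            p = net.forward(x, training=True)
            return _loss_and_dlogits("cross_entropy", y, p)

        _, dlogits = loss()
        net.backward(dlogits)
        grads = [g.copy() for g in net.gradients()]
        params = net.parameters()
        for pi in range(len(params)):
            p = params[pi]
            for _ in range(2):
                idx = tuple(int(rng.integers(0, s)) for s in p.shape)
                eps = 1e-6
                old = p[idx]
                p[idx] = old + eps
                lp, _ = loss()
                p[idx] = old - eps
                lm, _ = loss()
                p[idx] = old
                numeric = (lp - lm) / (2 * eps)
                analytic = grads[pi][idx]
                assert abs(numeric - analytic) <= 1e-6 * (
                    1.0 + abs(numeric) + abs(analytic)
                )


class TestCheckpoint:
    def test_save_load_preserves_predictions(self, rng, tmp_path):
        config = UNetConfig(input_length=256, pooling_sizes=(4, 4),
                            channel_schedule=(6, 8))
        net, _ = build_unet(config, seed=3)
        x = rng.normal(size=(13, 256))
        before = forward_predict(net, x)
        save_checkpoint(net, tmp_path / "ckpt.npz")
        back = load_checkpoint(tmp_path / "ckpt.npz")
        np.testing.assert_array_equal(forward_predict(back, x), before)
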