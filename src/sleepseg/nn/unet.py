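"""The deep 1D encoder-decoder (U-Net) for per-sample arousal segmentation.

The encoder is a stack of "ccp" blocks (conv -> batchnorm -> ReLU, twice,
then pooling) that shrinks the time axis while growing channels; at full
scale it takes a zero-centered 2^23 = 8,388,608-sample record down to a
256-sample bottleneck while channels grow from 13 to 480, so that deep
layers see context spanning from seconds to hours.  The decoder mirrors it
with "ccu" blocks (parameter-free repetition upscaling, concatenation with
the same-scale encoder output, then two conv -> batchnorm -> ReLU stages).
A final width-1 convolution plus sigmoid yields one arousal probability per
input sample.  Convolutions are same-padded with kernel 7, so temporal
lengths are controlled purely by pooling/upscaling.

The full-resolution default has 2 * 8 (encoder) + 2 (bottleneck) + 2 * 8
(decoder) + 1 (output projection) = 35 convolution layers.  The per-level
channel widths are a free choice — only the 13 -> 480 endpoints are pinned —
and default to [30, 60, 90, 120, 180, 240, 360, 480].
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from ..errors import ConfigError, ShapeError
from .layers import (
    AvgPool1d,
    BatchNorm1d,
    Conv1d,
    MaxPool1d,
    ReLU,
    Upsample1d,
    sigmoid,
)

DEFAULT_CHANNEL_SCHEDULE = (30, 60, 90, 120, 180, 240, 360, 480)


@dataclass
class UNetConfig:
    """Architecture hyperparameters.

    ``product(pooling_sizes) * bottleneck_length`` must equal
    ``input_length``; the three study resolutions keep the bottleneck at 256
    samples by trading pooling factors: full (2^23) pools [4x7, 2], half
    (2^22) pools [4x6, 2, 2], eighth (2^20) pools [4x4, 2x4].
    """

    input_length: int = 2 ** 23
    in_channels: int = 13
    pooling_sizes: tuple[int, ...] = (4, 4, 4, 4, 4, 4, 4, 2)
    channel_schedule: tuple[int, ...] = DEFAULT_CHANNEL_SCHEDULE
    kernel_size: int = 7
    pooling_type: str = "max"
    bottleneck_length: Optional[int] = None

    def __post_init__(self) -> None:
        self.pooling_sizes = tuple(int(p) for p in self.pooling_sizes)
        self.channel_schedule = tuple(int(c) for c in self.channel_schedule)
        prod = math.prod(self.pooling_sizes)
        if self.bottleneck_length is None:
            if self.input_length % prod:
                raise ConfigError(
                    "input_length is not divisible by the pooling product"
                )
            self.bottleneck_length = self.input_length // prod
        if prod * self.bottleneck_length != self.input_length:
            raise ConfigError(
                f"product(pooling_sizes)={prod} x bottleneck_length="
                f"{self.bottleneck_length} != input_length={self.input_length}"
            )
        if len(self.pooling_sizes) != len(self.channel_schedule):
            raise ConfigError(
                "pooling_sizes and channel_schedule must have equal length"
            )
        if self.n_levels < 1:
            raise ConfigError("need at least one level")
        if any(p < 2 for p in self.pooling_sizes):
            raise ConfigError("pooling sizes must be >= 2")
        if any(b > a for a, b in zip(self.channel_schedule[1:],
                                     self.channel_schedule[:-1])):
            raise ConfigError("channel_schedule must be nondecreasing")
        if self.kernel_size < 1 or self.kernel_size % 2 == 0:
            raise ConfigError("kernel_size must be odd and positive")
        if self.pooling_type not in ("max", "avg"):
            raise ConfigError("pooling_type must be 'max' or 'avg'")

    @property
    def n_levels(self) -> int:
        return len(self.pooling_sizes)

    # --- canonical configurations -------------------------------------
    @classmethod
    def full(cls) -> "UNetConfig":
        return cls()

    @classmethod
    def half(cls) -> "UNetConfig":
        return cls(input_length=2 ** 22,
                   pooling_sizes=(4, 4, 4, 4, 4, 4, 2, 2))

    @classmethod
    def eighth(cls) -> "UNetConfig":
        return cls(input_length=2 ** 20,
                   pooling_sizes=(4, 4, 4, 4, 2, 2, 2, 2))

    @classmethod
    def scaled(cls, input_length: int = 2048) -> "UNetConfig":
        """Desk-scale configuration used by the synthetic-data experiments:
        three levels, ~43k parameters."""
        return cls(input_length=input_length,
                   pooling_sizes=(4, 4, 4),
                   channel_schedule=(12, 16, 24))

    @classmethod
    def for_resolution(cls, resolution: str) -> "UNetConfig":
        try:
            return {"full": cls.full, "half": cls.half,
                    "eighth": cls.eighth}[resolution]()
        except KeyError:
            raise ConfigError(f"unknown resolution {resolution!r}") from None

    def to_dict(self) -> dict:
        return {
            "input_length": self.input_length,
            "in_channels": self.in_channels,
            "pooling_sizes": list(self.pooling_sizes),
            "channel_schedule": list(self.channel_schedule),
            "kernel_size": self.kernel_size,
            "pooling_type": self.pooling_type,
            "bottleneck_length": self.bottleneck_length,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "UNetConfig":
        return cls(**d)


@dataclass
class NetworkSummary:
    """Derived layer/shape inventory of a constructed network."""

    conv_layer_count: int
    parameter_count: int
    #: (length, channels) after each encoder level's pooling, then the
    #: bottleneck (same length, deepest channel width).
    per_level_shapes: list[tuple[int, int]] = field(default_factory=list)

    @property
    def bottleneck_shape(self) -> tuple[int, int]:
        return self.per_level_shapes[-1]

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(
            {
                "conv_layer_count": self.conv_layer_count,
                "parameter_count": self.parameter_count,
                "per_level_shapes": [list(s) for s in self.per_level_shapes],
            },
            indent=2,
        )
        if path is not None:
            Path(path).write_text(payload + "\n")
        return payload


def _conv_bn_relu(in_c, out_c, k, rng, dtype):
    return [Conv1d(in_c, out_c, k, rng, dtype), BatchNorm1d(out_c, dtype=dtype),
            ReLU()]


class UNet1d:
    """Concrete network; construct via :func:`build_unet`."""

    def __init__(self, config: UNetConfig, rng: np.random.Generator,
                 dtype=np.float32):
        self.config = config
        self.dtype = dtype
        k = config.kernel_size
        ch = config.channel_schedule
        pool_cls = MaxPool1d if config.pooling_type == "max" else AvgPool1d

        self.enc_blocks: list[list] = []
        self.pools: list = []
        in_c = config.in_channels
        for level in range(config.n_levels):
            block = (_conv_bn_relu(in_c, ch[level], k, rng, dtype)
                     + _conv_bn_relu(ch[level], ch[level], k, rng, dtype))
            self.enc_blocks.append(block)
            self.pools.append(pool_cls(config.pooling_sizes[level]))
            in_c = ch[level]

        self.bottleneck = (_conv_bn_relu(ch[-1], ch[-1], k, rng, dtype)
                           + _conv_bn_relu(ch[-1], ch[-1], k, rng, dtype))

        self.dec_blocks: list[list] = []
        self.upsamples: list = []
        prev_c = ch[-1]
        for level in reversed(range(config.n_levels)):
            self.upsamples.append(Upsample1d(config.pooling_sizes[level]))
            block = (_conv_bn_relu(prev_c + ch[level], ch[level], k, rng, dtype)
                     + _conv_bn_relu(ch[level], ch[level], k, rng, dtype))
            self.dec_blocks.append(block)
            prev_c = ch[level]

        self.out_conv = Conv1d(ch[0], 1, 1, rng, dtype)

    # -- layer traversal (fixed order, used for optimizer and checkpoints) --
    def _all_layers(self):
        for block in self.enc_blocks:
            yield from block
        yield from self.bottleneck
        for block in self.dec_blocks:
            yield from block
        yield self.out_conv

    def parameters(self) -> list[np.ndarray]:
        out = []
        for layer in self._all_layers():
            out.extend(layer.params())
        return out

    def gradients(self) -> list[np.ndarray]:
        out = []
        for layer in self._all_layers():
            out.extend(layer.grads())
        return out

    def get_state(self) -> list[np.ndarray]:
        out = []
        for layer in self._all_layers():
            out.extend(layer.state())
        return out

    def set_state(self, arrays: list[np.ndarray]) -> None:
        i = 0
        for layer in self._all_layers():
            n = len(layer.state())
            layer.load_state(arrays[i : i + n])
            i += n

    # -- forward / backward ---------------------------------------------
    def forward_logits(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        cfg = self.config
        if x.shape != (cfg.in_channels, cfg.input_length):
            raise ShapeError(
                f"expected input of shape ({cfg.in_channels}, "
                f"{cfg.input_length}), got {x.shape}"
            )
        h = np.ascontiguousarray(x, dtype=self.dtype)
        skips = []
        for block, pool in zip(self.enc_blocks, self.pools):
            for layer in block:
                h = layer.forward(h, training)
            skips.append(h)
            h = pool.forward(h, training)
        for layer in self.bottleneck:
            h = layer.forward(h, training)
        self._skip_channels = []
        for up, block, skip in zip(self.upsamples, self.dec_blocks,
                                   reversed(skips)):
            h = up.forward(h, training)
            self._skip_channels.append((h.shape[0], skip.shape[0]))
            h = np.concatenate([h, skip], axis=0)
            for layer in block:
                h = layer.forward(h, training)
        z = self.out_conv.forward(h, training)
        return z[0]

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        """Per-sample arousal probabilities (sigmoid of the logits)."""
        return sigmoid(self.forward_logits(x, training))

    def backward(self, dlogits: np.ndarray) -> None:
        """Backpropagate a gradient w.r.t. the output logits, filling every
        layer's parameter gradients.  Must follow a training-mode forward."""
        dh = self.out_conv.backward(dlogits[None, :])
        dskips = []
        # decoder stages were applied deepest-first; undo shallowest-first
        for i in range(len(self.dec_blocks) - 1, -1, -1):
            for layer in reversed(self.dec_blocks[i]):
                dh = layer.backward(dh)
            up_c, skip_c = self._skip_channels[i]
            d_up, d_skip = dh[:up_c], dh[up_c:]
            dskips.append(d_skip)
            dh = self.upsamples[i].backward(d_up)
        for layer in reversed(self.bottleneck):
            dh = layer.backward(dh)
        # backward visited decoder stages shallowest-first, so dskips[j]
        # pairs with encoder level j
        for level in range(len(self.enc_blocks) - 1, -1, -1):
            dh = self.pools[level].backward(dh)
            dh = dh + dskips[level]
            for layer in reversed(self.enc_blocks[level]):
                dh = layer.backward(dh)

    def summary(self) -> NetworkSummary:
        return summarize(self.config, network=self)


def summarize(config: UNetConfig, network: Optional[UNet1d] = None) -> NetworkSummary:
    """Layer/shape inventory for a configuration.

    When an actual network is given, the convolution and parameter counts are
    taken from its layer objects; otherwise they are derived analytically
    from the config (the two agree — regression-tested).
    """
    n = config.n_levels
    shapes = []
    length = config.input_length
    for level in range(n):
        length //= config.pooling_sizes[level]
        shapes.append((length, config.channel_schedule[level]))
    shapes.append((config.bottleneck_length, config.channel_schedule[-1]))

    if network is not None:
        convs = [l for l in network._all_layers() if isinstance(l, Conv1d)]
        conv_count = len(convs)
        param_count = int(sum(p.size for p in network.parameters()))
    else:
        conv_count = 2 * n + 2 + 2 * n + 1

        def conv_params(in_c, out_c, k, bn=True):
            return out_c * in_c * k + out_c + (2 * out_c if bn else 0)

        k = config.kernel_size
        ch = config.channel_schedule
        param_count = 0
        in_c = config.in_channels
        for level in range(n):
            param_count += conv_params(in_c, ch[level], k)
            param_count += conv_params(ch[level], ch[level], k)
            in_c = ch[level]
        param_count += 2 * conv_params(ch[-1], ch[-1], k)
        prev_c = ch[-1]
        for level in reversed(range(n)):
            param_count += conv_params(prev_c + ch[level], ch[level], k)
            param_count += conv_params(ch[level], ch[level], k)
            prev_c = ch[level]
        param_count += conv_params(ch[0], 1, 1, bn=False)

    return NetworkSummary(conv_count, param_count, shapes)


def build_unet(config: UNetConfig, seed: int = 0,
               dtype=np.float32) -> tuple[UNet1d, NetworkSummary]:
    """Construct the network and its summary.  Config invariants are checked
    by :class:`UNetConfig` before any allocation."""
    rng = np.random.default_rng(seed)
    net = UNet1d(config, rng, dtype=dtype)
    return net, net.summary()


def forward_predict(net: UNet1d, x: np.ndarray) -> np.ndarray:
    """Deterministic inference: frozen batch-norm statistics, one probability
    per input sample."""
    return net.forward(np.asarray(x), training=False)


def save_checkpoint(net: UNet1d, path: str | Path) -> None:
    state = net.get_state()
    np.savez_compressed(
        path,
        config=json.dumps(net.config.to_dict()),
        n_arrays=len(state),
        **{f"arr_{i:04d}": a for i, a in enumerate(state)},
    )


def load_checkpoint(path: str | Path) -> UNet1d:
    with np.load(path, allow_pickle=False) as data:
        config = UNetConfig.from_dict(json.loads(str(data["config"])))
        n = int(data["n_arrays"])
        arrays = [data[f"arr_{i:04d}"] for i in range(n)]
    net, _ = build_unet(config)
    net.set_state(arrays)
    return net
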