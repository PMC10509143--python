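"""Bottleneck residual regressors with optional squeeze-and-excitation.

Two architectures share one code path:

* ``variant="full"`` — the standard 50-layer layout: 7x7/2 stem, 3x3/2
  max pool, bottleneck stages of (3, 4, 6, 3) blocks with output widths
  (256, 512, 1024, 2048), global average pooling and a single-unit
  regression head (the classification softmax is replaced by one linear
  output: the network predicts an Hb mass, not a class).
* ``variant="tiny"`` — a 3-stage bottleneck network (one block per
  stage, widths 32/64/128, ~30k parameters, 64x64 input) that trains in
  minutes on one CPU. It exists so the full pipeline, including CNN
  training, is exercisable at desk scale; the full layout is construct-
  and shape-tested.

``kind="se_resnet"`` inserts a squeeze-and-excitation block after each
bottleneck's final convolution (post-BN), before the residual addition:
the block pools each channel to a scalar (squeeze), passes the C-vector
through a C -> C/r -> C bottleneck MLP with logistic output gates in
(0, 1) (excitation), and rescales the channels by their gates. The
reduction ratio r defaults to 8 (an SE compression rate of 1/8).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np

from .layers import (
    BatchNorm2d,
    Conv2d,
    Dense,
    GlobalAvgPool,
    Layer,
    MaxPool2d,
    Param,
    ReLU,
    sigmoid,
)

__all__ = ["RegressorConfig", "SEBlock", "Bottleneck", "ResNetRegressor", "build_regressor"]

KindName = Literal["resnet", "se_resnet"]


@dataclass(frozen=True)
class RegressorConfig:
    """Training and architecture hyperparameters.

    Defaults follow the full-scale recipe (224x224x3 input, batch 16,
    Adam at 1e-3, 1000 epochs, MSE + L1 loss, SE reduction 8). The tiny
    preset shrinks input to 64px and epochs to 30 for CPU-scale runs.
    ``target_scale`` divides masses during optimization (mg are O(100),
    which destabilizes a freshly initialized network); predictions are
    rescaled back to mg.
    """

    input_size: int = 224
    batch_size: int = 16
    learning_rate: float = 1e-3
    epochs: int = 1000
    l1_weight: float = 1.0  # lambda in loss = MSE + lambda * L1
    se_reduction: int = 8
    variant: Literal["full", "tiny"] = "full"
    seed: int = 0
    target_scale: float = 500.0

    def __post_init__(self) -> None:
        if self.input_size < 32:
            raise ValueError("input_size must be >= 32")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.l1_weight < 0:
            raise ValueError("l1_weight must be >= 0")
        if self.se_reduction < 1:
            raise ValueError("se_reduction must be >= 1")

    @classmethod
    def tiny(cls, seed: int = 0, **overrides) -> "RegressorConfig":
        base = cls(input_size=64, epochs=30, variant="tiny", seed=seed)
        return replace(base, **overrides) if overrides else base


class SEBlock(Layer):
    """Squeeze-and-excitation channel attention.

    squeeze: s_c = mean over the spatial map of channel c
    excite:  g = sigmoid(W2 relu(W1 s + b1) + b2), W1: C -> C/r, W2: C/r -> C
    output:  y_c = g_c * x_c  (gates strictly in (0, 1))
    """

    def __init__(self, channels: int, reduction: int, rng: np.random.Generator) -> None:
        if channels % reduction != 0:
            raise ValueError(
                f"SE reduction {reduction} must divide the gated channel count {channels}"
            )
        self.channels = channels
        self.hidden = channels // reduction
        s1 = np.sqrt(2.0 / channels)
        s2 = np.sqrt(2.0 / self.hidden)
        self.w1 = Param(rng.standard_normal((channels, self.hidden)) * s1, "se.w1")
        self.b1 = Param(np.zeros(self.hidden), "se.b1")
        self.w2 = Param(rng.standard_normal((self.hidden, channels)) * s2, "se.w2")
        self.b2 = Param(np.zeros(channels), "se.b2")
        self._cache: tuple | None = None

    def params(self) -> list[Param]:
        return [self.w1, self.b1, self.w2, self.b2]

    def squeeze(self, x: np.ndarray) -> np.ndarray:
        return x.mean(axis=(2, 3))

    def gates(self, x: np.ndarray) -> np.ndarray:
        s = self.squeeze(x)
        h = np.maximum(s @ self.w1.value + self.b1.value, 0.0)
        return sigmoid(h @ self.w2.value + self.b2.value)

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        s = self.squeeze(x)
        pre_h = s @ self.w1.value + self.b1.value
        h = np.maximum(pre_h, 0.0)
        g = sigmoid(h @ self.w2.value + self.b2.value)
        self._cache = (x, s, pre_h, h, g)
        return x * g[:, :, None, None]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        x, s, pre_h, h, g = self._cache
        n, c, hh, ww = x.shape
        dx = grad * g[:, :, None, None]
        dg = (grad * x).sum(axis=(2, 3))  # (N, C)
        dz2 = dg * g * (1.0 - g)
        self.w2.grad += h.T @ dz2
        self.b2.grad += dz2.sum(axis=0)
        dh = dz2 @ self.w2.value.T
        dz1 = dh * (pre_h > 0)
        self.w1.grad += s.T @ dz1
        self.b1.grad += dz1.sum(axis=0)
        ds = dz1 @ self.w1.value.T
        dx += ds[:, :, None, None] / (hh * ww)
        return dx


class Bottleneck(Layer):
    """1x1 -> 3x3(stride) -> 1x1 bottleneck with BN, optional SE, shortcut."""

    def __init__(
        self,
        in_channels: int,
        mid_channels: int,
        out_channels: int,
        *,
        stride: int = 1,
        se_reduction: int | None = None,
        rng: np.random.Generator,
    ) -> None:
        self.conv1 = Conv2d(in_channels, mid_channels, 1, pad=0, rng=rng)
        self.bn1 = BatchNorm2d(mid_channels)
        self.conv2 = Conv2d(mid_channels, mid_channels, 3, stride=stride, pad=1, rng=rng)
        self.bn2 = BatchNorm2d(mid_channels)
        self.conv3 = Conv2d(mid_channels, out_channels, 1, pad=0, rng=rng)
        self.bn3 = BatchNorm2d(out_channels)
        self.se = SEBlock(out_channels, se_reduction, rng) if se_reduction else None
        self.relu1, self.relu2, self.relu_out = ReLU(), ReLU(), ReLU()
        if stride != 1 or in_channels != out_channels:
            self.proj: Conv2d | None = Conv2d(
                in_channels, out_channels, 1, stride=stride, pad=0, rng=rng
            )
            self.proj_bn: BatchNorm2d | None = BatchNorm2d(out_channels)
        else:
            self.proj = None
            self.proj_bn = None

    def params(self) -> list[Param]:
        parts: list[Layer] = [self.conv1, self.bn1, self.conv2, self.bn2, self.conv3, self.bn3]
        if self.se is not None:
            parts.append(self.se)
        if self.proj is not None:
            parts.extend([self.proj, self.proj_bn])
        return [p for layer in parts for p in layer.params()]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        out = self.relu1.forward(self.bn1.forward(self.conv1.forward(x, train), train), train)
        out = self.relu2.forward(self.bn2.forward(self.conv2.forward(out, train), train), train)
        out = self.bn3.forward(self.conv3.forward(out, train), train)
        if self.se is not None:
            out = self.se.forward(out, train)
        if self.proj is not None:
            shortcut = self.proj_bn.forward(self.proj.forward(x, train), train)
        else:
            shortcut = x
        return self.relu_out.forward(out + shortcut, train)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        grad = self.relu_out.backward(grad)
        if self.proj is not None:
            dx = self.proj.backward(self.proj_bn.backward(grad))
        else:
            dx = grad
        branch = grad
        if self.se is not None:
            branch = self.se.backward(branch)
        branch = self.conv3.backward(self.bn3.backward(branch))
        branch = self.conv2.backward(self.bn2.backward(self.relu2.backward(branch)))
        branch = self.conv1.backward(self.bn1.backward(self.relu1.backward(branch)))
        return dx + branch


_FULL_STAGES = [
    # (blocks, mid, out, first stride)
    (3, 64, 256, 1),
    (4, 128, 512, 2),
    (6, 256, 1024, 2),
    (3, 512, 2048, 2),
]

_TINY_STAGES = [
    (1, 8, 32, 2),
    (1, 16, 64, 2),
    (1, 32, 128, 2),
]


@dataclass
class ResNetRegressor:
    """A (SE-)ResNet mapping an image batch to one Hb mass per image."""

    kind: KindName
    config: RegressorConfig
    layers: list[Layer] = field(default_factory=list, repr=False)
    head: Dense | None = field(default=None, repr=False)
    trained: bool = False
    history: list[float] = field(default_factory=list)

    def params(self) -> list[Param]:
        out = [p for layer in self.layers for p in layer.params()]
        out.extend(self.head.params())
        return out

    def num_parameters(self) -> int:
        return sum(p.size for p in self.params())

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """(N, 3, H, W) float batch -> (N,) raw predictions (scaled units)."""
        out = x
        for layer in self.layers:
            out = layer.forward(out, train)
        return self.head.forward(out, train)[:, 0]

    def backward(self, grad_pred: np.ndarray) -> None:
        grad = self.head.backward(grad_pred[:, None])
        for layer in reversed(self.layers):
            grad = layer.backward(grad)

    def se_blocks(self) -> list[SEBlock]:
        return [
            layer.se
            for layer in self.layers
            if isinstance(layer, Bottleneck) and layer.se is not None
        ]


def build_regressor(kind: str, config: RegressorConfig) -> ResNetRegressor:
    """Construct an untrained regressor of the requested kind/variant."""
    if kind not in ("resnet", "se_resnet"):
        raise ValueError(f"unknown kind {kind!r}: expected 'resnet' or 'se_resnet'")
    rng = np.random.default_rng(config.seed)
    se = config.se_reduction if kind == "se_resnet" else None

    layers: list[Layer] = []
    if config.variant == "full":
        stem_out = 64
        layers += [
            Conv2d(3, stem_out, 7, stride=2, pad=3, rng=rng),
            BatchNorm2d(stem_out),
            ReLU(),
            MaxPool2d(3, 2, pad=1),
        ]
        stages = _FULL_STAGES
    elif config.variant == "tiny":
        stem_out = 16
        layers += [Conv2d(3, stem_out, 3, stride=1, pad=1, rng=rng), BatchNorm2d(stem_out), ReLU()]
        stages = _TINY_STAGES
    else:
        raise ValueError(f"unknown variant {config.variant!r}")

    in_c = stem_out
    for blocks, mid, out_c, stride in stages:
        for b in range(blocks):
            layers.append(
                Bottleneck(
                    in_c,
                    mid,
                    out_c,
                    stride=stride if b == 0 else 1,
                    se_reduction=se,
                    rng=rng,
                )
            )
            in_c = out_c

    layers.append(GlobalAvgPool())
    head = Dense(in_c, 1, rng=rng)
    return ResNetRegressor(kind=kind, config=config, layers=layers, head=head)
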