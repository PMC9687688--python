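"""SqueezeNet-style classifier construction, loss and optimizer.

Two architectures are provided:

* :func:`build_model` — the compact 7-fire variant used throughout this
  package: batch normalization on the input, seven fire modules with a 2x2
  max pool after each of the first six, global average pooling and a dense
  2-way head.
* :func:`build_baseline_squeezenet` — the canonical SqueezeNet v1.0
  topology (standalone 7x7 convolution, eight fire modules, final 1x1
  convolution head) with a 2-class output, kept as a reference baseline.

Construction is pure given a seed: the same configuration always yields an
identical architecture summary (layer list, output shapes, parameter
counts).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .layers import (
    BatchNorm2d,
    Conv2d,
    Fire,
    GlobalAvgPool,
    Layer,
    Linear,
    MaxPool2d,
    ReLU,
)

__all__ = [
    "FireSpec",
    "ModelConfig",
    "Sequential",
    "build_fire",
    "build_model",
    "build_baseline_squeezenet",
    "softmax_cross_entropy",
    "predict_proba",
    "Adam",
]

_DT = np.float32

#: Default fire-module (squeeze, expand) channel sizes, palindromic.
DEFAULT_FIRES = ((24, 48), (48, 96), (64, 128), (64, 256), (64, 128), (48, 96), (24, 48))


@dataclass(frozen=True)
class FireSpec:
    """Channel sizes of one fire module: 1x1 squeeze stage and total expand."""

    squeeze: int
    expand: int

    def __post_init__(self) -> None:
        if self.squeeze <= 0 or self.expand <= 0:
            raise ValueError("fire channel counts must be positive")
        if self.squeeze >= self.expand:
            raise ValueError("squeeze must be smaller than expand")


@dataclass
class ModelConfig:
    """Architecture description of the modified classifier."""

    input_shape: tuple[int, int, int] = (240, 240, 3)  # H, W, C
    fires: tuple[FireSpec, ...] = tuple(FireSpec(s, e) for s, e in DEFAULT_FIRES)
    pool_size: int = 2
    n_pools: int = 6
    n_classes: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        self.fires = tuple(
            f if isinstance(f, FireSpec) else FireSpec(*f) for f in self.fires
        )
        h, w, _ = self.input_shape
        if min(h, w) // (self.pool_size ** self.n_pools) < 1:
            raise ValueError(
                f"input {h}x{w} too small for {self.n_pools} {self.pool_size}x"
                f"{self.pool_size} poolings"
            )


class Sequential:
    """Ordered layer stack with explicit backward pass and summaries."""

    def __init__(self, layers: list[Layer], name: str = "model"):
        self.layers = layers
        self.name = name

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, dout: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout

    def _leaf_layers(self):
        for layer in self.layers:
            if isinstance(layer, Fire):
                yield from layer.sublayers
            else:
                yield layer

    def parameters(self):
        """Yield (param_array, grad_array) pairs over all trainable leaves."""
        for layer in self._leaf_layers():
            for key in layer.params:
                yield layer.params[key], layer.grads[key]

    def param_count(self) -> int:
        return sum(l.param_count() for l in self.layers)

    def summary(self, input_shape: tuple[int, int, int]) -> list[dict]:
        """Dry-run shape propagation: one row per layer.

        ``input_shape`` is (H, W, C); rows carry layer name, output shape
        (C, H, W) and parameter count.
        """
        h, w, c = input_shape
        x = np.zeros((1, c, h, w), dtype=_DT)
        rows = []
        for layer in self.layers:
            x = layer.forward(x, train=True)
            rows.append(
                {
                    "layer": layer.name,
                    "output_shape": tuple(int(d) for d in x.shape[1:]),
                    "params": layer.param_count(),
                }
            )
        return rows

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {}
        for i, layer in enumerate(self._leaf_layers()):
            for key, val in layer.params.items():
                state[f"{i}:{layer.name}:{key}"] = val
            if isinstance(layer, BatchNorm2d):
                state[f"{i}:{layer.name}:running_mean"] = layer.running_mean
                state[f"{i}:{layer.name}:running_var"] = layer.running_var
        return state

    def save(self, path) -> None:
        np.savez(path, **self.state_dict())

    def load(self, path) -> None:
        data = np.load(path)
        for i, layer in enumerate(self._leaf_layers()):
            for key in layer.params:
                layer.params[key][...] = data[f"{i}:{layer.name}:{key}"]
            if isinstance(layer, BatchNorm2d):
                layer.running_mean[...] = data[f"{i}:{layer.name}:running_mean"]
                layer.running_var[...] = data[f"{i}:{layer.name}:running_var"]


def build_fire(in_channels: int, spec: FireSpec, rng=None, name: str = "fire") -> Fire:
    """One fire module; output channel count equals ``spec.expand``."""
    return Fire(in_channels, spec.squeeze, spec.expand, rng=rng, name=name)


def build_model(config: ModelConfig | None = None) -> Sequential:
    """Modified SqueezeNet: batchnorm, 7 fires interleaved with 6 pools.

    A 2x2 max pool follows each of the first ``n_pools`` fire modules;
    global average pooling and a dense layer produce the 2 class scores.
    """
    config = config or ModelConfig()
    rng = np.random.default_rng(config.seed)
    h, w, c = config.input_shape
    layers: list[Layer] = [BatchNorm2d(c, name="input_batchnorm")]
    in_ch = c
    for i, spec in enumerate(config.fires, start=1):
        layers.append(build_fire(in_ch, spec, rng=rng, name=f"fire{i}"))
        in_ch = spec.expand
        if i <= config.n_pools:
            layers.append(MaxPool2d(config.pool_size, name=f"pool{i}"))
    layers.append(GlobalAvgPool(name="global_avgpool"))
    layers.append(Linear(in_ch, config.n_classes, rng=rng, name="fc"))
    return Sequential(layers, name="modified_squeezenet")


#: Canonical SqueezeNet v1.0 fire sizes (squeeze, total expand).
_BASELINE_FIRES = (
    (16, 128),
    (16, 128),
    (32, 256),
    (32, 256),
    (48, 384),
    (48, 384),
    (64, 512),
    (64, 512),
)


def build_baseline_squeezenet(
    input_shape: tuple[int, int, int] = (240, 240, 3),
    n_classes: int = 2,
    seed: int = 0,
) -> Sequential:
    """Reference SqueezeNet v1.0 with a 2-class convolutional head.

    Standalone 7x7/stride-2 convolution, eight fire modules with 3x3/stride-2
    max pools in the canonical positions, then a 1x1 convolution to the
    class count and global average pooling.
    """
    rng = np.random.default_rng(seed)
    h, w, c = input_shape
    layers: list[Layer] = [
        Conv2d(c, 96, 7, stride=2, rng=rng, name="conv1"),
        ReLU(name="relu1"),
        MaxPool2d(3, stride=2, name="pool1"),
    ]
    in_ch = 96
    for i, (s, e) in enumerate(_BASELINE_FIRES):
        layers.append(Fire(in_ch, s, e, rng=rng, name=f"fire{i + 2}"))
        in_ch = e
        if i in (2, 6):  # pools after fire4 and fire8, v1.0 placement
            layers.append(MaxPool2d(3, stride=2, name=f"pool_after_fire{i + 2}"))
    layers.append(Conv2d(in_ch, n_classes, 1, rng=rng, name="conv10"))
    layers.append(ReLU(name="relu10"))
    layers.append(GlobalAvgPool(name="global_avgpool"))
    return Sequential(layers, name="squeezenet_v1_baseline")


def softmax_cross_entropy(logits: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross-entropy over a batch plus the gradient w.r.t. the logits.

    ``y`` holds integer class indices.  Log-sum-exp stabilized.
    """
    z = logits - logits.max(axis=1, keepdims=True)
    logp = z - np.log(np.exp(z).sum(axis=1, keepdims=True))
    n = logits.shape[0]
    loss = -float(logp[np.arange(n), y].mean())
    dlogits = np.exp(logp)
    dlogits[np.arange(n), y] -= 1.0
    return loss, (dlogits / n).astype(_DT)


def predict_proba(model: Sequential, x: np.ndarray) -> np.ndarray:
    """Softmax class probabilities in eval mode (running batchnorm stats)."""
    logits = model.forward(x, train=False)
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class Adam:
    """Adam optimizer over a model's (param, grad) pairs."""

    def __init__(self, model: Sequential, lr: float = 1e-3, betas=(0.9, 0.999), eps: float = 1e-8):
        self.pairs = list(model.parameters())
        self.lr, self.b1, self.b2, self.eps = lr, betas[0], betas[1], eps
        self.m = [np.zeros_like(p) for p, _ in self.pairs]
        self.v = [np.zeros_like(p) for p, _ in self.pairs]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1 ** self.t
        bc2 = 1.0 - self.b2 ** self.t
        for i, (p, g) in enumerate(self.pairs):
            self.m[i] += (1.0 - self.b1) * (g - self.m[i])
            self.v[i] += (1.0 - self.b2) * (g * g - self.v[i])
            p -= self.lr * (self.m[i] / bc1) / (np.sqrt(self.v[i] / bc2) + self.eps)
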