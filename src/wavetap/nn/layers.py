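"""Minimal CNN building blocks with explicit forward/backward passes.

All layers operate on float32 arrays in NCHW layout and keep their
parameters and gradients in ``self.params`` / ``self.grads`` dicts keyed by
name.  Convolutions are evaluated as matrix products over im2col patch
matrices; backward passes are hand-derived.  This is deliberately a small,
auditable engine: stride-1/2 convolutions, max pooling, batch
normalization, ReLU, global average pooling and a dense layer — exactly
what the SqueezeNet-style classifiers here require.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Layer",
    "Conv2d",
    "BatchNorm2d",
    "ReLU",
    "MaxPool2d",
    "GlobalAvgPool",
    "Flatten",
    "Linear",
    "Fire",
]

_DT = np.float32


class Layer:
    """Base class: parameterized differentiable transform."""

    def __init__(self, name: str = ""):
        self.name = name or self.__class__.__name__
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def param_count(self) -> int:
        return int(sum(p.size for p in self.params.values()))


def _im2col(x: np.ndarray, k: int, stride: int) -> np.ndarray:
    """(N, C, H, W) -> (N * Ho * Wo, C * k * k) patch matrix."""
    win = np.lib.stride_tricks.sliding_window_view(x, (k, k), axis=(2, 3))
    win = win[:, :, ::stride, ::stride]  # (N, C, Ho, Wo, k, k)
    n, c, ho, wo = win.shape[:4]
    return win.transpose(0, 2, 3, 1, 4, 5).reshape(n * ho * wo, c * k * k), ho, wo


class Conv2d(Layer):
    """2-D convolution (cross-correlation), stride >= 1, zero padding."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int,
        stride: int = 1,
        padding: int = 0,
        rng: np.random.Generator | None = None,
        name: str = "",
    ):
        super().__init__(name)
        self.cin, self.cout, self.k = in_channels, out_channels, kernel_size
        self.stride, self.pad = stride, padding
        rng = rng or np.random.default_rng()
        fan_in = in_channels * kernel_size * kernel_size
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(out_channels, fan_in))
        self.params = {"W": w.astype(_DT), "b": np.zeros(out_channels, dtype=_DT)}
        self.grads = {k_: np.zeros_like(v) for k_, v in self.params.items()}
        self._cache = None

    def forward(self, x, train=True):
        if self.pad:
            x = np.pad(x, ((0, 0), (0, 0), (self.pad,) * 2, (self.pad,) * 2))
        cols, ho, wo = _im2col(np.ascontiguousarray(x, dtype=_DT), self.k, self.stride)
        out = cols @ self.params["W"].T + self.params["b"]
        n = x.shape[0]
        self._cache = (cols, x.shape, ho, wo)
        return out.reshape(n, ho, wo, self.cout).transpose(0, 3, 1, 2)

    def backward(self, dout):
        cols, xshape, ho, wo = self._cache
        n = xshape[0]
        dflat = dout.transpose(0, 2, 3, 1).reshape(-1, self.cout)
        self.grads["W"][...] = dflat.T @ cols
        self.grads["b"][...] = dflat.sum(axis=0)
        dcols = dflat @ self.params["W"]  # (N*Ho*Wo, C*k*k)
        dcols = dcols.reshape(n, ho, wo, self.cin, self.k, self.k)
        dx = np.zeros(xshape, dtype=_DT)
        s = self.stride
        for i in range(self.k):
            for j in range(self.k):
                dx[:, :, i : i + s * ho : s, j : j + s * wo : s] += dcols[
                    :, :, :, :, i, j
                ].transpose(0, 3, 1, 2)
        if self.pad:
            dx = dx[:, :, self.pad : -self.pad, self.pad : -self.pad]
        return dx

    def out_shape(self, h: int, w: int) -> tuple[int, int]:
        h2 = (h + 2 * self.pad - self.k) // self.stride + 1
        w2 = (w + 2 * self.pad - self.k) // self.stride + 1
        return h2, w2


class BatchNorm2d(Layer):
    """Per-channel batch normalization with running statistics."""

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1, name: str = ""):
        super().__init__(name)
        self.eps, self.momentum = eps, momentum
        self.params = {
            "gamma": np.ones(channels, dtype=_DT),
            "beta": np.zeros(channels, dtype=_DT),
        }
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        self.running_mean = np.zeros(channels, dtype=_DT)
        self.running_var = np.ones(channels, dtype=_DT)
        self._cache = None

    def forward(self, x, train=True):
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv[None, :, None, None]
        self._cache = (xhat, inv)
        g, b = self.params["gamma"], self.params["beta"]
        return (g[None, :, None, None] * xhat + b[None, :, None, None]).astype(_DT)

    def backward(self, dout):
        xhat, inv = self._cache
        g = self.params["gamma"]
        m = dout.shape[0] * dout.shape[2] * dout.shape[3]
        self.grads["beta"][...] = dout.sum(axis=(0, 2, 3))
        self.grads["gamma"][...] = (dout * xhat).sum(axis=(0, 2, 3))
        dxhat = dout * g[None, :, None, None]
        dx = (
            dxhat
            - dxhat.mean(axis=(0, 2, 3), keepdims=True)
            - xhat * (dxhat * xhat).mean(axis=(0, 2, 3), keepdims=True)
        ) * inv[None, :, None, None]
        return dx.astype(_DT)


class ReLU(Layer):
    def forward(self, x, train=True):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class MaxPool2d(Layer):
    """Max pooling; excess rows/columns that do not fill a window are dropped."""

    def __init__(self, kernel_size: int = 2, stride: int | None = None, name: str = ""):
        super().__init__(name)
        self.k = kernel_size
        self.stride = stride or kernel_size

    def forward(self, x, train=True):
        win = np.lib.stride_tricks.sliding_window_view(x, (self.k, self.k), axis=(2, 3))
        win = win[:, :, :: self.stride, :: self.stride]
        n, c, ho, wo = win.shape[:4]
        flat = win.reshape(n, c, ho, wo, self.k * self.k)
        self._argmax = flat.argmax(axis=-1)
        self._xshape = x.shape
        self._oshape = (n, c, ho, wo)
        return flat.max(axis=-1)

    def backward(self, dout):
        n, c, ho, wo = self._oshape
        dx = np.zeros(self._xshape, dtype=_DT)
        ii, jj = np.divmod(self._argmax, self.k)
        ni, ci, hi, wi = np.indices((n, c, ho, wo), sparse=False)
        rows = hi * self.stride + ii
        cols = wi * self.stride + jj
        np.add.at(dx, (ni, ci, rows, cols), dout)
        return dx

    def out_shape(self, h: int, w: int) -> tuple[int, int]:
        return (h - self.k) // self.stride + 1, (w - self.k) // self.stride + 1


class GlobalAvgPool(Layer):
    """Average over the spatial axes: (N, C, H, W) -> (N, C)."""

    def forward(self, x, train=True):
        self._xshape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, dout):
        n, c, h, w = self._xshape
        return np.broadcast_to(
            dout[:, :, None, None] / (h * w), self._xshape
        ).astype(_DT)


class Flatten(Layer):
    def forward(self, x, train=True):
        self._xshape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._xshape)


class Linear(Layer):
    def __init__(self, in_features: int, out_features: int, rng=None, name: str = ""):
        super().__init__(name)
        rng = rng or np.random.default_rng()
        w = rng.normal(0.0, np.sqrt(2.0 / in_features), size=(out_features, in_features))
        self.params = {"W": w.astype(_DT), "b": np.zeros(out_features, dtype=_DT)}
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}

    def forward(self, x, train=True):
        self._x = x
        return x @ self.params["W"].T + self.params["b"]

    def backward(self, dout):
        self.grads["W"][...] = dout.T @ self._x
        self.grads["b"][...] = dout.sum(axis=0)
        return dout @ self.params["W"]


class Fire(Layer):
    """SqueezeNet fire module.

    A 1x1 "squeeze" convolution reduces the channel count, then parallel
    1x1 and 3x3 "expand" convolutions (the 3x3 branch padded to preserve
    spatial size) are concatenated along channels.  With an odd expand
    total, the 1x1 branch takes the extra channel.
    """

    def __init__(self, in_channels: int, squeeze: int, expand: int, rng=None, name: str = ""):
        super().__init__(name)
        if squeeze <= 0 or expand <= 0 or squeeze >= expand:
            raise ValueError(f"need 0 < squeeze < expand, got {squeeze}, {expand}")
        self.squeeze_channels = squeeze
        self.expand_channels = expand
        e1 = (expand + 1) // 2
        e3 = expand - e1
        self.sq = Conv2d(in_channels, squeeze, 1, rng=rng, name=f"{self.name}/squeeze1x1")
        self.e1 = Conv2d(squeeze, e1, 1, rng=rng, name=f"{self.name}/expand1x1")
        self.e3 = Conv2d(squeeze, e3, 3, padding=1, rng=rng, name=f"{self.name}/expand3x3")
        self.relu_s, self.relu_1, self.relu_3 = ReLU(), ReLU(), ReLU()
        self._e1_out = e1

    @property
    def sublayers(self):
        return (self.sq, self.e1, self.e3)

    def param_count(self) -> int:
        return sum(l.param_count() for l in self.sublayers)

    def forward(self, x, train=True):
        s = self.relu_s.forward(self.sq.forward(x, train), train)
        a = self.relu_1.forward(self.e1.forward(s, train), train)
        b = self.relu_3.forward(self.e3.forward(s, train), train)
        return np.concatenate([a, b], axis=1)

    def backward(self, dout):
        da = self.relu_1.backward(dout[:, : self._e1_out])
        db = self.relu_3.backward(dout[:, self._e1_out :])
        ds = self.e1.backward(da) + self.e3.backward(db)
        return self.sq.backward(self.relu_s.backward(ds))
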