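"""Neural-network layers with explicit forward/backward passes.

All feature maps are NHWC float32.  Every layer caches what its backward
pass needs during ``forward(..., training=True)``; ``backward`` consumes
the upstream gradient and returns the gradient with respect to the input
while accumulating parameter gradients in-place on :class:`Param` objects.
"""

from __future__ import annotations

import numpy as np

from . import _kernels

__all__ = [
    "Param", "Layer", "DepthwiseConv2d", "GroupedPointwise", "Dense",
    "BatchNorm2d", "ReLU", "MaxPool2d", "GlobalAvgPool", "Identity",
    "softmax", "cross_entropy",
]


class Param:
    """A trainable array with its accumulated gradient."""

    __slots__ = ("name", "value", "grad")

    def __init__(self, name: str, value: np.ndarray):
        self.name = name
        self.value = np.asarray(value, dtype=np.float32)
        self.grad = np.zeros_like(self.value)

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


class Layer:
    """Base layer: stateless by default, no parameters."""

    name: str = ""

    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def out_shape(self, in_shape: tuple[int, int, int]) -> tuple[int, int, int]:
        """Propagate an (H, W, C) shape; raises on inconsistency."""
        return in_shape


def _conv_out(size: int, k: int, stride: int, pad: int) -> int:
    out = (size + 2 * pad - k) // stride + 1
    if out <= 0:
        raise ValueError(f"spatial size {size} too small for kernel {k}/stride {stride}")
    return out


class DepthwiseConv2d(Layer):
    """Intra-state operator: one Dk x Dk filter per channel, no cross-channel
    mixing.  Zero padding of Dk // 2 keeps the spatial size at stride 1."""

    def __init__(self, channels: int, dk: int, stride: int = 1,
                 rng: np.random.Generator | None = None, bias: bool = True,
                 tie: int = 1, name: str = "depthwise"):
        self.channels = channels
        self.dk = dk
        self.stride = stride
        self.pad = dk // 2
        self.name = name
        rng = rng or np.random.default_rng(0)
        std = np.sqrt(2.0 / (dk * dk))
        if tie > 1 and channels % tie == 0:
            # state-symmetric start: consecutive groups of `tie` channels
            # (one lead's states) share a filter at init and may diverge
            # during training
            base = rng.normal(0.0, std, size=(dk, dk, channels // tie))
            w = np.repeat(base, tie, axis=2)
        else:
            w = rng.normal(0.0, std, size=(dk, dk, channels))
        self.weight = Param(f"{name}.weight", w)
        self.bias = Param(f"{name}.bias", np.zeros(channels)) if bias else None
        self._x: np.ndarray | None = None

    def params(self) -> list[Param]:
        return [self.weight] + ([self.bias] if self.bias is not None else [])

    def out_shape(self, in_shape):
        h, w, c = in_shape
        if c != self.channels:
            raise ValueError(
                f"{self.name}: expected {self.channels} channels, got {c}"
            )
        return (_conv_out(h, self.dk, self.stride, self.pad),
                _conv_out(w, self.dk, self.stride, self.pad), c)

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        n, h, w, c = x.shape
        if c != self.channels:
            raise ValueError(f"{self.name}: expected {self.channels} channels, got {c}")
        ho, wo, _ = self.out_shape((h, w, c))
        x = np.ascontiguousarray(x)
        out = np.empty((n, ho, wo, c), dtype=x.dtype)
        bias = self.bias.value if self.bias is not None else np.zeros(c, dtype=x.dtype)
        _kernels.depthwise_forward(
            x, self.weight.value.astype(x.dtype), bias.astype(x.dtype),
            self.stride, self.pad, out,
        )
        if training:
            self._x = x
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        x = self._x
        grad = np.ascontiguousarray(grad)
        dx = np.zeros_like(x)
        dw = np.zeros(self.weight.value.shape, dtype=x.dtype)
        db = np.zeros(self.channels, dtype=x.dtype)
        _kernels.depthwise_backward(
            x, self.weight.value.astype(x.dtype), grad, self.stride, self.pad,
            dx, dw, db,
        )
        self.weight.grad += dw
        if self.bias is not None:
            self.bias.grad += db
        self._x = None
        return dx


class GroupedPointwise(Layer):
    """Inter-state operator: grouped 1x1 convolution.

    With one group per lead (g = 12) each group's (C_in/g) x (C_out/g)
    matrix mixes only that lead's state channels; with g = 1 this is a
    dense 1x1 channel mixing.
    """

    def __init__(self, in_channels: int, out_channels: int, groups: int = 12,
                 rng: np.random.Generator | None = None, bias: bool = True,
                 init: str = "he", name: str = "pointwise"):
        if in_channels % groups or out_channels % groups:
            raise ValueError(
                f"{name}: channels ({in_channels}->{out_channels}) must be "
                f"divisible by groups ({groups})"
            )
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.groups = groups
        self.name = name
        cin_g = in_channels // groups
        cout_g = out_channels // groups
        rng = rng or np.random.default_rng(0)
        if init == "identity" and cin_g == cout_g:
            # near-identity start: the stage begins as a pass-through and
            # learns its mixing from there
            w = np.tile(np.eye(cin_g, dtype=np.float64), (groups, 1, 1))
            w += rng.normal(0.0, 0.05, size=(groups, cin_g, cout_g))
        else:
            w = rng.normal(0.0, np.sqrt(2.0 / cin_g), size=(groups, cin_g, cout_g))
        self.weight = Param(f"{name}.weight", w)
        self.bias = Param(f"{name}.bias", np.zeros(out_channels)) if bias else None
        self._xr: np.ndarray | None = None

    def params(self) -> list[Param]:
        return [self.weight] + ([self.bias] if self.bias is not None else [])

    def out_shape(self, in_shape):
        h, w, c = in_shape
        if c != self.in_channels:
            raise ValueError(f"{self.name}: expected {self.in_channels} channels, got {c}")
        return (h, w, self.out_channels)

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        n, h, w, c = x.shape
        if c != self.in_channels:
            raise ValueError(f"{self.name}: expected {self.in_channels} channels, got {c}")
        g = self.groups
        cin_g = c // g
        # (g, N*H*W, cin_g) so each group is a single BLAS matmul
        xr = np.ascontiguousarray(
            x.reshape(n * h * w, g, cin_g).transpose(1, 0, 2)
        )
        out = xr @ self.weight.value  # (g, M, cout_g)
        out = out.transpose(1, 0, 2).reshape(n, h, w, self.out_channels)
        if self.bias is not None:
            out = out + self.bias.value
        if training:
            self._xr = xr
            self._shape = (n, h, w)
        return np.ascontiguousarray(out)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, h, w = self._shape
        g = self.groups
        cout_g = self.out_channels // g
        gr = np.ascontiguousarray(
            grad.reshape(n * h * w, g, cout_g).transpose(1, 0, 2)
        )
        self.weight.grad += self._xr.transpose(0, 2, 1) @ gr
        if self.bias is not None:
            self.bias.grad += grad.sum(axis=(0, 1, 2))
        dx = gr @ self.weight.value.transpose(0, 2, 1)  # (g, M, cin_g)
        self._xr = None
        return np.ascontiguousarray(
            dx.transpose(1, 0, 2).reshape(n, h, w, self.in_channels)
        )


class Dense(Layer):
    """Fully connected layer on flattened (N, in) inputs."""

    def __init__(self, in_features: int, out_features: int,
                 rng: np.random.Generator | None = None, name: str = "dense"):
        self.in_features = in_features
        self.out_features = out_features
        self.name = name
        rng = rng or np.random.default_rng(0)
        std = np.sqrt(2.0 / in_features)
        self.weight = Param(f"{name}.weight",
                            rng.normal(0.0, std, size=(in_features, out_features)))
        self.bias = Param(f"{name}.bias", np.zeros(out_features))
        self._x: np.ndarray | None = None

    def params(self) -> list[Param]:
        return [self.weight, self.bias]

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if x.shape[1] != self.in_features:
            raise ValueError(
                f"{self.name}: expected {self.in_features} features, got {x.shape[1]}"
            )
        if training:
            self._x = x
        return x @ self.weight.value + self.bias.value

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.weight.grad += self._x.T @ grad
        self.bias.grad += grad.sum(axis=0)
        dx = grad @ self.weight.value.T
        self._x = None
        return dx


class BatchNorm2d(Layer):
    """Per-channel batch normalization over (N, H, W)."""

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1,
                 name: str = "bn"):
        self.channels = channels
        self.eps = eps
        self.momentum = momentum
        self.name = name
        self.gamma = Param(f"{name}.gamma", np.ones(channels))
        self.beta = Param(f"{name}.beta", np.zeros(channels))
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)

    def params(self) -> list[Param]:
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        axes = tuple(range(x.ndim - 1))
        if training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        # fold into a single affine pass: out = a * x + b
        a = (self.gamma.value * inv_std).astype(x.dtype)
        b = (self.beta.value - self.gamma.value * mean * inv_std).astype(x.dtype)
        out = x * a
        out += b
        if training:
            # x is kept by reference; xhat is rebuilt lazily in backward
            self._x = x
            self._mean = mean.astype(x.dtype)
            self._inv_std = inv_std.astype(x.dtype)
            self._m = int(np.prod([x.shape[ax] for ax in axes]))
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        axes = tuple(range(grad.ndim - 1))
        inv_std, m = self._inv_std, self._m
        xhat = (self._x - self._mean) * inv_std
        g_sum = grad.sum(axis=axes)
        gx_sum = (grad * xhat).sum(axis=axes)
        self.gamma.grad += gx_sum
        self.beta.grad += g_sum
        xhat *= gx_sum
        xhat += g_sum
        dx = grad * (self.gamma.value * inv_std)
        dx -= (self.gamma.value * inv_std / m) * xhat
        self._x = None
        return dx


class ReLU(Layer):
    name = "relu"

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        out = np.maximum(x, 0.0)
        if training:
            # out > 0 identifies exactly the pass-through positions
            self._out = out
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        grad = grad * (self._out > 0)
        self._out = None
        return grad


class MaxPool2d(Layer):
    """k x k max pooling; -inf padding, gradient routed to the first
    maximal element of each window (deterministic tie-break)."""

    def __init__(self, k: int = 3, stride: int = 2, pad: int = 1, name: str = "maxpool"):
        self.k = k
        self.stride = stride
        self.pad = pad
        self.name = name

    def out_shape(self, in_shape):
        h, w, c = in_shape
        return (_conv_out(h, self.k, self.stride, self.pad),
                _conv_out(w, self.k, self.stride, self.pad), c)

    def _slices(self, ho: int, wo: int, i: int, j: int):
        s = self.stride
        return (slice(i, i + s * (ho - 1) + 1, s), slice(j, j + s * (wo - 1) + 1, s))

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        n, h, w, c = x.shape
        ho, wo, _ = self.out_shape((h, w, c))
        p = self.pad
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)), constant_values=-np.inf)
        out = np.full((n, ho, wo, c), -np.inf, dtype=x.dtype)
        for i in range(self.k):
            for j in range(self.k):
                si, sj = self._slices(ho, wo, i, j)
                np.maximum(out, xp[:, si, sj, :], out=out)
        if training:
            self._xp = xp
            self._out = out
            self._in_hw = (h, w)
            self._out_hw = (ho, wo)
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        xp, out = self._xp, self._out
        (h, w), (ho, wo) = self._in_hw, self._out_hw
        p = self.pad
        dxp = np.zeros_like(xp)
        unrouted = np.ones_like(out, dtype=bool)
        for i in range(self.k):
            for j in range(self.k):
                si, sj = self._slices(ho, wo, i, j)
                take = (xp[:, si, sj, :] == out) & unrouted
                dxp[:, si, sj, :] += grad * take
                unrouted &= ~take
        self._xp = self._out = None
        return dxp[:, p:p + h, p:p + w, :]


class GlobalAvgPool(Layer):
    name = "avgpool"

    def out_shape(self, in_shape):
        h, w, c = in_shape
        return (1, 1, c)

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if training:
            self._in_shape = x.shape
        return x.mean(axis=(1, 2))

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, h, w, c = self._in_shape
        return np.broadcast_to(grad[:, None, None, :] / (h * w), (n, h, w, c)).copy()


class Identity(Layer):
    name = "identity"

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad


def softmax(logits: np.ndarray) -> np.ndarray:
    """Row-wise stable softmax."""
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def cross_entropy(probs: np.ndarray, labels: np.ndarray, eps: float = 1e-12) -> float:
    """Mean cross-entropy  L = -(1/N) sum_i sum_c y_ic log(p_ic).

    *labels* may be one-hot (N, C) or integer class indices (N,).  The log
    is clamped at *eps* for numerical safety.  N == 0 is an error.
    """
    probs = np.asarray(probs, dtype=np.float64)
    if probs.ndim != 2:
        raise ValueError(f"probs must be (N, C), got shape {probs.shape}")
    n = probs.shape[0]
    if n == 0:
        raise ValueError("cross-entropy of an empty batch is undefined")
    labels = np.asarray(labels)
    if labels.ndim == 1:
        onehot = np.zeros_like(probs)
        onehot[np.arange(n), labels.astype(int)] = 1.0
    else:
        onehot = labels.astype(np.float64)
    return float(-(onehot * np.log(np.clip(probs, eps, None))).sum() / n)
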