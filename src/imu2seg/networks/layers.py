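"""Feed-forward building blocks with explicit forward/backward passes.

All layers operate on float32 arrays of shape ``(N, T, C)`` (batch, time,
channels) unless noted.  Each layer owns its parameters and, after a
backward pass, the matching gradients; the optimizer updates them in place.
Stochastic layers (noise, dropout) are active only when ``training=True``
and draw from the generator passed to ``forward``, so a fixed seed gives
bit-identical training runs.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Layer",
    "GaussianNoise",
    "InputDropout",
    "Conv1D",
    "BatchNorm",
    "ReLU",
    "ConvBlock",
    "Dense",
    "Adam",
    "softmax",
    "conv_layer_forward",
]

F32 = np.float32


class Layer:
    """Minimal layer protocol: params/grads dicts + forward/backward."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    #: parameter names exempt from the L2 weight penalty (biases, BN affine)
    no_decay: tuple = ()

    def forward(self, x: np.ndarray, training: bool = False,
                rng: np.random.Generator | None = None, **kw) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class GaussianNoise(Layer):
    """Additive zero-mean Gaussian data augmentation, per-channel scale.

    Mirrors the accelerometer noise injected by the simulator (default
    sigma 1 m/s^2 on the three accelerometer channels, none on the
    gyroscope) so that real windows seen at inference resemble the training
    distribution.  When a boolean ``sim_mask`` is passed, noise is applied
    only to the flagged (simulated) windows.
    """

    def __init__(self, sigma: np.ndarray) -> None:
        super().__init__()
        self.sigma = np.asarray(sigma, dtype=F32).reshape(1, 1, -1)

    def forward(self, x, training=False, rng=None, sim_mask=None, **kw):
        if not training or not np.any(self.sigma > 0):
            return x
        noise = rng.normal(0.0, 1.0, size=x.shape).astype(F32) * self.sigma
        if sim_mask is not None:
            noise *= np.asarray(sim_mask, dtype=F32)[:, None, None]
        return x + noise

    def backward(self, dy):
        return dy


class InputDropout(Layer):
    """Elementwise dropout on the input, inverted scaling by the keep rate."""

    def __init__(self, keep_prob: float = 0.8) -> None:
        super().__init__()
        if not 0.0 < keep_prob <= 1.0:
            raise ValueError("keep probability must be in (0, 1]")
        self.keep = keep_prob
        self._mask = None

    def forward(self, x, training=False, rng=None, **kw):
        if not training or self.keep >= 1.0:
            self._mask = None
            return x
        self._mask = (rng.random(x.shape) < self.keep).astype(F32) / F32(self.keep)
        return x * self._mask

    def backward(self, dy):
        return dy if self._mask is None else dy * self._mask


class Conv1D(Layer):
    """Temporal convolution, valid padding, stride 1, with bias.

    Kernel ``K`` has shape (P, C_in, C_out); output length is T - P + 1.
    Implemented as an im2col matrix product.
    """

    no_decay = ("b",)

    def __init__(self, c_in: int, c_out: int, kernel: int,
                 rng: np.random.Generator) -> None:
        super().__init__()
        if kernel < 3 or kernel % 2 == 0:
            raise ValueError("kernel width must be odd and >= 3")
        scale = np.sqrt(2.0 / (kernel * c_in))  # He init for ReLU stacks
        self.params = {
            "K": (rng.normal(0.0, scale, size=(kernel, c_in, c_out))).astype(F32),
            "b": np.zeros(c_out, dtype=F32),
        }
        self.kernel = kernel
        self._xcol = None
        self._xshape = None

    def forward(self, x, training=False, rng=None, **kw):
        P = self.kernel
        n, t, c = x.shape
        if t < P:
            raise ValueError(f"sequence length {t} shorter than kernel {P}")
        # (N, T_out, C, P) view -> (N, T_out, P*C) columns
        win = np.lib.stride_tricks.sliding_window_view(x, P, axis=1)
        xcol = np.ascontiguousarray(win.transpose(0, 1, 3, 2)).reshape(
            n, t - P + 1, P * c)
        self._xcol, self._xshape = xcol, x.shape
        W = self.params["K"].reshape(P * c, -1)
        return xcol @ W + self.params["b"]

    def backward(self, dy):
        n, t_out, c_out = dy.shape
        P = self.kernel
        _, t, c = self._xshape
        W = self.params["K"].reshape(P * c, c_out)
        dy2 = dy.reshape(-1, c_out)
        self.grads["K"] = (self._xcol.reshape(-1, P * c).T @ dy2).reshape(
            P, c, c_out)
        self.grads["b"] = dy2.sum(axis=0)
        dxcol = (dy2 @ W.T).reshape(n, t_out, P, c)
        dx = np.zeros(self._xshape, dtype=dy.dtype)
        for p in range(P):
            dx[:, p:p + t_out] += dxcol[:, :, p]
        return dx


class BatchNorm(Layer):
    """Batch normalization per channel over the batch and time axes.

    Training uses batch statistics and updates exponential running averages;
    inference uses the running averages.
    """

    no_decay = ("gamma", "beta")

    def __init__(self, channels: int, momentum: float = 0.1,
                 eps: float = 1e-5) -> None:
        super().__init__()
        self.params = {"gamma": np.ones(channels, dtype=F32),
                       "beta": np.zeros(channels, dtype=F32)}
        self.running_mean = np.zeros(channels, dtype=F32)
        self.running_var = np.ones(channels, dtype=F32)
        self.momentum = momentum
        self.eps = eps
        self._cache = None

    def forward(self, x, training=False, rng=None, **kw):
        if training:
            mean = x.mean(axis=(0, 1))
            var = x.var(axis=(0, 1))
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mean).astype(F32)
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var).astype(F32)
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * inv_std
        self._cache = (xhat, inv_std.astype(F32), training, x.shape)
        return self.params["gamma"] * xhat + self.params["beta"]

    def backward(self, dy):
        xhat, inv_std, training, shape = self._cache
        self.grads["gamma"] = (dy * xhat).sum(axis=(0, 1))
        self.grads["beta"] = dy.sum(axis=(0, 1))
        g = self.params["gamma"]
        if not training:
            return dy * g * inv_std
        m = shape[0] * shape[1]
        dxhat = dy * g
        return (inv_std / m) * (m * dxhat
                                - dxhat.sum(axis=(0, 1))
                                - xhat * (dxhat * xhat).sum(axis=(0, 1)))


class ReLU(Layer):
    def forward(self, x, training=False, rng=None, **kw):
        self._mask = x > 0
        return np.where(self._mask, x, F32(0.0))

    def backward(self, dy):
        return dy * self._mask


class ConvBlock(Layer):
    """Conv -> bias -> batch norm -> ReLU, the unit of the temporal stack."""

    def __init__(self, c_in: int, c_out: int, kernel: int,
                 rng: np.random.Generator) -> None:
        super().__init__()
        self.conv = Conv1D(c_in, c_out, kernel, rng)
        self.bn = BatchNorm(c_out)
        self.relu = ReLU()
        self.sub = [self.conv, self.bn, self.relu]

    def forward(self, x, training=False, rng=None, **kw):
        for layer in self.sub:
            x = layer.forward(x, training=training, rng=rng)
        return x

    def backward(self, dy):
        for layer in reversed(self.sub):
            dy = layer.backward(dy)
        return dy


class Dense(Layer):
    """Fully connected layer on (N, C) inputs."""

    no_decay = ("b",)

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator) -> None:
        super().__init__()
        scale = np.sqrt(1.0 / c_in)
        self.params = {"W": rng.normal(0.0, scale, size=(c_in, c_out)).astype(F32),
                       "b": np.zeros(c_out, dtype=F32)}

    def forward(self, x, training=False, rng=None, **kw):
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dy):
        self.grads["W"] = self._x.T @ dy
        self.grads["b"] = dy.sum(axis=0)
        return dy @ self.params["W"].T


class Adam:
    """Adam optimizer over a flat list of (layer, param-name) handles."""

    def __init__(self, handles: list, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8,
                 l2: float = 0.0) -> None:
        self.handles = handles
        self.lr, self.b1, self.b2, self.eps, self.l2 = lr, beta1, beta2, eps, l2
        self.m = [np.zeros_like(layer.params[name]) for layer, name in handles]
        self.v = [np.zeros_like(layer.params[name]) for layer, name in handles]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for i, (layer, name) in enumerate(self.handles):
            g = layer.grads[name]
            if self.l2 > 0 and name not in layer.no_decay:
                g = g + 2.0 * self.l2 * layer.params[name]
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / b1t
            vhat = self.v[i] / b2t
            layer.params[name] -= (self.lr * mhat /
                                   (np.sqrt(vhat) + self.eps)).astype(F32)


def softmax(logits: np.ndarray) -> np.ndarray:
    """Row-wise softmax, numerically stabilized."""
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def conv_layer_forward(x: np.ndarray, block: ConvBlock,
                       training: bool = False) -> np.ndarray:
    """One full convolutional layer: conv + bias, batch norm, ReLU.

    Convenience functional wrapper around :class:`ConvBlock` for inspection
    and testing; ``x`` has shape (N, T, C_in), output (N, T - P + 1, C_out).
    """
    return block.forward(x, training=training)
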