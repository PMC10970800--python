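"""Minimal numpy neural-network layers with reverse-mode gradients.

All tensors are channels-last ``(N, H, W, C)`` float arrays.  Each layer
caches what its backward pass needs during ``forward(..., train=True)``
and releases it after ``backward``.  Convolutions pick between two
equivalent evaluation strategies depending on layer width:

* **slice-matmul** — accumulate ``k*k`` shifted channel-matmuls; cheap
  when the output channel count is small (it avoids materializing the
  im2col matrix);
* **im2col** — one large GEMM; faster when ``k*k*c_in*c_out`` is large
  enough to be compute-bound.

The crossover constant below was chosen from single-thread timings of
the layer shapes this package instantiates.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Parameter", "Conv2d", "LeakyReLU", "ChannelAttention",
           "pixel_shuffle", "pixel_unshuffle", "AdamState", "adam_step"]

_IM2COL_THRESHOLD = 16384  # k*k*c_in*c_out above which im2col wins


class Parameter:
    """A trainable array with an accumulated gradient."""

    __slots__ = ("name", "value", "grad")

    def __init__(self, name: str, value: np.ndarray):
        self.name = name
        self.value = value
        self.grad = np.zeros_like(value)

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


def he_normal(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int,
              slope: float, dtype=np.float32) -> np.ndarray:
    """He/Kaiming fan-in normal initialization with LeakyReLU gain."""
    std = np.sqrt(2.0 / ((1.0 + slope**2) * fan_in))
    return rng.normal(0.0, std, size=shape).astype(dtype)


def linear_normal(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int,
                  dtype=np.float32) -> np.ndarray:
    """Variance-preserving (gain-1) fan-in init for activation-less layers."""
    std = np.sqrt(1.0 / fan_in)
    return rng.normal(0.0, std, size=shape).astype(dtype)


class Conv2d:
    """Same-padded 2-D convolution, zero boundary, stride 1.

    ``activation`` names what follows the layer and selects the init
    gain: ``"leaky_relu"`` uses He fan-in scaling with the LeakyReLU
    correction; ``"linear"`` (fusion, upscaler and reconstruction
    layers, which feed no rectifier) uses gain 1 so that stacked
    activation-less layers do not inflate the forward variance.
    """

    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator,
                 name: str = "conv", slope: float = 0.2, dtype=np.float32,
                 activation: str = "leaky_relu"):
        if k % 2 != 1:
            raise ValueError("kernel size must be odd for same padding")
        self.c_in, self.c_out, self.k = c_in, c_out, k
        fan_in = k * k * c_in
        if activation == "linear":
            w0 = linear_normal(rng, (k, k, c_in, c_out), fan_in, dtype)
        else:
            w0 = he_normal(rng, (k, k, c_in, c_out), fan_in, slope, dtype)
        self.W = Parameter(f"{name}.W", w0)
        self.b = Parameter(f"{name}.b", np.zeros(c_out, dtype=dtype))
        self._use_im2col = k > 1 and k * k * c_in * c_out >= _IM2COL_THRESHOLD
        self._cache = None

    def params(self):
        return [self.W, self.b]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if x.shape[-1] != self.c_in:
            raise ValueError(
                f"expected {self.c_in} input channels, got {x.shape[-1]}"
            )
        n, h, w, _ = x.shape
        k, pad = self.k, self.k // 2
        if pad:
            xp = np.zeros((n, h + 2 * pad, w + 2 * pad, self.c_in), dtype=x.dtype)
            xp[:, pad : pad + h, pad : pad + w, :] = x
        else:
            xp = x
        Wk = self.W.value
        if k == 1:
            out = x.reshape(-1, self.c_in) @ Wk.reshape(self.c_in, self.c_out)
            out = out.reshape(n, h, w, self.c_out)
            if train:
                self._cache = (x, None)
        elif self._use_im2col:
            cols = np.empty((n, h, w, k * k, self.c_in), dtype=x.dtype)
            idx = 0
            for i in range(k):
                for j in range(k):
                    cols[:, :, :, idx, :] = xp[:, i : i + h, j : j + w, :]
                    idx += 1
            c2 = cols.reshape(n * h * w, k * k * self.c_in)
            out = (c2 @ Wk.reshape(k * k * self.c_in, self.c_out)).reshape(
                n, h, w, self.c_out
            )
            if train:
                self._cache = (xp.shape, c2)
        else:
            out = np.zeros((n, h, w, self.c_out), dtype=x.dtype)
            for i in range(k):
                for j in range(k):
                    out += xp[:, i : i + h, j : j + w, :] @ Wk[i, j]
            if train:
                self._cache = (xp, None)
        out += self.b.value
        return out

    def backward(self, g: np.ndarray) -> np.ndarray:
        n, h, w, _ = g.shape
        k, pad = self.k, self.k // 2
        Wk = self.W.value
        self.b.grad += g.sum(axis=(0, 1, 2))
        g2 = g.reshape(-1, self.c_out)
        if k == 1:
            x, _ = self._cache
            self.W.grad += (
                x.reshape(-1, self.c_in).T @ g2
            ).reshape(self.W.value.shape)
            gx = (g2 @ Wk.reshape(self.c_in, self.c_out).T).reshape(x.shape)
            self._cache = None
            return gx
        if self._use_im2col:
            xp_shape, c2 = self._cache
            self.W.grad += (c2.T @ g2).reshape(self.W.value.shape)
            gcols = (g2 @ Wk.reshape(k * k * self.c_in, self.c_out).T).reshape(
                n, h, w, k * k, self.c_in
            )
            gxp = np.zeros(xp_shape, dtype=g.dtype)
            idx = 0
            for i in range(k):
                for j in range(k):
                    gxp[:, i : i + h, j : j + w, :] += gcols[:, :, :, idx, :]
                    idx += 1
            self._cache = None
            return gxp[:, pad : pad + h, pad : pad + w, :]
        xp, _ = self._cache
        gxp = np.zeros_like(xp)
        for i in range(k):
            for j in range(k):
                sl = xp[:, i : i + h, j : j + w, :].reshape(-1, self.c_in)
                self.W.grad[i, j] += sl.T @ g2
                gxp[:, i : i + h, j : j + w, :] += (
                    g2 @ Wk[i, j].T
                ).reshape(n, h, w, self.c_in)
        self._cache = None
        return gxp[:, pad : pad + h, pad : pad + w, :]


class LeakyReLU:
    """Elementwise leaky rectifier with configurable negative slope."""

    def __init__(self, slope: float = 0.2):
        self.slope = slope
        self._mask = None

    def params(self):
        return []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        mask = x > 0
        out = np.where(mask, x, self.slope * x)
        if train:
            self._mask = mask
        return out

    def backward(self, g: np.ndarray) -> np.ndarray:
        gx = np.where(self._mask, g, self.slope * g)
        self._mask = None
        return gx


class ChannelAttention:
    """Squeeze-excitation channel gate.

    Global average pool per channel, a two-layer bottleneck (reduction
    ``r``) with LeakyReLU, then a logistic gate in (0, 1) rescaling each
    channel of the input.
    """

    def __init__(self, channels: int, reduction: int, rng: np.random.Generator,
                 name: str = "ca", slope: float = 0.2, dtype=np.float32):
        if channels % reduction != 0:
            raise ValueError(
                f"channels={channels} not divisible by reduction={reduction}"
            )
        mid = channels // reduction
        self.channels, self.mid, self.slope = channels, mid, slope
        self.W1 = Parameter(f"{name}.W1", he_normal(rng, (channels, mid), channels, slope, dtype))
        self.b1 = Parameter(f"{name}.b1", np.zeros(mid, dtype=dtype))
        self.W2 = Parameter(f"{name}.W2", linear_normal(rng, (mid, channels), mid, dtype))
        self.b2 = Parameter(f"{name}.b2", np.zeros(channels, dtype=dtype))
        self._cache = None

    def params(self):
        return [self.W1, self.b1, self.W2, self.b2]

    def gate(self, x: np.ndarray) -> np.ndarray:
        """The (N, C) logistic gate for input ``x`` (no caching)."""
        s = x.mean(axis=(1, 2))
        z1 = s @ self.W1.value + self.b1.value
        a1 = np.where(z1 > 0, z1, self.slope * z1)
        z2 = a1 @ self.W2.value + self.b2.value
        return 1.0 / (1.0 + np.exp(-z2))

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        s = x.mean(axis=(1, 2))
        z1 = s @ self.W1.value + self.b1.value
        a1 = np.where(z1 > 0, z1, self.slope * z1)
        z2 = a1 @ self.W2.value + self.b2.value
        gate = 1.0 / (1.0 + np.exp(-z2))
        out = x * gate[:, None, None, :]
        if train:
            self._cache = (x, s, z1, a1, gate)
        return out

    def backward(self, g: np.ndarray) -> np.ndarray:
        x, s, z1, a1, gate = self._cache
        n, h, w, c = x.shape
        gx = g * gate[:, None, None, :]
        ggate = (g * x).sum(axis=(1, 2))
        gz2 = ggate * gate * (1.0 - gate)
        self.W2.grad += a1.T @ gz2
        self.b2.grad += gz2.sum(axis=0)
        ga1 = gz2 @ self.W2.value.T
        gz1 = np.where(z1 > 0, ga1, self.slope * ga1)
        self.W1.grad += s.T @ gz1
        self.b1.grad += gz1.sum(axis=0)
        gs = gz1 @ self.W1.value.T
        gx += gs[:, None, None, :] / (h * w)
        self._cache = None
        return gx


def pixel_shuffle(x: np.ndarray, r: int) -> np.ndarray:
    """Rearrange ``(N, H, W, r*r*C)`` into ``(N, r*H, r*W, C)``.

    Channel index is interpreted as ``(dy, dx, c)`` in row-major order:
    output pixel ``(r*y + dy, r*x + dx, c)`` comes from channel
    ``(dy*r + dx)*C + c`` at ``(y, x)``.
    """
    n, h, w, c_full = x.shape
    if c_full % (r * r) != 0:
        raise ValueError(
            f"channels={c_full} not divisible by scale^2={r * r}"
        )
    c = c_full // (r * r)
    x = x.reshape(n, h, w, r, r, c)
    x = x.transpose(0, 1, 3, 2, 4, 5)
    return x.reshape(n, h * r, w * r, c)


def pixel_unshuffle(x: np.ndarray, r: int) -> np.ndarray:
    """Inverse of :func:`pixel_shuffle` (space-to-depth)."""
    n, hr, wr, c = x.shape
    if hr % r or wr % r:
        raise ValueError("spatial size not divisible by shuffle factor")
    h, w = hr // r, wr // r
    x = x.reshape(n, h, r, w, r, c)
    x = x.transpose(0, 1, 3, 2, 4, 5)
    return x.reshape(n, h, w, r * r * c)


class AdamState:
    """First/second-moment accumulators for one parameter set."""

    def __init__(self, params: list[Parameter]):
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0


def adam_step(params: list[Parameter], state: AdamState, lr: float,
              beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8) -> None:
    """One ADAM update over ``params`` using their accumulated gradients."""
    state.t += 1
    t = state.t
    bc1 = 1.0 - beta1**t
    bc2 = 1.0 - beta2**t
    for p, m, v in zip(params, state.m, state.v):
        g = p.grad
        m *= beta1
        m += (1.0 - beta1) * g
        v *= beta2
        v += (1.0 - beta2) * (g * g)
        p.value -= lr * (m / bc1) / (np.sqrt(v / bc2) + eps)
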