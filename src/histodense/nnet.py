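"""Minimal numpy neural-network engine (NHWC layout, manual backprop).

Provides exactly the layer vocabulary the segmentation and classification
networks need: 2-D convolution (plain and depthwise), max-pooling, nearest
up-sampling, batch normalisation, dropout, dense heads, and Adam/SGD/RMSProp
optimizers with fused sigmoid-BCE and softmax-CCE losses.  Every layer
implements ``forward``/``backward`` explicitly; correctness is enforced by
finite-difference gradient checks in the test suite.

All computation is float64 and single-threaded numpy, so identical seeds
give bit-identical training histories.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Layer",
    "Conv2D",
    "DepthwiseConv2D",
    "MaxPool2D",
    "UpSample2D",
    "BatchNorm2D",
    "Dropout",
    "Dense",
    "Flatten",
    "ReLU",
    "ZeroPad2D",
    "Sequential",
    "sigmoid",
    "softmax",
    "sigmoid_bce_with_logits",
    "softmax_cce_with_logits",
    "SGD",
    "RMSProp",
    "Adam",
    "make_optimizer",
]


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=float)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def softmax(z: np.ndarray, axis: int = -1) -> np.ndarray:
    z = z - z.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def _same_pad(extent: int, k: int, stride: int) -> tuple[int, int]:
    out = -(-extent // stride)  # ceil
    total = max((out - 1) * stride + k - extent, 0)
    return total // 2, total - total // 2


class Layer:
    """Base layer: trainable params/grads plus forward/backward."""

    def __init__(self) -> None:
        self.params: list[np.ndarray] = []
        self.grads: list[np.ndarray] = []

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv2D(Layer):
    """k x k convolution, 'same' or 'valid' padding, arbitrary stride."""

    def __init__(
        self,
        cin: int,
        cout: int,
        k: int = 3,
        stride: int = 1,
        padding: str = "same",
        use_bias: bool = True,
        rng: np.random.Generator | None = None,
    ) -> None:
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.k, self.stride, self.padding = k, stride, padding
        scale = np.sqrt(2.0 / (k * k * cin))
        self.w = rng.normal(0.0, scale, size=(k, k, cin, cout))
        self.params = [self.w]
        self.use_bias = use_bias
        if use_bias:
            self.b = np.zeros(cout)
            self.params.append(self.b)
        self.grads = [np.zeros_like(p) for p in self.params]

    def _pad(self, x: np.ndarray) -> tuple[np.ndarray, tuple[int, int], tuple[int, int]]:
        if self.padding == "same":
            pt = _same_pad(x.shape[1], self.k, self.stride)
            pl = _same_pad(x.shape[2], self.k, self.stride)
        else:
            pt = pl = (0, 0)
        if pt != (0, 0) or pl != (0, 0):
            x = np.pad(x, ((0, 0), pt, pl, (0, 0)))
        return x, pt, pl

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        xp, pt, pl = self._pad(np.asarray(x, dtype=float))
        self._xp, self._pt, self._pl, self._xshape = xp, pt, pl, x.shape
        cols = sliding_window_view(xp, (self.k, self.k), axis=(1, 2))
        cols = cols[:, :: self.stride, :: self.stride]
        self._cols = cols  # (N, Ho, Wo, C, k, k)
        out = np.einsum("nhwcij,ijco->nhwo", cols, self.w, optimize=True)
        if self.use_bias:
            out += self.b
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.grads[0][...] = np.einsum(
            "nhwcij,nhwo->ijco", self._cols, grad, optimize=True
        )
        if self.use_bias:
            self.grads[1][...] = grad.sum(axis=(0, 1, 2))
        dxp = np.zeros_like(self._xp)
        s, ho, wo = self.stride, grad.shape[1], grad.shape[2]
        for i in range(self.k):
            for j in range(self.k):
                dxp[:, i : i + s * (ho - 1) + 1 : s, j : j + s * (wo - 1) + 1 : s] += (
                    np.einsum("nhwo,co->nhwc", grad, self.w[i, j], optimize=True)
                )
        (t0, _), (l0, _) = self._pt, self._pl
        n, h, w, c = self._xshape
        return dxp[:, t0 : t0 + h, l0 : l0 + w]


class DepthwiseConv2D(Layer):
    """Per-channel k x k convolution (no cross-channel mixing)."""

    def __init__(
        self,
        c: int,
        k: int = 3,
        stride: int = 1,
        padding: str = "same",
        rng: np.random.Generator | None = None,
    ) -> None:
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.k, self.stride, self.padding = k, stride, padding
        self.w = rng.normal(0.0, np.sqrt(2.0 / (k * k)), size=(k, k, c))
        self.b = np.zeros(c)
        self.params = [self.w, self.b]
        self.grads = [np.zeros_like(p) for p in self.params]

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if self.padding == "same":
            pt = _same_pad(x.shape[1], self.k, self.stride)
            pl = _same_pad(x.shape[2], self.k, self.stride)
        else:
            pt = pl = (0, 0)
        xp = np.pad(x, ((0, 0), pt, pl, (0, 0))) if (pt != (0, 0) or pl != (0, 0)) else x
        self._xp, self._pt, self._pl, self._xshape = xp, pt, pl, x.shape
        cols = sliding_window_view(xp, (self.k, self.k), axis=(1, 2))
        self._cols = cols = cols[:, :: self.stride, :: self.stride]
        return np.einsum("nhwcij,ijc->nhwc", cols, self.w, optimize=True) + self.b

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.grads[0][...] = np.einsum("nhwcij,nhwc->ijc", self._cols, grad, optimize=True)
        self.grads[1][...] = grad.sum(axis=(0, 1, 2))
        dxp = np.zeros_like(self._xp)
        s, ho, wo = self.stride, grad.shape[1], grad.shape[2]
        for i in range(self.k):
            for j in range(self.k):
                dxp[:, i : i + s * (ho - 1) + 1 : s, j : j + s * (wo - 1) + 1 : s] += (
                    grad * self.w[i, j]
                )
        (t0, _), (l0, _) = self._pt, self._pl
        n, h, w, c = self._xshape
        return dxp[:, t0 : t0 + h, l0 : l0 + w]


class MaxPool2D(Layer):
    """Max pooling with 'same' padding (pad value -inf, never selected)."""

    def __init__(self, pool: int = 3, stride: int = 2, padding: str = "same") -> None:
        super().__init__()
        self.pool, self.stride, self.padding = pool, stride, padding

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        k, s = self.pool, self.stride
        if self.padding == "same":
            pt = _same_pad(x.shape[1], k, s)
            pl = _same_pad(x.shape[2], k, s)
        else:
            pt = pl = (0, 0)
        xp = np.pad(x, ((0, 0), pt, pl, (0, 0)), constant_values=-np.inf) if (
            pt != (0, 0) or pl != (0, 0)
        ) else x
        cols = sliding_window_view(xp, (k, k), axis=(1, 2))[:, ::s, ::s]
        flat = cols.reshape(*cols.shape[:4], k * k)
        self._arg = flat.argmax(axis=-1)
        self._pt, self._pl, self._xshape = pt, pl, x.shape
        return flat.max(axis=-1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        k, s = self.pool, self.stride
        n, ho, wo, c = grad.shape
        ni, hi, wi, ci = np.ix_(np.arange(n), np.arange(ho), np.arange(wo), np.arange(c))
        ih = hi * s + self._arg // k - self._pt[0]
        iw = wi * s + self._arg % k - self._pl[0]
        dx = np.zeros(self._xshape)
        valid = (ih >= 0) & (ih < self._xshape[1]) & (iw >= 0) & (iw < self._xshape[2])
        nn = np.broadcast_to(ni, grad.shape)[valid]
        cc = np.broadcast_to(ci, grad.shape)[valid]
        np.add.at(dx, (nn, ih[valid], iw[valid], cc), grad[valid])
        return dx


class UpSample2D(Layer):
    """Nearest-neighbour x2 up-sampling."""

    def __init__(self, factor: int = 2) -> None:
        super().__init__()
        self.factor = factor

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        f = self.factor
        return np.asarray(x, dtype=float).repeat(f, axis=1).repeat(f, axis=2)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        f = self.factor
        n, h, w, c = grad.shape
        return grad.reshape(n, h // f, f, w // f, f, c).sum(axis=(2, 4))


class BatchNorm2D(Layer):
    """Batch normalisation over (N, H, W) per channel, with running stats."""

    def __init__(self, c: int, momentum: float = 0.9, eps: float = 1e-5) -> None:
        super().__init__()
        self.gamma = np.ones(c)
        self.beta = np.zeros(c)
        self.params = [self.gamma, self.beta]
        self.grads = [np.zeros_like(p) for p in self.params]
        self.momentum, self.eps = momentum, eps
        self.running_mean = np.zeros(c)
        self.running_var = np.ones(c)

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        axes = tuple(range(x.ndim - 1))
        if training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mean, var = self.running_mean, self.running_var
        self._std = np.sqrt(var + self.eps)
        self._xhat = (x - mean) / self._std
        self._axes = axes
        self._m = x.size / x.shape[-1]
        self._training = training
        return self.gamma * self._xhat + self.beta

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.grads[0][...] = (grad * self._xhat).sum(axis=self._axes)
        self.grads[1][...] = grad.sum(axis=self._axes)
        if not self._training:
            return grad * self.gamma / self._std
        m = self._m
        dxhat = grad * self.gamma
        return (
            dxhat
            - dxhat.mean(axis=self._axes)
            - self._xhat * (dxhat * self._xhat).mean(axis=self._axes)
        ) / self._std


class Dropout(Layer):
    """Inverted dropout; active only when ``training`` is true."""

    def __init__(self, rate: float, rng: np.random.Generator | None = None) -> None:
        super().__init__()
        if not 0 <= rate < 1:
            raise ValueError(f"dropout rate must be in [0, 1), got {rate}")
        self.rate = rate
        self.rng = rng or np.random.default_rng(0)

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if not training or self.rate == 0:
            self._mask = None
            return np.asarray(x, dtype=float)
        self._mask = (self.rng.random(x.shape) >= self.rate) / (1 - self.rate)
        return x * self._mask

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad if self._mask is None else grad * self._mask


class Dense(Layer):
    def __init__(self, nin: int, nout: int, rng: np.random.Generator | None = None) -> None:
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.w = rng.normal(0.0, np.sqrt(2.0 / nin), size=(nin, nout))
        self.b = np.zeros(nout)
        self.params = [self.w, self.b]
        self.grads = [np.zeros_like(p) for p in self.params]

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._x = np.asarray(x, dtype=float)
        return self._x @ self.w + self.b

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.grads[0][...] = self._x.T @ grad
        self.grads[1][...] = grad.sum(axis=0)
        return grad @ self.w.T


class Flatten(Layer):
    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._shape = x.shape
        return np.asarray(x, dtype=float).reshape(x.shape[0], -1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad.reshape(self._shape)


class ReLU(Layer):
    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return np.where(self._mask, grad, 0.0)


class ZeroPad2D(Layer):
    def __init__(self, pad: tuple[tuple[int, int], tuple[int, int]] = ((0, 1), (0, 1))) -> None:
        super().__init__()
        self.pad = pad

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        return np.pad(np.asarray(x, dtype=float), ((0, 0), self.pad[0], self.pad[1], (0, 0)))

    def backward(self, grad: np.ndarray) -> np.ndarray:
        (t, b), (l, r) = self.pad
        h, w = grad.shape[1] - t - b, grad.shape[2] - l - r
        return grad[:, t : t + h, l : l + w]


class Sequential:
    """Plain layer stack with shared parameter/gradient views."""

    def __init__(self, layers: list[Layer]) -> None:
        self.layers = layers

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, training=training)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    @property
    def params(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.params]

    @property
    def grads(self) -> list[np.ndarray]:
        return [g for layer in self.layers for g in layer.grads]

    def n_params(self) -> int:
        return int(sum(p.size for p in self.params))


# ---------------------------------------------------------------------------
# Losses (fused with the output nonlinearity for numerical stability)
# ---------------------------------------------------------------------------

def sigmoid_bce_with_logits(
    logits: np.ndarray, targets: np.ndarray
) -> tuple[float, np.ndarray]:
    """Mean binary cross-entropy on logits; returns (loss, dloss/dlogits)."""
    z, y = np.asarray(logits, float), np.asarray(targets, float)
    loss = np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z)))
    grad = (sigmoid(z) - y) / z.size
    return float(loss.mean()), grad


def softmax_cce_with_logits(
    logits: np.ndarray, onehot: np.ndarray
) -> tuple[float, np.ndarray]:
    """Mean categorical cross-entropy on logits; returns (loss, dloss/dlogits)."""
    z, y = np.asarray(logits, float), np.asarray(onehot, float)
    zs = z - z.max(axis=-1, keepdims=True)
    logp = zs - np.log(np.exp(zs).sum(axis=-1, keepdims=True))
    loss = -(y * logp).sum(axis=-1).mean()
    grad = (np.exp(logp) - y) / z.shape[0]
    return float(loss), grad


# ---------------------------------------------------------------------------
# Optimizers
# ---------------------------------------------------------------------------

class SGD:
    def __init__(self, lr: float = 1e-2, momentum: float = 0.0) -> None:
        self.lr, self.momentum = lr, momentum
        self._v: list[np.ndarray] | None = None

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        if self._v is None:
            self._v = [np.zeros_like(p) for p in params]
        for p, g, v in zip(params, grads, self._v):
            v *= self.momentum
            v -= self.lr * g
            p += v


class RMSProp:
    def __init__(self, lr: float = 1e-3, rho: float = 0.9, eps: float = 1e-8) -> None:
        self.lr, self.rho, self.eps = lr, rho, eps
        self._s: list[np.ndarray] | None = None

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        if self._s is None:
            self._s = [np.zeros_like(p) for p in params]
        for p, g, s in zip(params, grads, self._s):
            s *= self.rho
            s += (1 - self.rho) * g * g
            p -= self.lr * g / (np.sqrt(s) + self.eps)


class Adam:
    def __init__(
        self, lr: float = 1e-3, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8
    ) -> None:
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self._m: list[np.ndarray] | None = None
        self._v: list[np.ndarray] | None = None
        self._t = 0

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        if self._m is None:
            self._m = [np.zeros_like(p) for p in params]
            self._v = [np.zeros_like(p) for p in params]
        self._t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1 - b1**self._t
        bc2 = 1 - b2**self._t
        for p, g, m, v in zip(params, grads, self._m, self._v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)


def refresh_batchnorm_stats(model: "Sequential", x: np.ndarray, batch_size: int = 64) -> None:
    """Re-estimate batch-norm running statistics over a reference set.

    With few, small batches the exponentially averaged statistics lag the
    final weights badly; this replaces them with the exact moments of each
    normalisation layer's input along the inference path (dropout off,
    upstream norms using batch statistics).
    """
    bn_layers = [l for l in model.layers if isinstance(l, BatchNorm2D)]
    if not bn_layers:
        return
    acc = {id(l): [0.0, 0.0, 0] for l in bn_layers}
    for start in range(0, len(x), batch_size):
        h = np.asarray(x[start : start + batch_size], dtype=float)
        for layer in model.layers:
            if isinstance(layer, BatchNorm2D):
                axes = tuple(range(h.ndim - 1))
                a = acc[id(layer)]
                a[0] += h.sum(axis=axes)
                a[1] += (h**2).sum(axis=axes)
                a[2] += h.size // h.shape[-1]
                h = layer.forward(h, training=True)
            else:
                h = layer.forward(h, training=False)
    for layer in bn_layers:
        s, ss, n = acc[id(layer)]
        mean = s / n
        layer.running_mean = mean
        layer.running_var = np.maximum(ss / n - mean**2, 0.0)


def save_params(path, params: list[np.ndarray]) -> None:
    """Serialise a parameter list (order defines identity)."""
    np.savez(path, *params)


def load_params_into(path, params: list[np.ndarray]) -> None:
    """Load a checkpoint into an existing parameter list, in place."""
    with np.load(path) as data:
        arrays = [data[f"arr_{i}"] for i in range(len(data.files))]
    if len(arrays) != len(params):
        raise ValueError(
            f"checkpoint holds {len(arrays)} arrays, model has {len(params)}"
        )
    for p, a in zip(params, arrays):
        if p.shape != a.shape:
            raise ValueError(f"shape mismatch {p.shape} vs {a.shape}")
        p[...] = a


def make_optimizer(name: str, lr: float) -> SGD | RMSProp | Adam:
    name = name.lower()
    if name == "adam":
        return Adam(lr=lr)
    if name == "sgd":
        return SGD(lr=lr, momentum=0.9)
    if name == "rmsprop":
        return RMSProp(lr=lr)
    raise ValueError(f"unknown optimizer {name!r}")
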