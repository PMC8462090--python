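"""A compact numpy CNN engine: 1D/3D convolutions, batch normalization,
dropout, dense layers, bottleneck residual blocks, Adam, and reverse-mode
gradients all the way back to the input (needed for gradient saliency).

Layers cache what their backward pass needs during forward; ``backward``
consumes the cache.  Convolutions use im2col + GEMM; the column buffer is
kept for the weight-gradient GEMM and the input gradient (col2im
scatter-add) is only computed when requested, so the first layer of a
network trains without paying for it.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Param",
    "Layer",
    "Conv1d",
    "Conv3d",
    "BatchNorm",
    "ReLU",
    "Dropout",
    "Dense",
    "GlobalAvgPool",
    "Bottleneck",
    "Sequential",
    "softmax",
    "softmax_cross_entropy",
    "l2_loss",
    "Adam",
]


class Param:
    """A trainable tensor and its gradient accumulator."""

    __slots__ = ("value", "grad", "name")

    def __init__(self, value: np.ndarray, name: str = ""):
        self.value = value
        self.grad = np.zeros_like(value)
        self.name = name


class Layer:
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dy: np.ndarray, need_input_grad: bool = True) -> np.ndarray | None:
        raise NotImplementedError  # pragma: no cover

    def params(self) -> list[Param]:
        return []


def _he_normal(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int, dtype) -> np.ndarray:
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(dtype)


class Conv1d(Layer):
    """1-D convolution along the last axis of (N, C, L) inputs, no bias
    (batch norm follows every convolution)."""

    def __init__(self, in_ch, out_ch, kernel, stride=1, pad=None, *, rng, dtype=np.float64, name="conv1d"):
        self.in_ch, self.out_ch, self.k, self.stride = in_ch, out_ch, kernel, stride
        self.pad = kernel // 2 if pad is None else pad
        self.w = Param(_he_normal(rng, (out_ch, in_ch * kernel), in_ch * kernel, dtype), f"{name}.w")
        self._cache = None

    def out_len(self, length: int) -> int:
        n = (length + 2 * self.pad - self.k) // self.stride + 1
        if n < 1:
            raise ValueError(f"input length {length} too small for kernel {self.k} stride {self.stride}")
        return n

    def forward(self, x, train):
        n, c, length = x.shape
        l_out = self.out_len(length)
        xp = np.pad(x, ((0, 0), (0, 0), (self.pad, self.pad)))
        s0, s1, s2 = xp.strides
        view = np.lib.stride_tricks.as_strided(
            xp, (n, c, self.k, l_out), (s0, s1, s2, s2 * self.stride)
        )
        cols = view.reshape(n, c * self.k, l_out)
        self._cache = (cols, length)
        return np.matmul(self.w.value, cols)

    def backward(self, dy, need_input_grad=True):
        cols, length = self._cache
        self._cache = None
        self.w.grad += np.tensordot(dy, cols, axes=([0, 2], [0, 2]))
        if not need_input_grad:
            return None
        n = dy.shape[0]
        l_out = dy.shape[2]
        dcols = np.matmul(self.w.value.T, dy).reshape(n, self.in_ch, self.k, l_out)
        dxp = np.zeros((n, self.in_ch, length + 2 * self.pad), dtype=dy.dtype)
        for t in range(self.k):
            dxp[:, :, t : t + self.stride * l_out : self.stride] += dcols[:, :, t, :]
        return dxp[:, :, self.pad : self.pad + length]

    def params(self):
        return [self.w]


class Conv3d(Layer):
    """3-D convolution over (N, C, D, H, W) inputs with a cubic kernel."""

    def __init__(self, in_ch, out_ch, kernel, stride=1, pad=None, *, rng, dtype=np.float32, name="conv3d"):
        self.in_ch, self.out_ch, self.k, self.stride = in_ch, out_ch, kernel, stride
        self.pad = kernel // 2 if pad is None else pad
        fan_in = in_ch * kernel**3
        self.w = Param(_he_normal(rng, (out_ch, fan_in), fan_in, dtype), f"{name}.w")
        self._cache = None

    def _out_dim(self, length: int) -> int:
        n = (length + 2 * self.pad - self.k) // self.stride + 1
        if n < 1:
            raise ValueError(f"input dim {length} too small for kernel {self.k} stride {self.stride}")
        return n

    def forward(self, x, train):
        n, c, d, h, w = x.shape
        do, ho, wo = (self._out_dim(v) for v in (d, h, w))
        p, k, s = self.pad, self.k, self.stride
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p), (p, p)))
        cols = np.empty((n, c, k, k, k, do, ho, wo), dtype=x.dtype)
        for a in range(k):
            for b in range(k):
                for cc in range(k):
                    cols[:, :, a, b, cc] = xp[:, :, a : a + s * do : s, b : b + s * ho : s, cc : cc + s * wo : s]
        cols = cols.reshape(n, c * k**3, do * ho * wo)
        self._cache = (cols, (d, h, w), (do, ho, wo))
        y = np.matmul(self.w.value, cols)
        return y.reshape(n, self.out_ch, do, ho, wo)

    def backward(self, dy, need_input_grad=True):
        cols, (d, h, w), (do, ho, wo) = self._cache
        self._cache = None
        n = dy.shape[0]
        dym = dy.reshape(n, self.out_ch, do * ho * wo)
        self.w.grad += np.tensordot(dym, cols, axes=([0, 2], [0, 2]))
        if not need_input_grad:
            return None
        p, k, s = self.pad, self.k, self.stride
        dcols = np.matmul(self.w.value.T, dym).reshape(n, self.in_ch, k, k, k, do, ho, wo)
        dxp = np.zeros((n, self.in_ch, d + 2 * p, h + 2 * p, w + 2 * p), dtype=dy.dtype)
        for a in range(k):
            for b in range(k):
                for cc in range(k):
                    dxp[:, :, a : a + s * do : s, b : b + s * ho : s, cc : cc + s * wo : s] += dcols[:, :, a, b, cc]
        return dxp[:, :, p : p + d, p : p + h, p : p + w]

    def params(self):
        return [self.w]


class BatchNorm(Layer):
    """Batch normalization over all axes except the channel axis (axis 1)."""

    def __init__(self, n_ch, momentum=0.9, eps=1e-5, dtype=np.float64, name="bn"):
        self.n_ch, self.momentum, self.eps = n_ch, momentum, eps
        self.gamma = Param(np.ones(n_ch, dtype=dtype), f"{name}.gamma")
        self.beta = Param(np.zeros(n_ch, dtype=dtype), f"{name}.beta")
        self.running_mean = np.zeros(n_ch, dtype=dtype)
        self.running_var = np.ones(n_ch, dtype=dtype)
        self._cache = None

    def _shape(self, ndim):
        return (1, self.n_ch) + (1,) * (ndim - 2)

    def forward(self, x, train):
        axes = (0,) + tuple(range(2, x.ndim))
        shape = self._shape(x.ndim)
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            inv_std = 1.0 / np.sqrt(var + self.eps)
            xhat = (x - mean.reshape(shape)) * inv_std.reshape(shape)
            m = x.size // self.n_ch
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
            self._cache = ("train", xhat, inv_std, m)
        else:
            inv_std = 1.0 / np.sqrt(self.running_var + self.eps)
            xhat = (x - self.running_mean.reshape(shape)) * inv_std.reshape(shape)
            self._cache = ("eval", xhat, inv_std, None)
        return self.gamma.value.reshape(shape) * xhat + self.beta.value.reshape(shape)

    def backward(self, dy, need_input_grad=True):
        mode, xhat, inv_std, m = self._cache
        self._cache = None
        axes = (0,) + tuple(range(2, dy.ndim))
        shape = self._shape(dy.ndim)
        self.gamma.grad += (dy * xhat).sum(axis=axes)
        self.beta.grad += dy.sum(axis=axes)
        if not need_input_grad:
            return None
        dxhat = dy * self.gamma.value.reshape(shape)
        if mode == "eval":
            return dxhat * inv_std.reshape(shape)
        s1 = dxhat.sum(axis=axes).reshape(shape)
        s2 = (dxhat * xhat).sum(axis=axes).reshape(shape)
        return (inv_std.reshape(shape) / m) * (m * dxhat - s1 - xhat * s2)

    def params(self):
        return [self.gamma, self.beta]


class ReLU(Layer):
    def forward(self, x, train):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy, need_input_grad=True):
        return dy * self._mask if need_input_grad else None


class Dropout(Layer):
    """Inverted dropout; active only in training mode."""

    def __init__(self, p, rng):
        if not 0.0 <= p < 1.0:
            raise ValueError(f"dropout probability must be in [0, 1), got {p}")
        self.p, self.rng = p, rng
        self._mask = None

    def forward(self, x, train):
        if train and self.p > 0:
            self._mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
            return x * self._mask.astype(x.dtype)
        self._mask = None
        return x

    def backward(self, dy, need_input_grad=True):
        if not need_input_grad:
            return None
        return dy if self._mask is None else dy * self._mask.astype(dy.dtype)


class Dense(Layer):
    def __init__(self, n_in, n_out, *, rng, dtype=np.float64, name="dense"):
        self.w = Param(_he_normal(rng, (n_in, n_out), n_in, dtype), f"{name}.w")
        self.b = Param(np.zeros(n_out, dtype=dtype), f"{name}.b")

    def forward(self, x, train):
        self._x = x
        return x @ self.w.value + self.b.value

    def backward(self, dy, need_input_grad=True):
        self.w.grad += self._x.T @ dy
        self.b.grad += dy.sum(axis=0)
        return dy @ self.w.value.T if need_input_grad else None

    def params(self):
        return [self.w, self.b]


class GlobalAvgPool(Layer):
    """Mean over all spatial axes: (N, C, ...) -> (N, C)."""

    def forward(self, x, train):
        self._shape = x.shape
        return x.mean(axis=tuple(range(2, x.ndim)))

    def backward(self, dy, need_input_grad=True):
        if not need_input_grad:
            return None
        n, c = dy.shape
        n_sp = int(np.prod(self._shape[2:]))
        out = np.broadcast_to(
            dy.reshape((n, c) + (1,) * (len(self._shape) - 2)), self._shape
        )
        return (out / n_sp).astype(dy.dtype)


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x, train):
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, dy, need_input_grad=True):
        for i in range(len(self.layers) - 1, -1, -1):
            need = need_input_grad or i > 0
            dy = self.layers[i].backward(dy, need_input_grad=need)
        return dy

    def params(self):
        return [p for layer in self.layers for p in layer.params()]


class Bottleneck(Layer):
    """Pre-activation bottleneck residual block.

    Main path: BN-ReLU-conv1(compress) -> BN-ReLU-conv3(stride) ->
    BN-ReLU-conv1(expand); shortcut is the identity, or a strided 1-kernel
    convolution when the channel count or resolution changes.
    """

    def __init__(self, conv_cls, in_ch, out_ch, mid_ch, stride, *, rng, dtype, name="block"):
        mk = lambda cin, cout, k, s, nm: conv_cls(cin, cout, k, stride=s, rng=rng, dtype=dtype, name=nm)
        self.main = Sequential(
            [
                BatchNorm(in_ch, dtype=dtype, name=f"{name}.bn_a"),
                ReLU(),
                mk(in_ch, mid_ch, 1, 1, f"{name}.conv_a"),
                BatchNorm(mid_ch, dtype=dtype, name=f"{name}.bn_b"),
                ReLU(),
                mk(mid_ch, mid_ch, 3, stride, f"{name}.conv_b"),
                BatchNorm(mid_ch, dtype=dtype, name=f"{name}.bn_c"),
                ReLU(),
                mk(mid_ch, out_ch, 1, 1, f"{name}.conv_c"),
            ]
        )
        self.shortcut = None
        if in_ch != out_ch or stride != 1:
            self.shortcut = mk(in_ch, out_ch, 1, stride, f"{name}.conv_sc")

    def forward(self, x, train):
        h = self.main.forward(x, train)
        s = self.shortcut.forward(x, train) if self.shortcut is not None else x
        return h + s

    def backward(self, dy, need_input_grad=True):
        dx_main = self.main.backward(dy, need_input_grad=True)
        if self.shortcut is not None:
            dx_short = self.shortcut.backward(dy, need_input_grad=need_input_grad)
            if not need_input_grad:
                return None
            return dx_main + dx_short
        return dx_main + dy if need_input_grad else None

    def params(self):
        out = self.main.params()
        if self.shortcut is not None:
            out += self.shortcut.params()
        return out


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross-entropy over the batch and its gradient w.r.t. the logits."""
    n = logits.shape[0]
    probs = softmax(logits)
    loss = float(-np.log(np.maximum(probs[np.arange(n), labels], 1e-300)).mean())
    dlogits = probs.copy()
    dlogits[np.arange(n), labels] -= 1.0
    return loss, (dlogits / n).astype(logits.dtype)


def l2_loss(pred: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean 0.5*(pred - target)^2 and its gradient w.r.t. pred."""
    pred_flat = pred.reshape(pred.shape[0])
    diff = pred_flat - target
    loss = float(0.5 * np.mean(diff**2))
    return loss, (diff / pred_flat.size).reshape(pred.shape).astype(pred.dtype)


class Adam:
    def __init__(self, params: list[Param], lr: float, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params, self.lr, self.beta1, self.beta2, self.eps = params, lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0

    def step(self):
        self.t += 1
        b1c = 1 - self.beta1**self.t
        b2c = 1 - self.beta2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= self.beta1
            m += (1 - self.beta1) * p.grad
            v *= self.beta2
            v += (1 - self.beta2) * p.grad**2
            p.value -= self.lr * (m / b1c) / (np.sqrt(v / b2c) + self.eps)
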