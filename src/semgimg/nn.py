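"""A compact numpy CNN engine for the multi-stream classifiers.

Implements the small set of layers the image-stream networks need —
stride-1 'same'-padded convolution, 2x2 non-overlapping max pooling, batch
normalization, ReLU, dropout, dense layers — with explicit forward and
backward passes, an Adam optimizer, and a softmax cross-entropy loss.
Convolutions are evaluated as im2col matrix products so the heavy lifting
runs through BLAS; all tensors are float32, layout ``(n, H, W, C)``.

All randomness (initialization, shuffling, dropout masks) flows from
numpy Generators seeded by the caller, so training is bit-reproducible for
a fixed seed and data order.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Conv2D",
    "MaxPool2x2",
    "BatchNorm",
    "ReLU",
    "Dropout",
    "Flatten",
    "Dense",
    "MultiStreamNet",
    "Adam",
    "softmax",
    "softmax_cross_entropy",
]


class Layer:
    """Base layer: forward caches what backward needs; params are named."""

    params: dict
    grads: dict

    def __init__(self) -> None:
        self.params = {}
        self.grads = {}

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv2D(Layer):
    """Stride-1 2-D convolution with integer zero padding, He-initialized."""

    def __init__(self, cin: int, cout: int, kh: int, kw: int, pad: int,
                 rng: np.random.Generator, stride: int = 1):
        super().__init__()
        if stride != 1:
            raise NotImplementedError("only stride-1 convolutions are supported")
        self.cin, self.cout, self.kh, self.kw, self.pad = cin, cout, kh, kw, pad
        fan_in = cin * kh * kw
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(fan_in, cout))
        self.params = {"W": w.astype(np.float32), "b": np.zeros(cout, np.float32)}
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        p = self.pad
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0))) if p else x
        # windows over (H, W): (n, oH, oW, cin, kh, kw)
        cols = sliding_window_view(xp, (self.kh, self.kw), axis=(1, 2))
        n, oh, ow = cols.shape[:3]
        colsf = cols.reshape(n * oh * ow, self.cin * self.kh * self.kw)
        out = colsf @ self.params["W"] + self.params["b"]
        self._cache = (colsf, x.shape, (n, oh, ow))
        return out.reshape(n, oh, ow, self.cout)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        colsf, xshape, (n, oh, ow) = self._cache
        doutf = dout.reshape(n * oh * ow, self.cout)
        self.grads["W"][...] = colsf.T @ doutf
        self.grads["b"][...] = doutf.sum(axis=0)
        # full correlation of dout with the spatially flipped kernel gives
        # the gradient w.r.t. the padded input
        W = self.params["W"].reshape(self.cin, self.kh, self.kw, self.cout)
        W2 = W[:, ::-1, ::-1, :].transpose(3, 1, 2, 0)  # (cout, kh, kw, cin)
        W2f = np.ascontiguousarray(W2).reshape(self.cout * self.kh * self.kw, self.cin)
        dp = np.pad(dout, ((0, 0), (self.kh - 1, self.kh - 1),
                           (self.kw - 1, self.kw - 1), (0, 0)))
        colsd = sliding_window_view(dp, (self.kh, self.kw), axis=(1, 2))
        hp, wp = colsd.shape[1], colsd.shape[2]
        dxp = colsd.reshape(n * hp * wp, -1) @ W2f
        dxp = dxp.reshape(n, hp, wp, self.cin)
        p = self.pad
        if p:
            dxp = dxp[:, p:-p, p:-p, :]
        return np.ascontiguousarray(dxp)

    def out_shape(self, h: int, w: int) -> tuple[int, int]:
        return h + 2 * self.pad - self.kh + 1, w + 2 * self.pad - self.kw + 1


class MaxPool2x2(Layer):
    """2x2 max pooling with stride 2; odd trailing rows/cols are dropped."""

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        n, h, w, c = x.shape
        h2, w2 = h // 2, w // 2
        xc = x[:, : h2 * 2, : w2 * 2, :]
        xr = xc.reshape(n, h2, 2, w2, 2, c).transpose(0, 1, 3, 5, 2, 4)
        xr = xr.reshape(n, h2, w2, c, 4)
        idx = xr.argmax(axis=-1)
        out = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]
        self._cache = (x.shape, idx)
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        (n, h, w, c), idx = self._cache
        h2, w2 = h // 2, w // 2
        dflat = np.zeros((n, h2, w2, c, 4), dtype=dout.dtype)
        np.put_along_axis(dflat, idx[..., None], dout[..., None], axis=-1)
        dx = np.zeros((n, h, w, c), dtype=dout.dtype)
        dxc = dflat.reshape(n, h2, w2, c, 2, 2).transpose(0, 1, 4, 2, 5, 3)
        dx[:, : h2 * 2, : w2 * 2, :] = dxc.reshape(n, h2 * 2, w2 * 2, c)
        return dx


class BatchNorm(Layer):
    """Batch normalization over all axes but the last (feature) axis."""

    def __init__(self, n_features: int, momentum: float = 0.9, eps: float = 1e-5):
        super().__init__()
        self.momentum, self.eps = momentum, eps
        self.params = {
            "gamma": np.ones(n_features, np.float32),
            "beta": np.zeros(n_features, np.float32),
        }
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        self.running_mean = np.zeros(n_features, np.float32)
        self.running_var = np.ones(n_features, np.float32)

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        axes = tuple(range(x.ndim - 1))
        if training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            m = self.momentum
            self.running_mean[...] = m * self.running_mean + (1 - m) * mean
            self.running_var[...] = m * self.running_var + (1 - m) * var
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * inv
        self._cache = (xhat, inv, axes, x.size // x.shape[-1])
        return self.params["gamma"] * xhat + self.params["beta"]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xhat, inv, axes, m = self._cache
        dgamma = (dout * xhat).sum(axis=axes)
        dbeta = dout.sum(axis=axes)
        self.grads["gamma"][...] = dgamma
        self.grads["beta"][...] = dbeta
        g = self.params["gamma"] * inv / m
        return (g * (m * dout - dbeta - xhat * dgamma)).astype(dout.dtype)


class ReLU(Layer):
    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dout, 0)


class Dropout(Layer):
    """Inverted dropout; identity at evaluation time."""

    def __init__(self, rate: float, rng: np.random.Generator):
        super().__init__()
        self.rate = rate
        self.rng = rng

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if not training or self.rate <= 0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(x.dtype) / keep
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout if self._mask is None else dout * self._mask


class Flatten(Layer):
    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout.reshape(self._shape)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        super().__init__()
        w = rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_in, n_out))
        self.params = {"W": w.astype(np.float32), "b": np.zeros(n_out, np.float32)}
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.grads["W"][...] = self._x.T @ dout
        self.grads["b"][...] = dout.sum(axis=0)
        return dout @ self.params["W"].T


class MultiStreamNet:
    """Several convolutional branches fused by concatenation into one head.

    ``branches`` is a list of layer stacks (one per input stream) each
    ending in :class:`Flatten`; ``head`` is the shared dense stack whose
    last layer emits class logits.
    """

    def __init__(self, branches: list[list[Layer]], head: list[Layer],
                 flatten_sizes: list[int]):
        self.branches = branches
        self.head = head
        self.flatten_sizes = flatten_sizes

    def forward(self, xs: list[np.ndarray], training: bool = False) -> np.ndarray:
        feats = []
        for branch, x in zip(self.branches, xs, strict=True):
            h = x
            for layer in branch:
                h = layer.forward(h, training)
            feats.append(h)
        z = np.concatenate(feats, axis=1) if len(feats) > 1 else feats[0]
        for layer in self.head:
            z = layer.forward(z, training)
        return z

    def backward(self, dlogits: np.ndarray) -> None:
        d = dlogits
        for layer in reversed(self.head):
            d = layer.backward(d)
        offset = 0
        for branch, size in zip(self.branches, self.flatten_sizes, strict=True):
            db = d[:, offset : offset + size]
            for layer in reversed(branch):
                db = layer.backward(db)
            offset += size

    def layers(self) -> list[Layer]:
        out: list[Layer] = []
        for branch in self.branches:
            out.extend(branch)
        out.extend(self.head)
        return out

    def parameters(self) -> list[tuple[np.ndarray, np.ndarray]]:
        pairs = []
        for layer in self.layers():
            for name in sorted(layer.params):
                pairs.append((layer.params[name], layer.grads[name]))
        return pairs

    def state_arrays(self) -> dict[str, np.ndarray]:
        """All learned arrays (params + BN running stats) keyed stably."""
        state = {}
        for i, layer in enumerate(self.layers()):
            for name in sorted(layer.params):
                state[f"layer{i:03d}.{name}"] = layer.params[name]
            if isinstance(layer, BatchNorm):
                state[f"layer{i:03d}.running_mean"] = layer.running_mean
                state[f"layer{i:03d}.running_var"] = layer.running_var
        return state

    def load_state(self, state: dict[str, np.ndarray]) -> None:
        own = self.state_arrays()
        if set(own) != set(state):
            raise ValueError("checkpoint does not match this architecture")
        for key, arr in own.items():
            arr[...] = state[key]


class Adam:
    """Adam with bias correction; one moment pair per parameter array."""

    def __init__(self, net: MultiStreamNet, lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.net = net
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self._m = [np.zeros_like(p) for p, _ in net.parameters()]
        self._v = [np.zeros_like(p) for p, _ in net.parameters()]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1**self.t
        bc2 = 1.0 - b2**self.t
        for (p, g), m, v in zip(self.net.parameters(), self._m, self._v):
            m[...] = b1 * m + (1 - b1) * g
            v[...] = b2 * v + (1 - b2) * g * g
            p -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, y: np.ndarray):
    """Mean cross-entropy loss; returns (loss, dlogits, probabilities)."""
    n = logits.shape[0]
    p = softmax(logits.astype(np.float64))
    loss = -np.log(np.clip(p[np.arange(n), y], 1e-12, None)).mean()
    d = p.copy()
    d[np.arange(n), y] -= 1.0
    d /= n
    return float(loss), d.astype(np.float32), p
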