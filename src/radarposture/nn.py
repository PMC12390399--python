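"""Minimal CPU neural-network layers with manual backpropagation.

Implements exactly the operations the dual-stream fusion classifiers need —
3x3 same convolution (im2col + BLAS matmul), batch normalization, ReLU, 2x2
max pooling with floor division, adaptive and global average pooling, linear
layers, dropout, a sigmoid spatial-attention head and softmax cross-entropy —
plus an Adam optimizer.  All tensors are float32 in NCHW layout; all
randomness comes from an explicit ``numpy.random.Generator``, so training is
bit-reproducible in single-threaded deterministic mode.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Param", "Conv2d", "BatchNorm2d", "ReLU", "MaxPool2d", "AdaptiveAvgPool2d",
    "GlobalAvgPool", "Linear", "Dropout", "Sequential", "SpatialAttention",
    "softmax", "cross_entropy", "Adam",
]


class Param:
    """A trainable array with its gradient accumulator."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.ascontiguousarray(value, dtype=np.float32)
        self.grad = np.zeros_like(self.value)

    def zero_grad(self) -> None:
        self.grad.fill(0.0)


class Module:
    def params(self) -> list[Param]:
        return []

    def free_caches(self) -> None:
        """Drop forward/backward activation caches (keeps parameters)."""
        for name in ("_cols", "_cache", "_mask", "_x", "_shape"):
            if hasattr(self, name):
                setattr(self, name, None)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def __call__(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        return self.forward(x, train)


def _im2col3(x: np.ndarray) -> np.ndarray:
    """3x3/pad-1 patch matrix: (N, C, H, W) -> (N, C*9, H*W)."""
    N, C, H, W = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
    s = xp.strides
    cols = np.lib.stride_tricks.as_strided(
        xp, (N, C, 3, 3, H, W), (s[0], s[1], s[2], s[3], s[2], s[3])
    )
    return np.ascontiguousarray(cols).reshape(N, C * 9, H * W)


class Conv2d(Module):
    """3x3 convolution, stride 1, padding 1 (shape-preserving)."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        std = np.sqrt(2.0 / (cin * 9))  # He initialization
        self.w = Param(rng.normal(0.0, std, (cout, cin, 3, 3)))
        self.b = Param(np.zeros(cout))
        self.cin, self.cout = cin, cout
        self._cols = None
        self._shape = None
        #: set on the first layer of a network: its input gradient is never
        #: consumed, so the (large) transposed convolution can be skipped
        self.skip_input_grad = False

    def params(self):
        return [self.w, self.b]

    def forward(self, x, train=False):
        N, C, H, W = x.shape
        if C != self.cin:
            raise ValueError(f"expected {self.cin} input channels, got {C}")
        cols = _im2col3(x.astype(np.float32, copy=False))
        w2 = self.w.value.reshape(self.cout, -1)
        out = np.matmul(w2[None], cols)  # (N, cout, H*W)
        out += self.b.value[None, :, None]
        self._cols, self._shape = cols, (N, C, H, W)
        return out.reshape(N, self.cout, H, W)

    def backward(self, dout):
        N, C, H, W = self._shape
        d2 = dout.reshape(N, self.cout, H * W).astype(np.float32, copy=False)
        dw = np.matmul(d2, self._cols.transpose(0, 2, 1)).sum(axis=0)
        self.w.grad += dw.reshape(self.w.value.shape)
        self.b.grad += d2.sum(axis=(0, 2))
        if self.skip_input_grad:
            self._cols = None
            return None
        # dx via col2im: dcols = W^T dout, then scatter-add the 9 taps
        w2 = self.w.value.reshape(self.cout, -1)
        dcols = np.matmul(w2.T[None], d2)  # (N, cin*9, H*W)
        dcols = dcols.reshape(N, self.cin, 3, 3, H, W)
        dxp = np.zeros((N, self.cin, H + 2, W + 2), dtype=np.float32)
        for dy in range(3):
            for dx_ in range(3):
                dxp[:, :, dy:dy + H, dx_:dx_ + W] += dcols[:, :, dy, dx_]
        self._cols = None
        return dxp[:, :, 1:-1, 1:-1]


class BatchNorm2d(Module):
    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Param(np.ones(channels))
        self.beta = Param(np.zeros(channels))
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)
        self.momentum, self.eps = momentum, eps

    def params(self):
        return [self.gamma, self.beta]

    @staticmethod
    def _channel_sums(x):
        return (np.einsum("nchw->c", x, optimize=True),
                np.einsum("nchw,nchw->c", x, x, optimize=True))

    def forward(self, x, train=False):
        x = x.astype(np.float32, copy=False)
        m = x.shape[0] * x.shape[2] * x.shape[3]
        if train:
            s1, s2 = self._channel_sums(x)
            mean = s1 / m
            var = np.maximum(s2 / m - mean * mean, 0.0)
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        invstd = (1.0 / np.sqrt(var + self.eps)).astype(np.float32)
        mean = mean.astype(np.float32)
        a = self.gamma.value * invstd
        b = self.beta.value - mean * a
        self._cache = (x, mean, invstd, train)
        return x * a[None, :, None, None] + b[None, :, None, None]

    def backward(self, dout):
        x, mean, invstd, train = self._cache
        dout = dout.astype(np.float32, copy=False)
        m = x.shape[0] * x.shape[2] * x.shape[3]
        s1 = np.einsum("nchw->c", dout, optimize=True)
        s2 = np.einsum("nchw,nchw->c", dout, x, optimize=True)
        self.gamma.grad += (s2 - mean * s1) * invstd
        self.beta.grad += s1
        g = self.gamma.value
        if not train:
            return dout * (g * invstd)[None, :, None, None]
        # dx = invstd * (dxhat - mean(dxhat) - xhat * mean(dxhat * xhat))
        m1 = g * s1 / m  # per-channel mean of dxhat
        q = g * invstd * (s2 / m - mean * s1 / m)  # mean of dxhat * xhat
        a = (g * invstd).astype(np.float32)
        c2 = (invstd * invstd * q).astype(np.float32)
        c1 = (invstd * m1 - mean * c2).astype(np.float32)
        return (dout * a[None, :, None, None]
                - x * c2[None, :, None, None]
                - c1[None, :, None, None])


class ReLU(Module):
    def forward(self, x, train=False):
        mask = x > 0
        self._mask = mask
        out = x.astype(np.float32, copy=False)
        return np.multiply(out, mask, out=np.empty_like(out))

    def backward(self, dout):
        return dout * self._mask


class MaxPool2d(Module):
    """2x2 max pooling, stride 2, floor division of odd dimensions.

    Backward routes the gradient to every position attaining the window
    maximum (ties share the gradient only where the forward value is tied,
    which for continuous activations happens with probability zero; tied
    zeros are killed by the preceding ReLU's backward anyway).
    """

    def forward(self, x, train=False):
        N, C, H, W = x.shape
        Ho, Wo = H // 2, W // 2
        xc = x[:, :, : Ho * 2, : Wo * 2]
        a = xc[:, :, 0::2, 0::2]
        b = xc[:, :, 0::2, 1::2]
        c = xc[:, :, 1::2, 0::2]
        d = xc[:, :, 1::2, 1::2]
        out = np.maximum(np.maximum(a, b), np.maximum(c, d))
        self._cache = (x, out, (N, C, H, W))
        return out

    def backward(self, dout):
        x, out, (N, C, H, W) = self._cache
        Ho, Wo = H // 2, W // 2
        dx = np.zeros((N, C, H, W), dtype=np.float32)
        for dy in range(2):
            for dx_ in range(2):
                sl = x[:, :, dy: Ho * 2: 2, dx_: Wo * 2: 2]
                dx[:, :, dy: Ho * 2: 2, dx_: Wo * 2: 2] = (sl == out) * dout
        return dx


class AdaptiveAvgPool2d(Module):
    """Average pooling to a fixed output size with variable window bounds."""

    def __init__(self, out_hw: tuple[int, int]):
        self.out_hw = out_hw

    @staticmethod
    def _bounds(n_in: int, n_out: int):
        starts = (np.arange(n_out) * n_in) // n_out
        ends = -((-(np.arange(1, n_out + 1) * n_in)) // n_out)  # ceil
        return starts, ends

    def forward(self, x, train=False):
        N, C, H, W = x.shape
        oh, ow = self.out_hw
        hs, he = self._bounds(H, oh)
        ws, we = self._bounds(W, ow)
        out = np.empty((N, C, oh, ow), dtype=np.float32)
        for i in range(oh):
            for j in range(ow):
                out[:, :, i, j] = x[:, :, hs[i]:he[i], ws[j]:we[j]].mean(axis=(2, 3))
        self._cache = (hs, he, ws, we, (N, C, H, W))
        return out

    def backward(self, dout):
        hs, he, ws, we, shape = self._cache
        dx = np.zeros(shape, dtype=np.float32)
        oh, ow = self.out_hw
        for i in range(oh):
            for j in range(ow):
                area = (he[i] - hs[i]) * (we[j] - ws[j])
                dx[:, :, hs[i]:he[i], ws[j]:we[j]] += (
                    dout[:, :, i, j][:, :, None, None] / area
                )
        return dx


class GlobalAvgPool(Module):
    """(N, C, H, W) -> (N, C) by spatial averaging."""

    def forward(self, x, train=False):
        self._shape = x.shape
        return x.mean(axis=(2, 3)).astype(np.float32)

    def backward(self, dout):
        N, C, H, W = self._shape
        return (np.broadcast_to(dout[:, :, None, None], (N, C, H, W))
                / (H * W)).astype(np.float32)


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        std = np.sqrt(2.0 / n_in)
        self.w = Param(rng.normal(0.0, std, (n_in, n_out)))
        self.b = Param(np.zeros(n_out))

    def params(self):
        return [self.w, self.b]

    def forward(self, x, train=False):
        self._x = x.astype(np.float32, copy=False)
        return self._x @ self.w.value + self.b.value

    def backward(self, dout):
        self.w.grad += self._x.T @ dout
        self.b.grad += dout.sum(axis=0)
        return (dout @ self.w.value.T).astype(np.float32)


class Dropout(Module):
    def __init__(self, p: float, rng: np.random.Generator):
        self.p, self.rng = p, rng

    def forward(self, x, train=False):
        if not train or self.p <= 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.p
        self._mask = (self.rng.random(x.shape) < keep).astype(np.float32) / keep
        return x * self._mask

    def backward(self, dout):
        return dout if self._mask is None else dout * self._mask


class Sequential(Module):
    def __init__(self, *layers: Module):
        self.layers = list(layers)

    def params(self):
        return [p for layer in self.layers for p in layer.params()]

    def free_caches(self):
        for layer in self.layers:
            layer.free_caches()

    def forward(self, x, train=False):
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, dout):
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
            if dout is None:
                break
        return dout


def _sigmoid(x):
    return np.where(x >= 0, 1.0 / (1.0 + np.exp(-x)),
                    np.exp(np.clip(x, -60, 0)) / (1.0 + np.exp(np.clip(x, -60, 0))))


class SpatialAttention(Module):
    """Single-channel spatial attention mask from channel-wise statistics.

    Channel-wise average and max maps are stacked into a 2-channel tensor,
    passed through a 3x3 convolution (2 -> 1 channels) and a sigmoid,
    yielding a mask in (0, 1) with the input's spatial size.  One instance
    may be shared between modality streams (shared weights).

    ``forward`` returns the mask only; use :meth:`apply` for mask * features
    with the matching backward.
    """

    def __init__(self, rng: np.random.Generator):
        self.conv = Conv2d(2, 1, rng)

    def params(self):
        return self.conv.params()

    def free_caches(self):
        super().free_caches()
        self.conv.free_caches()

    def forward(self, f, train=False):
        if f.ndim != 4:
            raise ValueError("expected NCHW features")
        avg = f.mean(axis=1, keepdims=True)
        idx = np.argmax(f, axis=1, keepdims=True)
        mx = np.take_along_axis(f, idx, axis=1)
        stacked = np.concatenate([avg, mx], axis=1).astype(np.float32)
        logits = self.conv.forward(stacked, train)
        mask = _sigmoid(logits).astype(np.float32)
        self._cache = (idx, f.shape, mask)
        return mask

    def backward(self, dmask):
        idx, fshape, mask = self._cache
        dlogits = dmask * mask * (1.0 - mask)
        dstacked = self.conv.backward(dlogits.astype(np.float32))
        davg, dmx = dstacked[:, :1], dstacked[:, 1:]
        C = fshape[1]
        df = np.broadcast_to(davg / C, fshape).copy()
        np.put_along_axis(df, idx, np.take_along_axis(df, idx, axis=1) + dmx, axis=1)
        return df.astype(np.float32)


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def cross_entropy(logits: np.ndarray, labels: np.ndarray):
    """Mean cross-entropy loss and its gradient w.r.t. the logits."""
    n = logits.shape[0]
    p = softmax(logits.astype(np.float64))
    loss = -np.log(np.maximum(p[np.arange(n), labels], 1e-12)).mean()
    dlogits = p
    dlogits[np.arange(n), labels] -= 1.0
    return float(loss), (dlogits / n).astype(np.float32)


class Adam:
    def __init__(self, params: list[Param], lr: float = 1e-3,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, betas[0], betas[1], eps
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.zero_grad()

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m += (1.0 - self.b1) * (p.grad - m)
            v += (1.0 - self.b2) * (p.grad * p.grad - v)
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
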