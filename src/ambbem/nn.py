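"""Minimal NumPy CNN backend for the slice classifier.

Implements exactly the layer set the improved ResNet50 needs — 2-D
convolution (im2col + GEMM), batch normalization, ReLU/sigmoid, max and
global-average pooling, fully connected layers, softmax, residual
bottleneck blocks, squeeze-and-excitation gating, and CBAM attention —
each with an explicit backward pass, plus an Adam optimizer.  Data layout
is NCHW float32.  Every layer caches what its backward pass needs during a
``train=True`` forward call; inference calls cache nothing.

The backward passes are verified against central-difference numerical
gradients in the test suite.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.special import expit as _sigmoid

__all__ = [
    "Param", "Layer", "Sequential", "Conv2d", "BatchNorm2d", "ReLU",
    "Sigmoid", "MaxPool2d", "GlobalAvgPool", "Linear", "Softmax",
    "Bottleneck", "SEBlock", "CBAM", "Adam",
]


class Param:
    """A trainable tensor and its gradient accumulator."""

    __slots__ = ("data", "grad")

    def __init__(self, data: np.ndarray):
        self.data = np.ascontiguousarray(data, dtype=np.float32)
        self.grad = np.zeros_like(self.data)


class Layer:
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def parameters(self) -> list[Param]:
        return []


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x, train=False):
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, grad):
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def parameters(self):
        return [p for layer in self.layers for p in layer.parameters()]


# -- primitive layers -------------------------------------------------------

def _im2col(xp: np.ndarray, k: int, stride: int):
    """(N,C,Hp,Wp) -> (N,Ho,Wo,C,k,k) view with the given stride."""
    win = sliding_window_view(xp, (k, k), axis=(2, 3))  # N,C,Ho*,Wo*,k,k
    win = win[:, :, ::stride, ::stride]
    return np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5))


class Conv2d(Layer):
    """k x k convolution, no bias (batch norm always follows), He init."""

    def __init__(self, cin, cout, k, stride=1, pad=0, rng=None):
        rng = rng or np.random.default_rng()
        scale = np.sqrt(2.0 / (cin * k * k))
        self.w = Param(rng.normal(0.0, scale, (cout, cin, k, k)))
        self.k, self.stride, self.pad = k, stride, pad
        self._cache = None

    def forward(self, x, train=False):
        k, s, p = self.k, self.stride, self.pad
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p))) if p else x
        cols = _im2col(xp, k, s)                      # N,Ho,Wo,C,k,k
        n, ho, wo = cols.shape[:3]
        cols2 = cols.reshape(n * ho * wo, -1)
        out = cols2 @ self.w.data.reshape(self.w.data.shape[0], -1).T
        out = out.reshape(n, ho, wo, -1).transpose(0, 3, 1, 2)
        if train:
            self._cache = (cols2, x.shape, (n, ho, wo))
        return np.ascontiguousarray(out)

    def backward(self, grad):
        cols2, xshape, (n, ho, wo) = self._cache
        cout = self.w.data.shape[0]
        g2 = grad.transpose(0, 2, 3, 1).reshape(n * ho * wo, cout)
        self.w.grad += (g2.T @ cols2).reshape(self.w.data.shape)
        dcols = (g2 @ self.w.data.reshape(cout, -1))
        k, s, p = self.k, self.stride, self.pad
        _, c, h, w = xshape
        dcols = dcols.reshape(n, ho, wo, c, k, k).transpose(0, 3, 1, 2, 4, 5)
        dxp = np.zeros((n, c, h + 2 * p, w + 2 * p), dtype=np.float32)
        for ki in range(k):
            for kj in range(k):
                dxp[:, :, ki:ki + s * ho:s, kj:kj + s * wo:s] += dcols[:, :, :, :, ki, kj]
        return dxp[:, :, p:p + h, p:p + w] if p else dxp

    def parameters(self):
        return [self.w]


class BatchNorm2d(Layer):
    def __init__(self, c, momentum=0.9, eps=1e-5):
        self.gamma, self.beta = Param(np.ones(c)), Param(np.zeros(c))
        self.running_mean = np.zeros(c, dtype=np.float32)
        self.running_var = np.ones(c, dtype=np.float32)
        self.momentum, self.eps = momentum, eps
        self._cache = None

    def forward(self, x, train=False):
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = (self.momentum * self.running_mean
                                 + (1 - self.momentum) * mean)
            self.running_var = (self.momentum * self.running_var
                                + (1 - self.momentum) * var)
        else:
            mean, var = self.running_mean, self.running_var
        std = np.sqrt(var + self.eps).astype(np.float32)
        xhat = (x - mean[:, None, None]) / std[:, None, None]
        if train:
            self._cache = (xhat, std)
        return (self.gamma.data[:, None, None] * xhat
                + self.beta.data[:, None, None]).astype(np.float32)

    def backward(self, grad):
        xhat, std = self._cache
        axes = (0, 2, 3)
        self.gamma.grad += (grad * xhat).sum(axis=axes)
        self.beta.grad += grad.sum(axis=axes)
        m = grad.shape[0] * grad.shape[2] * grad.shape[3]
        g = self.gamma.data[:, None, None]
        dmean = grad.mean(axis=axes)[:, None, None]
        dvarterm = (grad * xhat).mean(axis=axes)[:, None, None]
        return (g / std[:, None, None]) * (grad - dmean - xhat * dvarterm)

    def parameters(self):
        return [self.gamma, self.beta]


class ReLU(Layer):
    def forward(self, x, train=False):
        out = np.maximum(x, 0.0)
        if train:
            self._mask = x > 0
        return out

    def backward(self, grad):
        return grad * self._mask


class Sigmoid(Layer):
    def forward(self, x, train=False):
        out = _sigmoid(x)
        if train:
            self._out = out
        return out

    def backward(self, grad):
        return grad * self._out * (1.0 - self._out)


class MaxPool2d(Layer):
    def __init__(self, k, stride, pad=0):
        self.k, self.stride, self.pad = k, stride, pad

    def forward(self, x, train=False):
        k, s, p = self.k, self.stride, self.pad
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)),
                    constant_values=-np.inf) if p else x
        win = sliding_window_view(xp, (k, k), axis=(2, 3))[:, :, ::s, ::s]
        flat = win.reshape(*win.shape[:4], k * k)
        if train:
            self._argmax = flat.argmax(axis=-1)
            self._xshape, self._oshape = x.shape, flat.shape[:4]
        return flat.max(axis=-1)

    def backward(self, grad):
        k, s, p = self.k, self.stride, self.pad
        n, c, h, w = self._xshape
        _, _, ho, wo = self._oshape
        dxp = np.zeros((n, c, h + 2 * p, w + 2 * p), dtype=np.float32)
        for pos in range(k * k):
            mask = self._argmax == pos
            if not mask.any():
                continue
            ki, kj = divmod(pos, k)
            dxp[:, :, ki:ki + s * ho:s, kj:kj + s * wo:s] += grad * mask
        return dxp[:, :, p:p + h, p:p + w] if p else dxp


class GlobalAvgPool(Layer):
    """(N,C,H,W) -> (N,C)."""

    def forward(self, x, train=False):
        if train:
            self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, grad):
        n, c, h, w = self._shape
        return np.broadcast_to(grad[:, :, None, None] / (h * w), self._shape).astype(np.float32)


class Linear(Layer):
    def __init__(self, cin, cout, rng=None):
        rng = rng or np.random.default_rng()
        scale = np.sqrt(2.0 / cin)
        self.w = Param(rng.normal(0.0, scale, (cin, cout)))
        self.b = Param(np.zeros(cout))

    def forward(self, x, train=False):
        if train:
            self._x = x
        return x @ self.w.data + self.b.data

    def backward(self, grad):
        self.w.grad += self._x.T @ grad
        self.b.grad += grad.sum(axis=0)
        return grad @ self.w.data.T

    def parameters(self):
        return [self.w, self.b]


class Softmax(Layer):
    """Row-wise softmax.  ``backward`` expects dL/dlogits directly (the
    cross-entropy gradient ``probs - onehot``), the usual fused convention."""

    def forward(self, x, train=False):
        z = x - x.max(axis=1, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=1, keepdims=True)

    def backward(self, grad):
        return grad


# -- composite blocks -------------------------------------------------------

class SEBlock(Layer):
    """Squeeze-and-excitation: global average pool, two FC layers with the
    given reduction ratio, sigmoid gate multiplied back onto the features."""

    def __init__(self, c, reduction=16, rng=None):
        hidden = max(1, c // reduction)
        self.fc1, self.relu = Linear(c, hidden, rng=rng), ReLU()
        self.fc2, self.sig = Linear(hidden, c, rng=rng), Sigmoid()

    def _gate(self, x, train):
        z = x.mean(axis=(2, 3))
        return self.sig.forward(
            self.fc2.forward(self.relu.forward(self.fc1.forward(z, train), train), train),
            train)

    def forward(self, x, train=False):
        s = self._gate(x, train)
        if train:
            self._x, self._s = x, s
        return x * s[:, :, None, None]

    def backward(self, grad):
        x, s = self._x, self._s
        ds = (grad * x).sum(axis=(2, 3))
        dz = self.fc1.backward(self.relu.backward(self.fc2.backward(self.sig.backward(ds))))
        h, w = x.shape[2], x.shape[3]
        return grad * s[:, :, None, None] + dz[:, :, None, None] / (h * w)

    def parameters(self):
        return self.fc1.parameters() + self.fc2.parameters()


class CBAM(Layer):
    """Convolutional block attention: channel attention (shared MLP over
    average- and max-pooled descriptors) followed by spatial attention
    (7x7 conv over channel-wise mean and max maps)."""

    def __init__(self, c, reduction=16, spatial_kernel=7, rng=None):
        hidden = max(1, c // reduction)
        self.fc1, self.fc2 = Linear(c, hidden, rng=rng), Linear(hidden, c, rng=rng)
        self.conv = Conv2d(2, 1, spatial_kernel, stride=1,
                           pad=spatial_kernel // 2, rng=rng)

    def forward(self, x, train=False):
        n, c, h, w = x.shape
        avg, mx = x.mean(axis=(2, 3)), x.max(axis=(2, 3))
        relu = lambda v: np.maximum(v, 0.0)
        pre_a = self.fc1.forward(avg, False)
        pre_m = self.fc1.forward(mx, False)
        logits = (self.fc2.forward(relu(pre_a), False)
                  + self.fc2.forward(relu(pre_m), False))
        ca = _sigmoid(logits)                            # (N,C)
        x1 = x * ca[:, :, None, None]

        savg = x1.mean(axis=1, keepdims=True)
        smax = x1.max(axis=1, keepdims=True)
        sin = np.concatenate([savg, smax], axis=1)       # (N,2,H,W)
        slogit = self.conv.forward(sin, train)
        sa = _sigmoid(slogit)                            # (N,1,H,W)
        out = x1 * sa
        if train:
            self._cache = (x, avg, mx, pre_a, pre_m, ca, x1, smax, sa)
        return out

    def backward(self, grad):
        x, avg, mx, pre_a, pre_m, ca, x1, smax, sa = self._cache
        n, c, h, w = x.shape
        # spatial gate
        dx1 = grad * sa
        dsa = (grad * x1).sum(axis=1, keepdims=True)
        dslogit = dsa * sa * (1.0 - sa)
        dsin = self.conv.backward(dslogit)
        dx1 += dsin[:, 0:1] / c                           # mean-map path
        maxmask = (x1 == smax)
        maxmask = maxmask / np.maximum(maxmask.sum(axis=1, keepdims=True), 1)
        dx1 += dsin[:, 1:2] * maxmask                     # max-map path
        # channel gate
        dx = dx1 * ca[:, :, None, None]
        dca = (dx1 * x).sum(axis=(2, 3))
        dlogits = dca * ca * (1.0 - ca)
        # shared-MLP branches (manual, since the Linears are reused)
        dh_a = dlogits @ self.fc2.w.data.T * (pre_a > 0)
        dh_m = dlogits @ self.fc2.w.data.T * (pre_m > 0)
        self.fc2.w.grad += (np.maximum(pre_a, 0).T @ dlogits
                            + np.maximum(pre_m, 0).T @ dlogits)
        self.fc2.b.grad += 2 * dlogits.sum(axis=0)
        self.fc1.w.grad += avg.T @ dh_a + mx.T @ dh_m
        self.fc1.b.grad += dh_a.sum(axis=0) + dh_m.sum(axis=0)
        davg = dh_a @ self.fc1.w.data.T
        dmx = dh_m @ self.fc1.w.data.T
        dx += davg[:, :, None, None] / (h * w)
        flat = x.reshape(n, c, -1)
        am = flat.argmax(axis=2)
        scatter = np.zeros_like(flat)
        ni, ci = np.meshgrid(np.arange(n), np.arange(c), indexing="ij")
        scatter[ni, ci, am] = dmx
        dx += scatter.reshape(x.shape)
        return dx

    def parameters(self):
        return self.fc1.parameters() + self.fc2.parameters() + self.conv.parameters()


class Bottleneck(Layer):
    """ResNet bottleneck: 1x1 reduce, 3x3 (stride), 1x1 expand, residual add.

    A 1x1 strided projection with batch norm is used on the shortcut when
    the shape changes; otherwise the shortcut is the identity."""

    def __init__(self, cin, cmid, cout, stride=1, rng=None):
        self.conv1, self.bn1 = Conv2d(cin, cmid, 1, rng=rng), BatchNorm2d(cmid)
        self.conv2, self.bn2 = Conv2d(cmid, cmid, 3, stride=stride, pad=1, rng=rng), BatchNorm2d(cmid)
        self.conv3, self.bn3 = Conv2d(cmid, cout, 1, rng=rng), BatchNorm2d(cout)
        self.relu1, self.relu2, self.relu3 = ReLU(), ReLU(), ReLU()
        if stride != 1 or cin != cout:
            self.proj, self.bnp = Conv2d(cin, cout, 1, stride=stride, rng=rng), BatchNorm2d(cout)
        else:
            self.proj = self.bnp = None

    def forward(self, x, train=False):
        y = self.relu1.forward(self.bn1.forward(self.conv1.forward(x, train), train), train)
        y = self.relu2.forward(self.bn2.forward(self.conv2.forward(y, train), train), train)
        y = self.bn3.forward(self.conv3.forward(y, train), train)
        short = x if self.proj is None else self.bnp.forward(self.proj.forward(x, train), train)
        return self.relu3.forward(y + short, train)

    def backward(self, grad):
        grad = self.relu3.backward(grad)
        dshort = grad if self.proj is None else self.proj.backward(self.bnp.backward(grad))
        g = self.conv3.backward(self.bn3.backward(grad))
        g = self.conv2.backward(self.bn2.backward(self.relu2.backward(g)))
        g = self.conv1.backward(self.bn1.backward(self.relu1.backward(g)))
        return g + dshort

    def parameters(self):
        layers = [self.conv1, self.bn1, self.conv2, self.bn2, self.conv3, self.bn3]
        if self.proj is not None:
            layers += [self.proj, self.bnp]
        return [p for l in layers for p in l.parameters()]


class Adam(Layer):
    def __init__(self, params: list[Param], lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def step(self):
        self.t += 1
        b1t = 1 - self.b1 ** self.t
        b2t = 1 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * p.grad
            v *= self.b2
            v += (1 - self.b2) * p.grad ** 2
            p.data -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
            p.grad[:] = 0.0
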