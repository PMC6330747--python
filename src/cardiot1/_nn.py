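"""Minimal NumPy neural-network layers with manual backpropagation.

Just what the myocardium segmenter needs: 2-D convolution (im2col + GEMM),
batch normalization, ReLU, inverted dropout, 2x2 max pooling, nearest
up-sampling, channel concatenation, softmax cross-entropy, and Adam.
Everything is float32; each layer caches what its backward pass needs.
"""

from __future__ import annotations

import numpy as np

F32 = np.float32


class Layer:
    """Base: layers expose params/grads as parallel lists of arrays."""

    params: list
    grads: list

    def __init__(self):
        self.params = []
        self.grads = []

    def forward(self, x, training=False, rng=None):
        raise NotImplementedError

    def backward(self, dout):
        raise NotImplementedError


def _im2col(x, k, pad):
    """(N, C, H, W) -> (N, H, W, C*k*k) patch matrix (stride 1, same size)."""
    n, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
    # win: (N, C, H, W, k, k) -> (N, H, W, C, k, k)
    return np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(n, h, w, c * k * k)


def _col2im(dcol, x_shape, k, pad):
    """Adjoint of _im2col: scatter-add patches back to the input grid."""
    n, c, h, w = x_shape
    dxp = np.zeros((n, c, h + 2 * pad, w + 2 * pad), dtype=dcol.dtype)
    d6 = dcol.reshape(n, h, w, c, k, k).transpose(0, 3, 1, 2, 4, 5)
    for ki in range(k):
        for kj in range(k):
            dxp[:, :, ki:ki + h, kj:kj + w] += d6[:, :, :, :, ki, kj]
    if pad:
        return dxp[:, :, pad:-pad, pad:-pad]
    return dxp


class Conv2D(Layer):
    """Same-padded stride-1 convolution with He-initialized kernels."""

    def __init__(self, in_ch, out_ch, k, rng):
        super().__init__()
        self.in_ch, self.out_ch, self.k = in_ch, out_ch, k
        self.pad = k // 2
        std = np.sqrt(2.0 / (in_ch * k * k))
        w = rng.normal(0.0, std, size=(out_ch, in_ch * k * k)).astype(F32)
        b = np.zeros(out_ch, dtype=F32)
        self.params = [w, b]
        self.grads = [np.zeros_like(w), np.zeros_like(b)]

    def forward(self, x, training=False, rng=None):
        self._x_shape = x.shape
        col = _im2col(x, self.k, self.pad)               # (N, H, W, Cin*k*k)
        self._col = col if training else None
        out = col @ self.params[0].T + self.params[1]    # (N, H, W, Cout)
        return np.ascontiguousarray(out.transpose(0, 3, 1, 2))

    def backward(self, dout):
        n, co, h, w = dout.shape
        dmat = dout.transpose(0, 2, 3, 1).reshape(-1, co)      # (NHW, Cout)
        colmat = self._col.reshape(-1, self.in_ch * self.k * self.k)
        self.grads[0][...] = dmat.T @ colmat
        self.grads[1][...] = dmat.sum(axis=0)
        dcol = dmat @ self.params[0]                            # (NHW, Cin*k*k)
        self._col = None
        return _col2im(dcol.reshape(n, h, w, -1), self._x_shape, self.k, self.pad)


class BatchNorm2D(Layer):
    """Per-channel batch normalization; running stats are used at inference
    (frozen — inference is deterministic)."""

    def __init__(self, ch, momentum=0.1, eps=1e-5):
        super().__init__()
        self.eps = F32(eps)
        self.momentum = momentum
        gamma = np.ones(ch, dtype=F32)
        beta = np.zeros(ch, dtype=F32)
        self.params = [gamma, beta]
        self.grads = [np.zeros_like(gamma), np.zeros_like(beta)]
        self.running_mean = np.zeros(ch, dtype=F32)
        self.running_var = np.ones(ch, dtype=F32)

    def forward(self, x, training=False, rng=None):
        gamma, beta = self.params
        if training:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv[None, :, None, None]
        if training:
            self._xhat, self._inv = xhat, inv
        return gamma[None, :, None, None] * xhat + beta[None, :, None, None]

    def backward(self, dout):
        gamma = self.params[0]
        xhat, inv = self._xhat, self._inv
        m = dout.shape[0] * dout.shape[2] * dout.shape[3]
        self.grads[0][...] = (dout * xhat).sum(axis=(0, 2, 3))
        self.grads[1][...] = dout.sum(axis=(0, 2, 3))
        dxhat = dout * gamma[None, :, None, None]
        dx = (inv[None, :, None, None] / m) * (
            m * dxhat
            - dxhat.sum(axis=(0, 2, 3), keepdims=True)
            - xhat * (dxhat * xhat).sum(axis=(0, 2, 3), keepdims=True))
        self._xhat = self._inv = None
        return dx.astype(F32)


class ReLU(Layer):
    def forward(self, x, training=False, rng=None):
        mask = x > 0
        self._mask = mask if training else None
        return x * mask

    def backward(self, dout):
        dx = dout * self._mask
        self._mask = None
        return dx


class Dropout(Layer):
    """Inverted dropout; identity at inference."""

    def __init__(self, p):
        super().__init__()
        self.p = p

    def forward(self, x, training=False, rng=None):
        if not training or self.p == 0:
            self._mask = None
            return x
        keep = 1.0 - self.p
        self._mask = (rng.random(x.shape) < keep).astype(F32) / F32(keep)
        return x * self._mask

    def backward(self, dout):
        if self._mask is None:
            return dout
        dx = dout * self._mask
        self._mask = None
        return dx


class MaxPool2x2(Layer):
    def forward(self, x, training=False, rng=None):
        n, c, h, w = x.shape
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2)
        out = xr.max(axis=(3, 5))
        if training:
            self._mask = (xr == out[:, :, :, None, :, None])
            self._shape = x.shape
        return out

    def backward(self, dout):
        n, c, h, w = self._shape
        dx = (self._mask * dout[:, :, :, None, :, None]).reshape(n, c, h, w)
        self._mask = None
        return dx.astype(F32)


class UpsampleNearest2x(Layer):
    def forward(self, x, training=False, rng=None):
        return np.repeat(np.repeat(x, 2, axis=2), 2, axis=3)

    def backward(self, dout):
        n, c, h, w = dout.shape
        return dout.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


def softmax_channels(logits):
    """Softmax over the channel axis of (N, C, H, W)."""
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy_loss(logits, labels):
    """Mean pixel-wise cross entropy; returns (loss, dlogits).

    ``labels`` are integer class maps of shape (N, H, W).
    """
    probs = softmax_channels(logits)
    n, c, h, w = probs.shape
    idx_n, idx_h, idx_w = np.ogrid[:n, :h, :w]
    p_true = probs[idx_n, labels, idx_h, idx_w]
    loss = float(-np.log(np.clip(p_true, 1e-12, None)).mean())
    dlogits = probs.copy()
    onehot = np.zeros_like(probs)
    onehot[idx_n, labels, idx_h, idx_w] = 1.0
    dlogits = (dlogits - onehot) / (n * h * w)
    return loss, dlogits.astype(F32)


class Adam:
    """Adam with L2 weight decay folded into the gradient."""

    def __init__(self, params, grads, lr=0.001, beta1=0.9, beta2=0.999,
                 eps=1e-8, weight_decay=0.001):
        self.params, self.grads = params, grads
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.wd = weight_decay
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self):
        self.t += 1
        b1t = 1 - self.b1 ** self.t
        b2t = 1 - self.b2 ** self.t
        for p, g, m, v in zip(self.params, self.grads, self.m, self.v):
            g = g + self.wd * p
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
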