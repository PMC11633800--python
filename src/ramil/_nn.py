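"""Minimal neural-network numerics: layers with forward/backward passes and Adam.

Everything operates on plain ``numpy`` arrays. Each ``*_forward`` returns
``(output, cache)`` and the matching ``*_backward`` consumes the upstream
gradient plus that cache, mirroring the usual autodiff contract. Gradients
are exact (analytic); correctness is checked against finite differences in
the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "sigmoid",
    "stable_softmax",
    "linear_forward",
    "linear_backward",
    "relu_forward",
    "relu_backward",
    "conv2d_forward",
    "conv2d_backward",
    "maxpool_forward",
    "maxpool_backward",
    "global_avgpool_forward",
    "global_avgpool_backward",
    "Adam",
]


def sigmoid(x: np.ndarray | float) -> np.ndarray | float:
    """Numerically stable logistic function."""
    return np.where(
        np.asarray(x) >= 0,
        1.0 / (1.0 + np.exp(-np.clip(x, -500, 500))),
        np.exp(np.clip(x, -500, 500)) / (1.0 + np.exp(np.clip(x, -500, 500))),
    )


def stable_softmax(logits: np.ndarray) -> np.ndarray:
    """Softmax over the last axis with max-logit subtraction."""
    z = logits - np.max(logits, axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


# ---------------------------------------------------------------------------
# dense / activation layers


def linear_forward(x, W, b):
    """y = x @ W.T + b for x of shape (..., in), W of shape (out, in)."""
    return x @ W.T + b, (x, W)


def linear_backward(gy, cache):
    x, W = cache
    x2 = x.reshape(-1, x.shape[-1])
    gy2 = gy.reshape(-1, gy.shape[-1])
    gW = gy2.T @ x2
    gb = gy2.sum(axis=0)
    gx = gy @ W
    return gx.reshape(x.shape), gW, gb


def relu_forward(x):
    y = np.maximum(x, 0.0)
    return y, (x > 0)


def relu_backward(gy, mask):
    return gy * mask


# ---------------------------------------------------------------------------
# convolution (stride 1, 'same' padding) via im2col


def _im2col(x: np.ndarray, kh: int, kw: int) -> np.ndarray:
    """x: (C, H, W) zero-padded -> columns (H*W, C*kh*kw) for stride-1 'same' conv."""
    C, H, W = x.shape
    ph, pw = kh // 2, kw // 2
    xp = np.pad(x, ((0, 0), (ph, ph), (pw, pw)))
    s0, s1, s2 = xp.strides
    windows = np.lib.stride_tricks.as_strided(
        xp,
        shape=(C, H, W, kh, kw),
        strides=(s0, s1, s2, s1, s2),
        writeable=False,
    )
    return windows.transpose(1, 2, 0, 3, 4).reshape(H * W, C * kh * kw)


def conv2d_forward(x, W, b):
    """2D convolution (cross-correlation), stride 1, same padding.

    x: (C_in, H, W); W: (C_out, C_in, kh, kw); b: (C_out,)
    returns y: (C_out, H, W)
    """
    c_out, c_in, kh, kw = W.shape
    _, H, Wd = x.shape
    cols = _im2col(x, kh, kw)
    y = cols @ W.reshape(c_out, -1).T + b
    return y.T.reshape(c_out, H, Wd), (x, W, cols)


def conv2d_backward(gy, cache):
    x, W, cols = cache
    c_out, c_in, kh, kw = W.shape
    _, H, Wd = x.shape
    gy2 = gy.reshape(c_out, -1).T  # (H*W, C_out)
    gW = (gy2.T @ cols).reshape(W.shape)
    gb = gy2.sum(axis=0)
    # gradient to input: scatter columns back (col2im)
    gcols = gy2 @ W.reshape(c_out, -1)  # (H*W, C_in*kh*kw)
    ph, pw = kh // 2, kw // 2
    gxp = np.zeros((c_in, H + 2 * ph, Wd + 2 * pw))
    gcols = gcols.reshape(H, Wd, c_in, kh, kw)
    for i in range(kh):
        for j in range(kw):
            gxp[:, i : i + H, j : j + Wd] += gcols[:, :, :, i, j].transpose(2, 0, 1)
    gx = gxp[:, ph : ph + H, pw : pw + Wd]
    return gx, gW, gb


# ---------------------------------------------------------------------------
# pooling


def maxpool_forward(x, size):
    """Non-overlapping max pool; trailing rows/cols that do not fill a window are dropped.

    x: (C, H, W) -> (C, H//size, W//size)
    """
    C, H, W = x.shape
    Ho, Wo = H // size, W // size
    xc = x[:, : Ho * size, : Wo * size].reshape(C, Ho, size, Wo, size)
    xw = xc.transpose(0, 1, 3, 2, 4).reshape(C, Ho, Wo, size * size)
    arg = xw.argmax(axis=-1)
    y = np.take_along_axis(xw, arg[..., None], axis=-1)[..., 0]
    return y, (x.shape, size, arg)


def maxpool_backward(gy, cache):
    shape, size, arg = cache
    C, H, W = shape
    Ho, Wo = H // size, W // size
    gxw = np.zeros((C, Ho, Wo, size * size))
    np.put_along_axis(gxw, arg[..., None], gy[..., None], axis=-1)
    gx = np.zeros(shape)
    gx[:, : Ho * size, : Wo * size] = (
        gxw.reshape(C, Ho, Wo, size, size).transpose(0, 1, 3, 2, 4).reshape(C, Ho * size, Wo * size)
    )
    return gx


def global_avgpool_forward(x):
    """(C, H, W) -> (C,) spatial mean."""
    return x.mean(axis=(1, 2)), x.shape


def global_avgpool_backward(gy, shape):
    C, H, W = shape
    return np.broadcast_to(gy[:, None, None] / (H * W), shape).copy()


# ---------------------------------------------------------------------------
# optimizer


class Adam:
    """Adam with (optionally) L2 weight decay added to the gradient.

    Operates in place on a dict of parameter arrays keyed by name.
    """

    def __init__(self, params, lr=2e-5, beta1=0.9, beta2=0.999, eps=1e-8, weight_decay=0.0):
        self.params = params
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, grads) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k, p in self.params.items():
            g = grads.get(k)
            if g is None:
                continue
            if self.weight_decay:
                g = g + self.weight_decay * p
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / (1 - b1**self.t)
            vhat = self.v[k] / (1 - b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
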