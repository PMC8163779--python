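"""Minimal NumPy CNN core used by :class:`myogrid.model.GridConvNetClassifier`.

Layers: conv3x3(same) -> ReLU -> conv3x3(same) -> ReLU -> global average
pool -> dense -> ReLU -> dense head -> softmax.  The head (final dense
layer) is the session-tunable classifier; everything before it is the
feature extractor.
"""

from __future__ import annotations

import numpy as np

FEATURE_PARAMS = ("conv1_W", "conv1_b", "conv2_W", "conv2_b", "fc1_W", "fc1_b")
HEAD_PARAMS = ("head_W", "head_b")
ALL_PARAMS = FEATURE_PARAMS + HEAD_PARAMS


def init_params(rng, n_filters1, n_filters2, hidden_units, n_classes, dtype=np.float32):
    def he(shape, fan_in):
        return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(dtype)

    return {
        "conv1_W": he((n_filters1, 1, 3, 3), 9),
        "conv1_b": np.zeros(n_filters1, dtype=dtype),
        "conv2_W": he((n_filters2, n_filters1, 3, 3), 9 * n_filters1),
        "conv2_b": np.zeros(n_filters2, dtype=dtype),
        "fc1_W": he((n_filters2, hidden_units), n_filters2),
        "fc1_b": np.zeros(hidden_units, dtype=dtype),
        "head_W": he((hidden_units, n_classes), hidden_units),
        "head_b": np.zeros(n_classes, dtype=dtype),
    }


def conv3x3(x, W, b):
    # x: (N, C, H, Wd); W: (F, C, 3, 3); same padding
    n, c, h, wd = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
    out = np.zeros((n, W.shape[0], h, wd), dtype=x.dtype)
    for di in range(3):
        for dj in range(3):
            patch = xp[:, :, di : di + h, dj : dj + wd]
            out += np.einsum("nchw,fc->nfhw", patch, W[:, :, di, dj], optimize=True)
    return out + b[None, :, None, None]


def conv3x3_backward(dout, x, W):
    n, c, h, wd = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
    dxp = np.zeros_like(xp)
    dW = np.zeros_like(W)
    for di in range(3):
        for dj in range(3):
            patch = xp[:, :, di : di + h, dj : dj + wd]
            dW[:, :, di, dj] = np.einsum("nfhw,nchw->fc", dout, patch, optimize=True)
            dxp[:, :, di : di + h, dj : dj + wd] += np.einsum(
                "nfhw,fc->nchw", dout, W[:, :, di, dj], optimize=True
            )
    db = dout.sum(axis=(0, 2, 3))
    return dxp[:, :, 1 : 1 + h, 1 : 1 + wd], dW, db


def forward(params, x):
    # x: (N, 1, 4, 8) -> logits (N, K); cache for backward
    z1 = conv3x3(x, params["conv1_W"], params["conv1_b"])
    a1 = np.maximum(z1, 0)
    z2 = conv3x3(a1, params["conv2_W"], params["conv2_b"])
    a2 = np.maximum(z2, 0)
    pooled = a2.mean(axis=(2, 3))
    z3 = pooled @ params["fc1_W"] + params["fc1_b"]
    a3 = np.maximum(z3, 0)
    logits = a3 @ params["head_W"] + params["head_b"]
    cache = (x, z1, a1, z2, a2, pooled, z3, a3)
    return logits, cache


def backward(params, cache, dlogits):
    x, z1, a1, z2, a2, pooled, z3, a3 = cache
    grads = {}
    grads["head_W"] = a3.T @ dlogits
    grads["head_b"] = dlogits.sum(axis=0)
    da3 = dlogits @ params["head_W"].T
    dz3 = da3 * (z3 > 0)
    grads["fc1_W"] = pooled.T @ dz3
    grads["fc1_b"] = dz3.sum(axis=0)
    dpooled = dz3 @ params["fc1_W"].T
    hw = a2.shape[2] * a2.shape[3]
    da2 = np.broadcast_to(
        dpooled[:, :, None, None] / hw, a2.shape
    ).astype(a2.dtype)
    dz2 = da2 * (z2 > 0)
    da1, grads["conv2_W"], grads["conv2_b"] = conv3x3_backward(dz2, a1, params["conv2_W"])
    dz1 = da1 * (z1 > 0)
    _, grads["conv1_W"], grads["conv1_b"] = conv3x3_backward(dz1, x, params["conv1_W"])
    return grads


def softmax(logits):
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_xent(logits, y_idx):
    # mean cross-entropy and gradient w.r.t. logits
    p = softmax(logits)
    n = logits.shape[0]
    loss = -float(np.mean(np.log(p[np.arange(n), y_idx] + 1e-12)))
    dlogits = p
    dlogits[np.arange(n), y_idx] -= 1.0
    return loss, dlogits / n


class Adam:
    """Adam over a named subset of parameters."""

    def __init__(self, names, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.names = tuple(names)
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {}
        self.v = {}
        self.t = 0

    def step(self, params, grads):
        self.t += 1
        for name in self.names:
            g = grads[name].astype(params[name].dtype)
            m = self.m.setdefault(name, np.zeros_like(params[name]))
            v = self.v.setdefault(name, np.zeros_like(params[name]))
            m += (1 - self.b1) * (g - m)
            v += (1 - self.b2) * (g * g - v)
            mh = m / (1 - self.b1**self.t)
            vh = v / (1 - self.b2**self.t)
            params[name] -= (self.lr * mh / (np.sqrt(vh) + self.eps)).astype(
                params[name].dtype
            )
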