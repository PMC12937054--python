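"""Compact convolutional network for EIC image classification.

A small, dependency-free CNN sized so that a few hundred images per
class train in minutes on one CPU.  The architecture is deliberately
modest — two conv/pool stages and two dense layers on a 112x112
grayscale downsampling of the rendered 224x224 image — because the
discriminative signal in a chronogram plot (event-locked comb vs flat
or drifting baseline vs isolated spikes) is texture at the scale of a
few pixels, not fine detail; halving once keeps that texture while
quartering the compute.

Any model implementing the same small interface (``train_step``,
``predict_proba``, ``get_state``/``set_state``, ``hyperparams``) can
be dropped in, e.g. a transfer-learned backbone; this class is the
reference implementation.  All initialisation and updates are driven
by an explicit seed, so identical data and seed reproduce identical
training trajectories bit for bit.
"""

from __future__ import annotations

import numpy as np

__all__ = ["CompactCNN", "preprocess_images", "MODEL_REGISTRY"]


def preprocess_images(pixels: np.ndarray) -> np.ndarray:
    """(N, 224, 224, 3) uint8 -> (N, 1, 112, 112) float in [0, 1], ink=1."""
    x = np.asarray(pixels, dtype=np.float64)
    if x.ndim == 3:
        x = x[None]
    gray = 1.0 - x.mean(axis=3) / 255.0  # dark line on white -> positive signal
    n, h, w = gray.shape
    gray = gray.reshape(n, h // 2, 2, w // 2, 2).mean(axis=(2, 4))
    return gray[:, None, :, :]


def _conv_forward(x, w, b, stride):
    n, _c, hin, win = x.shape
    f, _c, kh, kw = w.shape
    ho = (hin - kh) // stride + 1
    wo = (win - kw) // stride + 1
    out = np.tile(b[None, :, None, None], (n, 1, ho, wo))
    for i in range(kh):
        for j in range(kw):
            patch = x[:, :, i:i + stride * ho:stride, j:j + stride * wo:stride]
            out += np.einsum("nchw,fc->nfhw", patch, w[:, :, i, j])
    return out


def _conv_backward(x, w, stride, dout):
    n, _c, hin, win = x.shape
    f, c, kh, kw = w.shape
    _n, _f, ho, wo = dout.shape
    dx = np.zeros_like(x)
    dw = np.zeros_like(w)
    for i in range(kh):
        for j in range(kw):
            patch = x[:, :, i:i + stride * ho:stride, j:j + stride * wo:stride]
            dw[:, :, i, j] = np.einsum("nfhw,nchw->fc", dout, patch)
            dx[:, :, i:i + stride * ho:stride, j:j + stride * wo:stride] += \
                np.einsum("nfhw,fc->nchw", dout, w[:, :, i, j])
    db = dout.sum(axis=(0, 2, 3))
    return dx, dw, db


def _pool_forward(x):
    n, c, h, w = x.shape
    h2, w2 = h // 2, w // 2
    x = x[:, :, :2 * h2, :2 * w2]
    r = x.reshape(n, c, h2, 2, w2, 2)
    out = r.max(axis=(3, 5))
    mask = r == out[:, :, :, None, :, None]
    return out, (mask, (n, c, h, w))


def _pool_backward(dout, cache):
    mask, (n, c, h, w) = cache
    h2, w2 = dout.shape[2], dout.shape[3]
    dr = mask * dout[:, :, :, None, :, None]
    dx = np.zeros((n, c, h, w))
    dx[:, :, :2 * h2, :2 * w2] = dr.reshape(n, c, 2 * h2, 2 * w2)
    return dx


class CompactCNN:
    """conv(8,5x5,s2)-pool - conv(16,3x3)-pool - fc64 - fc(n_classes).

    On the 112x112 input the feature maps are 54 -> 27 -> 25 -> 12,
    flattening to 2304 values before the dense head.
    """

    def __init__(self, n_classes: int = 3, seed: int = 0, lr: float = 1e-3):
        self.n_classes = n_classes
        self.seed = seed
        self.lr = lr
        rng = np.random.default_rng(seed)

        def he(shape, fan_in):
            return rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)

        self.params = {
            "w1": he((8, 1, 5, 5), 25), "b1": np.zeros(8),
            "w2": he((16, 8, 3, 3), 72), "b2": np.zeros(16),
            "w3": he((2304, 64), 2304), "b3": np.zeros(64),
            "w4": he((64, n_classes), 64), "b4": np.zeros(n_classes),
        }
        self._adam = {k: (np.zeros_like(v), np.zeros_like(v))
                      for k, v in self.params.items()}
        self._t = 0

    # -- forward / backward ------------------------------------------------

    def _forward(self, x):
        p = self.params
        c1 = _conv_forward(x, p["w1"], p["b1"], 2)
        a1 = np.maximum(c1, 0.0)
        p1, cache1 = _pool_forward(a1)
        c2 = _conv_forward(p1, p["w2"], p["b2"], 1)
        a2 = np.maximum(c2, 0.0)
        p2, cache2 = _pool_forward(a2)
        flat = p2.reshape(x.shape[0], -1)
        h = flat @ p["w3"] + p["b3"]
        ah = np.maximum(h, 0.0)
        logits = ah @ p["w4"] + p["b4"]
        cache = (x, c1, a1, p1, cache1, c2, a2, p2, cache2, flat, h, ah)
        return logits, cache

    @staticmethod
    def _softmax(logits):
        z = logits - logits.max(axis=1, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=1, keepdims=True)

    def loss(self, x, y):
        """Mean cross-entropy of preprocessed inputs ``x`` vs labels ``y``."""
        logits, _ = self._forward(x)
        probs = self._softmax(logits)
        return float(-np.log(probs[np.arange(y.size), y] + 1e-12).mean())

    def train_step(self, x, y) -> float:
        logits, cache = self._forward(x)
        probs = self._softmax(logits)
        n = y.size
        loss = float(-np.log(probs[np.arange(n), y] + 1e-12).mean())

        dlogits = probs.copy()
        dlogits[np.arange(n), y] -= 1.0
        dlogits /= n

        (x0, c1, _a1, p1, cache1, c2, _a2, p2, cache2, flat, h, ah) = cache
        p = self.params
        grads = {}
        grads["w4"] = ah.T @ dlogits
        grads["b4"] = dlogits.sum(axis=0)
        dah = dlogits @ p["w4"].T
        dh = dah * (h > 0)
        grads["w3"] = flat.T @ dh
        grads["b3"] = dh.sum(axis=0)
        dflat = dh @ p["w3"].T
        dp2 = dflat.reshape(p2.shape)
        da2 = _pool_backward(dp2, cache2)
        dc2 = da2 * (c2 > 0)
        dp1, grads["w2"], grads["b2"] = _conv_backward(p1, p["w2"], 1, dc2)
        da1 = _pool_backward(dp1, cache1)
        dc1 = da1 * (c1 > 0)
        _dx, grads["w1"], grads["b1"] = _conv_backward(x0, p["w1"], 2, dc1)

        self._t += 1
        b1, b2, eps = 0.9, 0.999, 1e-8
        for k, g in grads.items():
            m, v = self._adam[k]
            m[:] = b1 * m + (1 - b1) * g
            v[:] = b2 * v + (1 - b2) * g * g
            mhat = m / (1 - b1 ** self._t)
            vhat = v / (1 - b2 ** self._t)
            self.params[k] -= self.lr * mhat / (np.sqrt(vhat) + eps)
        return loss

    def predict_proba(self, x) -> np.ndarray:
        logits, _ = self._forward(x)
        return self._softmax(logits)

    # -- state -------------------------------------------------------------

    def get_state(self) -> dict:
        return {k: v.copy() for k, v in self.params.items()}

    def set_state(self, state: dict) -> None:
        for k, v in state.items():
            self.params[k] = np.asarray(v, dtype=np.float64).copy()

    def hyperparams(self) -> dict:
        return {"model": "compact_cnn", "n_classes": self.n_classes,
                "seed": self.seed, "lr": self.lr}


MODEL_REGISTRY = {"compact_cnn": CompactCNN}
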