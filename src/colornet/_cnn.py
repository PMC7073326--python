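"""Minimal convolutional network in numpy (NHWC, 3x3 valid conv, 2x2 maxpool).

Sized for small binary patch classification on a CPU: the forward and
backward passes are expressed as batched matrix products over im2col patches,
with Adam updates and a sigmoid/binary-cross-entropy head.  Deterministic for
a fixed seed.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


def _im2col(x: np.ndarray) -> np.ndarray:
    """(N, H, W, C) -> (N, H-2, W-2, C*9) view-copy of 3x3 neighborhoods."""
    v = sliding_window_view(x, (3, 3), axis=(1, 2))  # (N, H-2, W-2, C, 3, 3)
    n, ho, wo, c = v.shape[:4]
    return v.reshape(n, ho, wo, c * 9)


class Conv3x3:
    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / (9 * c_in))
        self.W = rng.normal(0.0, scale, size=(c_in * 9, c_out))
        self.b = np.zeros(c_out)
        self.params = [self.W, self.b]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        cols = _im2col(x)
        if train:
            self._cols = cols
            self._in_shape = x.shape
        return cols @ self.W + self.b

    def backward(self, dout: np.ndarray):
        n, ho, wo, co = dout.shape
        cols2d = self._cols.reshape(-1, self.W.shape[0])
        d2d = dout.reshape(-1, co)
        dW = cols2d.T @ d2d
        db = d2d.sum(axis=0)
        dcols = (d2d @ self.W.T).reshape(n, ho, wo, -1, 3, 3)
        dx = np.zeros(self._in_shape)
        for di in range(3):
            for dj in range(3):
                dx[:, di : di + ho, dj : dj + wo, :] += dcols[:, :, :, :, di, dj]
        self._cols = None
        return dx, [dW, db]


class ReLU:
    params: list = []

    def forward(self, x, train):
        if train:
            self._mask = x > 0
        return np.maximum(x, 0.0)

    def backward(self, dout):
        return dout * self._mask, []


class MaxPool2:
    params: list = []

    def forward(self, x, train):
        n, h, w, c = x.shape
        h2, w2 = h // 2, w // 2
        xr = x[:, : h2 * 2, : w2 * 2, :].reshape(n, h2, 2, w2, 2, c)
        xf = xr.transpose(0, 1, 3, 5, 2, 4).reshape(n, h2, w2, c, 4)
        out = xf.max(axis=-1)
        if train:
            self._argmax = xf.argmax(axis=-1)
            self._in_shape = x.shape
        return out

    def backward(self, dout):
        n, h, w, c = self._in_shape
        h2, w2 = h // 2, w // 2
        dxf = np.zeros((n, h2, w2, c, 4))
        np.put_along_axis(dxf, self._argmax[..., None], dout[..., None], axis=-1)
        dxr = dxf.reshape(n, h2, w2, c, 2, 2).transpose(0, 1, 4, 2, 5, 3)
        dx = np.zeros(self._in_shape)
        dx[:, : h2 * 2, : w2 * 2, :] = dxr.reshape(n, h2 * 2, w2 * 2, c)
        return dx, []


class Flatten:
    params: list = []

    def forward(self, x, train):
        if train:
            self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._shape), []


class Dense:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / n_in)
        self.W = rng.normal(0.0, scale, size=(n_in, n_out))
        self.b = np.zeros(n_out)
        self.params = [self.W, self.b]

    def forward(self, x, train):
        if train:
            self._x = x
        return x @ self.W + self.b

    def backward(self, dout):
        dW = self._x.T @ dout
        db = dout.sum(axis=0)
        dx = dout @ self.W.T
        self._x = None
        return dx, [dW, db]


def sigmoid(z):
    out = np.empty_like(z, dtype=np.float64)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class SmallCNN:
    """conv(3x3)/relu/pool blocks -> dense/relu -> dense(1), sigmoid output."""

    def __init__(self, input_hw: int, channels: tuple[int, ...] = (16, 32, 64),
                 dense: int = 64, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.input_hw = int(input_hw)
        self.channels = tuple(int(c) for c in channels)
        self.dense = int(dense)
        self.layers = []
        c_in = 3
        hw = self.input_hw
        for c_out in self.channels:
            self.layers += [Conv3x3(c_in, c_out, rng), ReLU(), MaxPool2()]
            hw = (hw - 2) // 2
            c_in = c_out
        self.layers.append(Flatten())
        self.layers.append(Dense(hw * hw * c_in, self.dense, rng))
        self.layers.append(ReLU())
        self.layers.append(Dense(self.dense, 1, rng))
        self._adam_state = None

    # -- inference ---------------------------------------------------------
    def logits(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        out = x
        for layer in self.layers:
            out = layer.forward(out, train)
        return out[:, 0]

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return sigmoid(self.logits(x, train=False))

    # -- training ----------------------------------------------------------
    def _init_adam(self):
        self._adam_state = []
        for layer in self.layers:
            self._adam_state.append(
                [(np.zeros_like(p), np.zeros_like(p)) for p in layer.params]
            )

    def train_step(self, x, y, lr, beta1=0.9, beta2=0.999, eps=1e-8, t=1):
        """One Adam step on a minibatch; returns the mean BCE loss."""
        z = self.logits(x, train=True)
        p = sigmoid(z)
        yf = y.astype(np.float64)
        loss = -np.mean(yf * np.log(p + 1e-12) + (1 - yf) * np.log(1 - p + 1e-12))
        dz = ((p - yf) / len(yf))[:, None]
        grads_per_layer = []
        dout = dz
        for layer in reversed(self.layers):
            dout, grads = layer.backward(dout)
            grads_per_layer.append(grads)
        grads_per_layer.reverse()
        if self._adam_state is None:
            self._init_adam()
        for layer, grads, state in zip(self.layers, grads_per_layer, self._adam_state):
            for p_arr, g, (m, v) in zip(layer.params, grads, state):
                m *= beta1
                m += (1 - beta1) * g
                v *= beta2
                v += (1 - beta2) * g * g
                mhat = m / (1 - beta1**t)
                vhat = v / (1 - beta2**t)
                p_arr -= lr * mhat / (np.sqrt(vhat) + eps)
        return float(loss)

    def fit(self, x, y, epochs=10, batch_size=64, lr=1e-3, seed=0, verbose=False):
        rng = np.random.default_rng(seed)
        n = len(x)
        t = 0
        for epoch in range(epochs):
            order = rng.permutation(n)
            losses = []
            for start in range(0, n, batch_size):
                idx = order[start : start + batch_size]
                t += 1
                losses.append(self.train_step(x[idx], y[idx], lr=lr, t=t))
            if verbose:
                print(f"epoch {epoch + 1}/{epochs}: loss {np.mean(losses):.4f}")
        return self

    # -- weights -----------------------------------------------------------
    def get_weights(self) -> list[np.ndarray]:
        out = []
        for layer in self.layers:
            out.extend(layer.params)
        return out

    def set_weights(self, arrays) -> None:
        arrays = list(arrays)
        i = 0
        for layer in self.layers:
            for j in range(len(layer.params)):
                if layer.params[j].shape != arrays[i].shape:
                    raise ValueError("weight shape mismatch for this architecture")
                layer.params[j][...] = arrays[i]
                i += 1
        if i != len(arrays):
            raise ValueError("wrong number of weight arrays for this architecture")
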