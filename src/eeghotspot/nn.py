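"""A small NumPy neural-network engine for 2D-CNN coordinate regression.

Implements exactly the layer types the hotspot regressor needs: 2D
convolution (stride 1, shape-preserving zero-padding) computed as an
im2col/GEMM product, 2x2 stride-2 max-pooling with ceil (zero-padding)
semantics, ReLU, flatten, fully connected layers, mean-squared-error loss and
the Adam optimizer.  Everything runs in float32 and is deterministic given
the initialization RNG and a fixed batch order.
"""

from __future__ import annotations

import numpy as np

DTYPE = np.float32


class Layer:
    params: list  # list of [array, grad, adam_m, adam_v]

    def __init__(self):
        self.params = []

    def forward(self, x, train=True):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, grad):  # pragma: no cover - interface
        raise NotImplementedError

    def _register(self, *arrays):
        for a in arrays:
            self.params.append(
                [a, np.zeros_like(a), np.zeros_like(a), np.zeros_like(a)]
            )


def _im2col(x, kh, kw):
    """(N, C, H, W) -> (N*H*W, C*kh*kw) patches of the zero-padded input."""
    n, c, h, w = x.shape
    ph, pw = kh // 2, kw // 2
    xp = np.pad(x, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
    windows = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(2, 3))
    # windows: (N, C, H, W, kh, kw) -> (N, H, W, C, kh, kw)
    cols = windows.transpose(0, 2, 3, 1, 4, 5).reshape(n * h * w, c * kh * kw)
    return np.ascontiguousarray(cols)


class Conv2D(Layer):
    """7x7 (configurable) convolution, stride 1, same padding."""

    def __init__(self, c_in, c_out, kernel, rng):
        super().__init__()
        kh, kw = kernel
        fan_in = c_in * kh * kw
        w = rng.standard_normal((fan_in, c_out)) * np.sqrt(2.0 / fan_in)
        self.w = w.astype(DTYPE)
        self.b = np.zeros(c_out, dtype=DTYPE)
        self.kernel = (kh, kw)
        self.c_in, self.c_out = c_in, c_out
        self._register(self.w, self.b)

    def forward(self, x, train=True):
        n, c, h, w = x.shape
        cols = _im2col(x, *self.kernel)
        out = cols @ self.params[0][0] + self.params[1][0]
        if train:
            self._cache = (cols, x.shape)
        return out.reshape(n, h, w, self.c_out).transpose(0, 3, 1, 2)

    def backward(self, grad):
        cols, (n, c, h, w) = self._cache
        g = grad.transpose(0, 2, 3, 1).reshape(-1, self.c_out)
        g = np.ascontiguousarray(g)
        self.params[0][1] += cols.T @ g
        self.params[1][1] += g.sum(axis=0)
        # gradient w.r.t. input: correlate grad with the flipped kernel
        kh, kw = self.kernel
        wmat = self.params[0][0].reshape(c, kh, kw, self.c_out)
        wflip = wmat[:, ::-1, ::-1, :].transpose(3, 1, 2, 0).reshape(
            self.c_out * kh * kw, c
        )
        gimg = grad  # (N, c_out, H, W)
        gcols = _im2col(gimg, kh, kw)
        dx = (gcols @ np.ascontiguousarray(wflip)).reshape(n, h, w, c)
        self._cache = None
        return dx.transpose(0, 3, 1, 2)


class ReLU(Layer):
    def forward(self, x, train=True):
        if train:
            self._mask = x > 0
        return np.maximum(x, 0)

    def backward(self, grad):
        return grad * self._mask


class MaxPool2x2(Layer):
    """2x2 window, stride 2, ceil semantics (odd edges zero-padded)."""

    def forward(self, x, train=True):
        n, c, h, w = x.shape
        h2, w2 = -(-h // 2), -(-w // 2)
        if h % 2 or w % 2:
            xp = np.zeros((n, c, h2 * 2, w2 * 2), dtype=x.dtype)
            xp[:, :, :h, :w] = x
        else:
            xp = x
        blocks = xp.reshape(n, c, h2, 2, w2, 2)
        out = blocks.max(axis=(3, 5))
        if train:
            mask = blocks == out[:, :, :, None, :, None]
            # break ties toward the first maximal element
            cum = np.cumsum(np.cumsum(mask, axis=3), axis=5)
            mask = mask & (cum == 1)
            self._cache = (mask, (n, c, h, w))
        return out

    def backward(self, grad):
        mask, (n, c, h, w) = self._cache
        g = mask * grad[:, :, :, None, :, None]
        h2, w2 = mask.shape[2], mask.shape[4]
        g = g.reshape(n, c, h2 * 2, w2 * 2)
        return np.ascontiguousarray(g[:, :, :h, :w])


class Flatten(Layer):
    def forward(self, x, train=True):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class Dense(Layer):
    def __init__(self, n_in, n_out, rng, relu_fan=True):
        super().__init__()
        scale = np.sqrt((2.0 if relu_fan else 1.0) / n_in)
        self.w = (rng.standard_normal((n_in, n_out)) * scale).astype(DTYPE)
        self.b = np.zeros(n_out, dtype=DTYPE)
        self._register(self.w, self.b)

    def forward(self, x, train=True):
        if train:
            self._x = x
        return x @ self.params[0][0] + self.params[1][0]

    def backward(self, grad):
        self.params[0][1] += self._x.T @ grad
        self.params[1][1] += grad.sum(axis=0)
        dx = grad @ self.params[0][0].T
        self._x = None
        return dx


class Network:
    def __init__(self, layers):
        self.layers = layers

    def forward(self, x, train=True):
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, grad):
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def zero_grad(self):
        for p in self._params():
            p[1][...] = 0

    def _params(self):
        return [p for layer in self.layers for p in layer.params]

    def get_weights(self):
        return [p[0].copy() for p in self._params()]

    def set_weights(self, weights):
        for p, w in zip(self._params(), weights):
            p[0][...] = w


class Adam:
    def __init__(self, network, lr=0.001, beta1=0.9, beta2=0.999, eps=1e-7):
        self.net = network
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0

    def step(self):
        self.t += 1
        b1t = 1 - self.b1**self.t
        b2t = 1 - self.b2**self.t
        for value, grad, m, v in self.net._params():
            m *= self.b1
            m += (1 - self.b1) * grad
            v *= self.b2
            v += (1 - self.b2) * grad**2
            value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def mse_loss(pred, target):
    diff = pred - target
    return float(np.mean(diff**2)), (2.0 / diff.size) * diff
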