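"""Layers for the small patch-classification CNNs (float32, NCHW)."""

from __future__ import annotations

import numpy as np


def _im2col3x3(x: np.ndarray) -> np.ndarray:
    """im2col for a 3x3 same-padding convolution.

    x: (N, C, H, W) -> (N*H*W, C*9), rows ordered (n, i, j), columns (c, u, v).
    """
    n, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
    win = np.lib.stride_tricks.sliding_window_view(xp, (3, 3), axis=(2, 3))
    # (N, C, H, W, 3, 3) -> (N, H, W, C, 3, 3)
    return np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(
        n * h * w, c * 9
    )


class Conv2d:
    """3x3 convolution with 'same' (zero) padding, stride 1.

    Weights are He-initialized; the backward pass computes the input
    gradient as a full correlation with the spatially flipped kernels,
    which lets it reuse the same im2col machinery.
    """

    def __init__(self, in_channels: int, out_channels: int, rng: np.random.Generator):
        std = np.sqrt(2.0 / (in_channels * 9))
        self.weight = rng.normal(0.0, std, (out_channels, in_channels, 3, 3)).astype(
            np.float32
        )
        self.bias = np.zeros(out_channels, dtype=np.float32)
        self.dweight = np.zeros_like(self.weight)
        self.dbias = np.zeros_like(self.bias)
        self._col: np.ndarray | None = None
        self._xshape: tuple | None = None

    def params(self):
        return [(self.weight, self.dweight), (self.bias, self.dbias)]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        n, c, h, w = x.shape
        col = _im2col3x3(x)
        if train:
            self._col = col
            self._xshape = x.shape
        cout = self.weight.shape[0]
        wr = self.weight.reshape(cout, c * 9)
        out = col @ wr.T + self.bias
        return out.reshape(n, h, w, cout).transpose(0, 3, 1, 2)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, cout, h, w = dout.shape
        cin = self.weight.shape[1]
        dflat = np.ascontiguousarray(dout.transpose(0, 2, 3, 1)).reshape(
            n * h * w, cout
        )
        self.dweight[...] = (dflat.T @ self._col).reshape(self.weight.shape)
        self.dbias[...] = dflat.sum(axis=0)
        # dx = full-correlation of dout with flipped kernels, summed over cout
        dcol = _im2col3x3(dout)  # (N*H*W, cout*9)
        wflip = self.weight[:, :, ::-1, ::-1].transpose(1, 0, 2, 3)  # (cin, cout, 3, 3)
        dx = dcol @ wflip.reshape(cin, cout * 9).T
        self._col = None
        return dx.reshape(n, h, w, cin).transpose(0, 3, 1, 2)


class BatchNorm2d:
    """Per-channel batch normalization over (N, H, W).

    Training uses mini-batch statistics and keeps exponential running
    estimates (momentum 0.1) for inference.
    """

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1):
        self.gamma = np.ones(channels, dtype=np.float32)
        self.beta = np.zeros(channels, dtype=np.float32)
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)
        self.eps = eps
        self.momentum = momentum
        self._cache = None

    def params(self):
        return [(self.gamma, self.dgamma), (self.beta, self.dbeta)]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean[...] = (
                (1 - self.momentum) * self.running_mean + self.momentum * mean
            )
            self.running_var[...] = (
                (1 - self.momentum) * self.running_var + self.momentum * var
            )
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv_std[None, :, None, None]
        if train:
            self._cache = (xhat, inv_std, x.shape)
        return self.gamma[None, :, None, None] * xhat + self.beta[None, :, None, None]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xhat, inv_std, shape = self._cache
        n, c, h, w = shape
        m = n * h * w
        self.dgamma[...] = (dout * xhat).sum(axis=(0, 2, 3))
        self.dbeta[...] = dout.sum(axis=(0, 2, 3))
        dxhat = dout * self.gamma[None, :, None, None]
        s1 = dxhat.sum(axis=(0, 2, 3))[None, :, None, None]
        s2 = (dxhat * xhat).sum(axis=(0, 2, 3))[None, :, None, None]
        dx = (inv_std[None, :, None, None] / m) * (m * dxhat - s1 - xhat * s2)
        self._cache = None
        return dx.astype(dout.dtype)


class ReLU:
    def __init__(self):
        self._mask = None

    def params(self):
        return []

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if train:
            self._mask = x > 0
        return np.maximum(x, 0)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        dx = dout * self._mask
        self._mask = None
        return dx


class MaxPool2d:
    """2x2 max pooling with stride 2; odd trailing rows/columns are dropped."""

    def __init__(self):
        self._cache = None

    def params(self):
        return []

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        n, c, h, w = x.shape
        h2, w2 = h // 2, w // 2
        # (n, c, h2, w2, 4): the 4 pixels of each 2x2 block
        blocks = (
            x[:, :, : 2 * h2, : 2 * w2]
            .reshape(n, c, h2, 2, w2, 2)
            .transpose(0, 1, 2, 4, 3, 5)
            .reshape(n, c, h2, w2, 4)
        )
        arg = blocks.argmax(axis=-1)
        out = np.take_along_axis(blocks, arg[..., None], axis=-1)[..., 0]
        if train:
            self._cache = (arg, x.shape)
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        arg, xshape = self._cache
        n, c, h, w = xshape
        h2, w2 = h // 2, w // 2
        dblocks = np.zeros((n, c, h2, w2, 4), dtype=np.float32)
        np.put_along_axis(dblocks, arg[..., None], dout[..., None], axis=-1)
        dx = np.zeros(xshape, dtype=np.float32)
        dx[:, :, : 2 * h2, : 2 * w2] = (
            dblocks.reshape(n, c, h2, w2, 2, 2)
            .transpose(0, 1, 2, 4, 3, 5)
            .reshape(n, c, 2 * h2, 2 * w2)
        )
        self._cache = None
        return dx


class Flatten:
    def __init__(self):
        self._shape = None

    def params(self):
        return []

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if train:
            self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout.reshape(self._shape)


class Linear:
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator):
        std = np.sqrt(2.0 / in_features)
        self.weight = rng.normal(0.0, std, (out_features, in_features)).astype(
            np.float32
        )
        self.bias = np.zeros(out_features, dtype=np.float32)
        self.dweight = np.zeros_like(self.weight)
        self.dbias = np.zeros_like(self.bias)
        self._x = None

    def params(self):
        return [(self.weight, self.dweight), (self.bias, self.dbias)]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if train:
            self._x = x
        return x @ self.weight.T + self.bias

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.dweight[...] = dout.T @ self._x
        self.dbias[...] = dout.sum(axis=0)
        dx = dout @ self.weight
        self._x = None
        return dx


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy_loss(logits: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross-entropy on softmax outputs and its logit gradient."""
    n = len(y)
    p = softmax(logits)
    loss = float(-np.log(np.maximum(p[np.arange(n), y], 1e-12)).mean())
    dlogits = p.copy()
    dlogits[np.arange(n), y] -= 1.0
    return loss, (dlogits / n).astype(np.float32)


def mse_softmax_loss(logits: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean squared error between softmax outputs and one-hot targets.

    The gradient goes through the softmax Jacobian:
    dL/dz = (2/(N*K)) * p * ((p - t) - sum_j (p_j - t_j) p_j).
    """
    n, k = logits.shape
    p = softmax(logits)
    t = np.zeros_like(p)
    t[np.arange(n), y] = 1.0
    diff = p - t
    loss = float((diff**2).mean())
    inner = diff - (diff * p).sum(axis=1, keepdims=True)
    dlogits = (2.0 / (n * k)) * p * inner
    return loss, dlogits.astype(np.float32)
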