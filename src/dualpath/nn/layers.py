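"""Minimal reverse-mode layers over numpy arrays.

Each layer caches what its backward pass needs, accumulates parameter
gradients in ``grads`` and returns the gradient with respect to its input,
which is what lets attribution methods differentiate the network output
with respect to the BOLD input itself.
All arithmetic is float32 for speed; shapes follow the (batch, channels,
time) convention of temporal convolution stacks.
"""

from __future__ import annotations

import numpy as np

DTYPE = np.float32


class Layer:
    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, train: bool = False,
                rng: np.random.Generator | None = None) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def zero_grad(self) -> None:
        for k in self.params:
            self.grads[k] = np.zeros_like(self.params[k])


class Conv1d(Layer):
    """Temporal convolution, stride 1, symmetric zero padding (T preserved)."""

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator):
        super().__init__()
        if kernel % 2 == 0:
            raise ValueError("odd kernel sizes only (symmetric padding)")
        scale = np.sqrt(2.0 / (c_in * kernel))
        self.params["W"] = rng.normal(0, scale, size=(c_out, c_in, kernel)).astype(DTYPE)
        self.params["b"] = np.zeros(c_out, dtype=DTYPE)
        self.kernel = kernel
        self.c_in, self.c_out = c_in, c_out
        self.zero_grad()

    def forward(self, x, train=False, rng=None):
        B, C, T = x.shape
        k, pad = self.kernel, self.kernel // 2
        xp = np.zeros((B, C, T + 2 * pad), dtype=DTYPE)
        xp[:, :, pad:pad + T] = x
        # cols[b, c, j, t] = xp[b, c, t + j]
        cols = np.stack([xp[:, :, j:j + T] for j in range(k)], axis=2)
        self._cols = cols.reshape(B, C * k, T)
        Wm = self.params["W"].reshape(self.c_out, C * k)
        y = np.matmul(Wm, self._cols) + self.params["b"][None, :, None]
        self._in_shape = (B, C, T)
        return y.astype(DTYPE)

    def backward(self, dout):
        B, C, T = self._in_shape
        k, pad = self.kernel, self.kernel // 2
        Wm = self.params["W"].reshape(self.c_out, C * k)
        self.grads["W"] += np.matmul(dout, self._cols.transpose(0, 2, 1)) \
            .sum(axis=0).reshape(self.params["W"].shape)
        self.grads["b"] += dout.sum(axis=(0, 2))
        dcols = np.matmul(Wm.T, dout).reshape(B, C, k, T)
        dxp = np.zeros((B, C, T + 2 * pad), dtype=DTYPE)
        for j in range(k):
            dxp[:, :, j:j + T] += dcols[:, :, j, :]
        return dxp[:, :, pad:pad + T]


class BatchNorm1d(Layer):
    """Per-channel normalization over batch and time; running stats in eval."""

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.params["gamma"] = np.ones(channels, dtype=DTYPE)
        self.params["beta"] = np.zeros(channels, dtype=DTYPE)
        self.running_mean = np.zeros(channels, dtype=DTYPE)
        self.running_var = np.ones(channels, dtype=DTYPE)
        self.momentum, self.eps = momentum, eps
        self.zero_grad()

    def forward(self, x, train=False, rng=None):
        if train:
            mean = x.mean(axis=(0, 2))
            var = x.var(axis=(0, 2))
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mean).astype(DTYPE)
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var).astype(DTYPE)
        else:
            mean, var = self.running_mean, self.running_var
        self._istd = (1.0 / np.sqrt(var + self.eps)).astype(DTYPE)
        self._xhat = ((x - mean[None, :, None]) * self._istd[None, :, None]).astype(DTYPE)
        self._train = train
        return self.params["gamma"][None, :, None] * self._xhat \
            + self.params["beta"][None, :, None]

    def backward(self, dout):
        self.grads["gamma"] += (dout * self._xhat).sum(axis=(0, 2))
        self.grads["beta"] += dout.sum(axis=(0, 2))
        dxhat = dout * self.params["gamma"][None, :, None]
        if not self._train:
            return dxhat * self._istd[None, :, None]
        B, C, T = dout.shape
        m = B * T
        s1 = dxhat.sum(axis=(0, 2))[None, :, None]
        s2 = (dxhat * self._xhat).sum(axis=(0, 2))[None, :, None]
        return (self._istd[None, :, None] / m) * (m * dxhat - s1 - self._xhat * s2)


class ReLU(Layer):
    def forward(self, x, train=False, rng=None):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class Dropout(Layer):
    """Inverted dropout; identity in eval mode."""

    def __init__(self, p: float):
        super().__init__()
        if not 0 <= p < 1:
            raise ValueError("dropout p must be in [0, 1)")
        self.p = p

    def forward(self, x, train=False, rng=None):
        if not train or self.p == 0:
            self._mask = None
            return x
        if rng is None:
            raise ValueError("training-mode dropout needs an rng")
        self._mask = (rng.random(x.shape) >= self.p).astype(DTYPE) / (1 - self.p)
        return x * self._mask

    def backward(self, dout):
        return dout if self._mask is None else dout * self._mask


class Linear(Layer):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        super().__init__()
        scale = np.sqrt(2.0 / d_in)
        self.params["W"] = rng.normal(0, scale, size=(d_out, d_in)).astype(DTYPE)
        self.params["b"] = np.zeros(d_out, dtype=DTYPE)
        self.zero_grad()

    def forward(self, x, train=False, rng=None):
        self._x = x
        return x @ self.params["W"].T + self.params["b"]

    def backward(self, dout):
        self.grads["W"] += dout.T @ self._x
        self.grads["b"] += dout.sum(axis=0)
        return dout @ self.params["W"]


class GatedAttention(Layer):
    """Tanh-gated instance attention over the time axis.

    Score for timepoint t is u . tanh(V h_t); a softmax over t yields
    nonnegative weights summing to one, and the bag representation is the
    attention-weighted sum of the feature columns.
    """

    def __init__(self, channels: int, hidden: int, rng: np.random.Generator):
        super().__init__()
        self.params["V"] = rng.normal(0, np.sqrt(1.0 / channels),
                                      size=(hidden, channels)).astype(DTYPE)
        self.params["u"] = rng.normal(0, np.sqrt(1.0 / hidden), size=hidden).astype(DTYPE)
        self.zero_grad()

    def forward(self, h, train=False, rng=None):
        # h: (B, C, T) -> bag (B, C), attention (B, T)
        pre = np.einsum("hc,bct->bht", self.params["V"], h)
        self._th = np.tanh(pre)
        scores = np.einsum("h,bht->bt", self.params["u"], self._th)
        scores = scores - scores.max(axis=1, keepdims=True)
        ex = np.exp(scores)
        self._a = (ex / ex.sum(axis=1, keepdims=True)).astype(DTYPE)
        self._h = h
        bag = np.einsum("bt,bct->bc", self._a, h)
        return bag.astype(DTYPE), self._a

    def backward(self, dbag):
        a, h, th, u, V = self._a, self._h, self._th, self.params["u"], self.params["V"]
        dh = a[:, None, :] * dbag[:, :, None]
        da = np.einsum("bc,bct->bt", dbag, h)
        ds = a * (da - (da * a).sum(axis=1, keepdims=True))
        self.grads["u"] += np.einsum("bt,bht->h", ds, th)
        dpre = (u[None, :, None] * ds[:, None, :]) * (1.0 - th ** 2)
        self.grads["V"] += np.einsum("bht,bct->hc", dpre, h)
        dh += np.einsum("hc,bht->bct", V, dpre)
        return dh.astype(DTYPE)


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy(logits: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross-entropy over the batch and its gradient w.r.t. logits."""
    B = logits.shape[0]
    p = softmax(logits.astype(np.float64))
    ll = -np.log(np.clip(p[np.arange(B), labels], 1e-12, None))
    dlogits = p.copy()
    dlogits[np.arange(B), labels] -= 1.0
    return float(ll.mean()), (dlogits / B).astype(DTYPE)
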