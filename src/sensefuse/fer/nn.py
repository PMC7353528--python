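"""Minimal neural-network building blocks in numpy.

Only what the two-stage emotion classifier needs: same-padded 3x3
convolutions (im2col + BLAS matmul), 2x2 max pooling, dense layers, ReLU,
inverted dropout, a fused softmax/cross-entropy head and Adam.  Forward
and backward passes are exact analytic gradients; float32 throughout.
Weight initialization and dropout are driven by explicit generators so
training is bit-reproducible under a fixed seed.
"""

from __future__ import annotations

import numpy as np

DTYPE = np.float32


def _he_init(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(DTYPE)


class Layer:
    trainable: bool = False

    def forward(self, x, train=False, rng=None):
        raise NotImplementedError

    def backward(self, grad):
        raise NotImplementedError

    def params_grads(self):
        return []


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(N, C, H, W) -> (N*H*W, C*k*k) for stride-1 same-padded k x k conv."""
    p = k // 2
    xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
    win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
    # win: (N, C, H, W, k, k) -> (N, H, W, C, k, k)
    n, c, h, w = x.shape
    return win.transpose(0, 2, 3, 1, 4, 5).reshape(n * h * w, c * k * k)


class Conv2D(Layer):
    """Stride-1, same-padded square convolution."""

    trainable = True

    def __init__(self, in_channels: int, out_channels: int, kernel: int, rng: np.random.Generator):
        self.k = kernel
        self.in_c, self.out_c = in_channels, out_channels
        self.W = _he_init(rng, (out_channels, in_channels * kernel * kernel),
                          in_channels * kernel * kernel)
        self.b = np.zeros(out_channels, dtype=DTYPE)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def forward(self, x, train=False, rng=None):
        self._shape = x.shape
        self._cols = _im2col(x, self.k)
        n, _, h, w = x.shape
        out = self._cols @ self.W.T + self.b
        return out.reshape(n, h, w, self.out_c).transpose(0, 3, 1, 2)

    def backward(self, grad):
        n, _, h, w = self._shape
        g = grad.transpose(0, 2, 3, 1).reshape(n * h * w, self.out_c)
        self.dW[:] = g.T @ self._cols
        self.db[:] = g.sum(axis=0)
        # dx = full correlation of grad with flipped kernels
        W_t = (self.W.reshape(self.out_c, self.in_c, self.k, self.k)[:, :, ::-1, ::-1]
               .transpose(1, 0, 2, 3).reshape(self.in_c, self.out_c * self.k * self.k))
        g_img = grad.astype(DTYPE, copy=False)
        cols_g = _im2col(g_img, self.k)
        dx = cols_g @ W_t.T
        return dx.reshape(n, h, w, self.in_c).transpose(0, 3, 1, 2)

    def params_grads(self):
        return [(self.W, self.dW), (self.b, self.db)]


class MaxPool2x2(Layer):
    def forward(self, x, train=False, rng=None):
        n, c, h, w = x.shape
        assert h % 2 == 0 and w % 2 == 0, "max pooling expects even spatial dims"
        self._x = x
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2)
        out = xr.max(axis=(3, 5))
        self._out = out
        return out

    def backward(self, grad):
        n, c, h, w = self._x.shape
        up = np.repeat(np.repeat(self._out, 2, axis=2), 2, axis=3)
        mask = (self._x == up)
        counts = mask.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))
        gup = np.repeat(np.repeat(grad / counts, 2, axis=2), 2, axis=3)
        return (gup * mask).astype(DTYPE, copy=False)


class Flatten(Layer):
    def forward(self, x, train=False, rng=None):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class Dense(Layer):
    trainable = True

    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator):
        self.W = _he_init(rng, (in_dim, out_dim), in_dim)
        self.b = np.zeros(out_dim, dtype=DTYPE)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def forward(self, x, train=False, rng=None):
        if x.shape[1] != self.W.shape[0]:
            raise ValueError(f"dense layer expects input width {self.W.shape[0]}, got {x.shape[1]}")
        self._x = x
        return x @ self.W + self.b

    def backward(self, grad):
        self.dW[:] = self._x.T @ grad
        self.db[:] = grad.sum(axis=0)
        return grad @ self.W.T

    def params_grads(self):
        return [(self.W, self.dW), (self.b, self.db)]


class ReLU(Layer):
    def forward(self, x, train=False, rng=None):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask


class Dropout(Layer):
    """Inverted dropout; identity at inference time."""

    def __init__(self, rate: float):
        if not 0 <= rate < 1:
            raise ValueError("dropout rate must lie in [0, 1)")
        self.rate = rate

    def forward(self, x, train=False, rng=None):
        if not train or self.rate == 0:
            self._mask = None
            return x
        assert rng is not None, "training-mode dropout needs a generator"
        self._mask = (rng.random(x.shape) >= self.rate).astype(DTYPE) / (1 - self.rate)
        return x * self._mask

    def backward(self, grad):
        return grad if self._mask is None else grad * self._mask


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy(probs: np.ndarray, labels: np.ndarray) -> float:
    n = labels.size
    return float(-np.log(np.clip(probs[np.arange(n), labels], 1e-12, None)).mean())


class Sequential:
    """A feed-forward stack ending in a softmax classification head."""

    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def logits(self, x, train=False, rng=None):
        out = np.asarray(x, dtype=DTYPE)
        for layer in self.layers:
            out = layer.forward(out, train=train, rng=rng)
        return out

    def predict_proba(self, x, batch_size: int = 256) -> np.ndarray:
        x = np.asarray(x, dtype=DTYPE)
        chunks = [softmax(self.logits(x[i:i + batch_size]))
                  for i in range(0, x.shape[0], batch_size)]
        return np.concatenate(chunks) if chunks else np.empty((0, 0))

    def train_step(self, x, labels, optimizer, rng) -> tuple[float, float]:
        """One minibatch update; returns (loss, accuracy)."""
        probs = softmax(self.logits(x, train=True, rng=rng))
        loss = cross_entropy(probs, labels)
        acc = float((probs.argmax(axis=1) == labels).mean())
        n = labels.size
        grad = probs.astype(DTYPE)
        grad[np.arange(n), labels] -= 1
        grad /= DTYPE(n)
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        optimizer.step(self)
        return loss, acc

    def params_grads(self):
        out = []
        for layer in self.layers:
            out.extend(layer.params_grads())
        return out

    def state(self) -> list[np.ndarray]:
        return [p for p, _ in self.params_grads()]

    def load_state(self, arrays: list[np.ndarray]) -> None:
        params = self.params_grads()
        if len(arrays) != len(params):
            raise ValueError("state does not match the architecture")
        for (p, _), a in zip(params, arrays):
            if p.shape != a.shape:
                raise ValueError(f"shape mismatch {p.shape} vs {a.shape}")
            p[:] = a.astype(DTYPE)


class Adam:
    def __init__(self, lr: float = 1e-3, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self._m: dict[int, np.ndarray] = {}
        self._v: dict[int, np.ndarray] = {}

    def step(self, model: Sequential) -> None:
        self.t += 1
        for p, g in model.params_grads():
            key = id(p)
            m = self._m.setdefault(key, np.zeros_like(p))
            v = self._v.setdefault(key, np.zeros_like(p))
            m[:] = self.b1 * m + (1 - self.b1) * g
            v[:] = self.b2 * v + (1 - self.b2) * g * g
            mhat = m / (1 - self.b1 ** self.t)
            vhat = v / (1 - self.b2 ** self.t)
            p -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(DTYPE)
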