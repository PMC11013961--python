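"""A small NumPy neural-network engine for the patch-count regressor.

Implements exactly the pieces the counting network needs — 3×3 same-padded
convolutions (im2col + GEMM), batch normalization, 2×2 max pooling, inverted
dropout, a linear head, and Adam — in float32, NCHW layout. Everything is
driven by explicit ``numpy.random.Generator`` objects so training is
reproducible from a single seed.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Conv2d",
    "BatchNorm2d",
    "ReLU",
    "MaxPool2",
    "Dropout",
    "Flatten",
    "Linear",
    "Sequential",
    "Adam",
]


class Layer:
    """Base layer: forward/backward plus named parameter and gradient dicts."""

    params: dict[str, np.ndarray]
    grads: dict[str, np.ndarray]

    def __init__(self) -> None:
        self.params = {}
        self.grads = {}

    def forward(self, x: np.ndarray, train: bool, rng: np.random.Generator | None):
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    # extra (non-trainable) state such as batch-norm running moments
    def state(self) -> dict[str, np.ndarray]:
        return {}

    def load_state(self, state: dict[str, np.ndarray]) -> None:
        pass


class Conv2d(Layer):
    """3×3 convolution with padding 1 (shape-preserving), He-initialized."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator, k: int = 3):
        super().__init__()
        self.cin, self.cout, self.k = cin, cout, k
        fan_in = cin * k * k
        self.params["W"] = rng.normal(0.0, np.sqrt(2.0 / fan_in), (cout, fan_in)).astype(
            np.float32
        )
        self.params["b"] = np.zeros(cout, dtype=np.float32)

    def forward(self, x, train, rng=None):
        n, c, h, w = x.shape
        k = self.k
        p = k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        cols = sliding_window_view(xp, (k, k), axis=(2, 3))  # N,C,H,W,k,k
        cols = np.ascontiguousarray(cols.transpose(0, 2, 3, 1, 4, 5)).reshape(
            n * h * w, c * k * k
        )
        out = cols @ self.params["W"].T + self.params["b"]
        self._cache = (x.shape, cols)
        return out.reshape(n, h, w, self.cout).transpose(0, 3, 1, 2)

    def backward(self, dout):
        (n, c, h, w), cols = self._cache
        k, p = self.k, self.k // 2
        d = np.ascontiguousarray(dout.transpose(0, 2, 3, 1)).reshape(n * h * w, self.cout)
        self.grads["W"] = d.T @ cols
        self.grads["b"] = d.sum(axis=0)
        dcols = (d @ self.params["W"]).reshape(n, h, w, c, k, k)
        dxp = np.zeros((n, c, h + 2 * p, w + 2 * p), dtype=np.float32)
        for i in range(k):
            for j in range(k):
                dxp[:, :, i : i + h, j : j + w] += dcols[:, :, :, :, i, j].transpose(
                    0, 3, 1, 2
                )
        self._cache = None
        return dxp[:, :, p : p + h, p : p + w]


class BatchNorm2d(Layer):
    """Per-channel batch normalization with running moments for inference."""

    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.momentum, self.eps = momentum, eps
        self.params["gamma"] = np.ones(c, dtype=np.float32)
        self.params["beta"] = np.zeros(c, dtype=np.float32)
        self.running_mean = np.zeros(c, dtype=np.float32)
        self.running_var = np.ones(c, dtype=np.float32)

    def forward(self, x, train, rng=None):
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = (
                (1 - self.momentum) * self.running_mean + self.momentum * mean
            ).astype(np.float32)
            self.running_var = (
                (1 - self.momentum) * self.running_var + self.momentum * var
            ).astype(np.float32)
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv[None, :, None, None]
        if train:
            self._cache = (xhat, inv, x.shape)
        return self.params["gamma"][None, :, None, None] * xhat + self.params["beta"][
            None, :, None, None
        ]

    def backward(self, dout):
        xhat, inv, shape = self._cache
        n, c, h, w = shape
        m = n * h * w
        self.grads["gamma"] = (dout * xhat).sum(axis=(0, 2, 3))
        self.grads["beta"] = dout.sum(axis=(0, 2, 3))
        g = self.params["gamma"][None, :, None, None]
        dxhat = dout * g
        # standard batch-norm backward, reduced over the per-channel batch
        dx = (
            dxhat
            - dxhat.mean(axis=(0, 2, 3), keepdims=True)
            - xhat * (dxhat * xhat).mean(axis=(0, 2, 3), keepdims=True)
        ) * inv[None, :, None, None]
        self._cache = None
        return dx.astype(np.float32)

    def state(self):
        return {"running_mean": self.running_mean, "running_var": self.running_var}

    def load_state(self, state):
        self.running_mean = state["running_mean"].astype(np.float32)
        self.running_var = state["running_var"].astype(np.float32)


class ReLU(Layer):
    def forward(self, x, train, rng=None):
        mask = x > 0
        if train:
            self._cache = mask
        return x * mask

    def backward(self, dout):
        dx = dout * self._cache
        self._cache = None
        return dx


class MaxPool2(Layer):
    """2×2 max pooling, stride 2; requires even spatial dimensions."""

    def forward(self, x, train, rng=None):
        n, c, h, w = x.shape
        xr = (
            x.reshape(n, c, h // 2, 2, w // 2, 2)
            .transpose(0, 1, 2, 4, 3, 5)
            .reshape(n, c, h // 2, w // 2, 4)
        )
        idx = xr.argmax(axis=-1)
        out = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]
        if train:
            self._cache = (idx, x.shape)
        return out

    def backward(self, dout):
        idx, (n, c, h, w) = self._cache
        dxr = np.zeros((n, c, h // 2, w // 2, 4), dtype=np.float32)
        np.put_along_axis(dxr, idx[..., None], dout[..., None], axis=-1)
        dx = (
            dxr.reshape(n, c, h // 2, w // 2, 2, 2)
            .transpose(0, 1, 2, 4, 3, 5)
            .reshape(n, c, h, w)
        )
        self._cache = None
        return dx


class Dropout(Layer):
    """Inverted dropout; identity at inference."""

    def __init__(self, p: float):
        super().__init__()
        self.p = p

    def forward(self, x, train, rng=None):
        if not train or self.p <= 0:
            return x
        mask = (rng.random(x.shape) >= self.p).astype(np.float32) / (1.0 - self.p)
        self._cache = mask
        return x * mask

    def backward(self, dout):
        dx = dout * self._cache
        self._cache = None
        return dx


class Flatten(Layer):
    def forward(self, x, train, rng=None):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._shape)


class Linear(Layer):
    def __init__(self, fin: int, fout: int, rng: np.random.Generator):
        super().__init__()
        self.params["W"] = rng.normal(0.0, np.sqrt(2.0 / fin), (fout, fin)).astype(
            np.float32
        )
        self.params["b"] = np.zeros(fout, dtype=np.float32)

    def forward(self, x, train, rng=None):
        if train:
            self._cache = x
        return x @ self.params["W"].T + self.params["b"]

    def backward(self, dout):
        x = self._cache
        self.grads["W"] = dout.T @ x
        self.grads["b"] = dout.sum(axis=0)
        self._cache = None
        return dout @ self.params["W"]


class Sequential:
    """A feed-forward stack with flat parameter access for the optimizer."""

    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x: np.ndarray, train: bool, rng: np.random.Generator | None = None):
        for layer in self.layers:
            x = layer.forward(x, train, rng)
        return x

    def backward(self, dout: np.ndarray) -> None:
        for layer in reversed(self.layers):
            dout = layer.backward(dout)

    def parameters(self) -> list[tuple[dict, str]]:
        return [(ly.params, name) for ly in self.layers for name in ly.params]

    def gradients(self) -> list[np.ndarray]:
        return [ly.grads[name] for ly in self.layers for name in ly.params]

    def get_state(self) -> list[np.ndarray]:
        """Snapshot of all trainable parameters and auxiliary state (copies)."""
        out = []
        for ly in self.layers:
            for name in ly.params:
                out.append(ly.params[name].copy())
            for name in sorted(ly.state()):
                out.append(ly.state()[name].copy())
        return out

    def set_state(self, state: list[np.ndarray]) -> None:
        i = 0
        for ly in self.layers:
            for name in ly.params:
                ly.params[name] = state[i].copy()
                i += 1
            names = sorted(ly.state())
            if names:
                ly.load_state({n: state[i + j] for j, n in enumerate(names)})
                i += len(names)


class Adam:
    """Adam optimizer over a :class:`Sequential`'s parameters."""

    def __init__(self, model: Sequential, lr: float, betas=(0.9, 0.999), eps=1e-8):
        self.model = model
        self.lr, self.b1, self.b2, self.eps = lr, betas[0], betas[1], eps
        self.t = 0
        self.m = [np.zeros_like(p[name]) for p, name in model.parameters()]
        self.v = [np.zeros_like(p[name]) for p, name in model.parameters()]

    def step(self) -> None:
        self.t += 1
        grads = self.model.gradients()
        for i, (params, name) in enumerate(self.model.parameters()):
            g = grads[i]
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            params[name] = (
                params[name] - self.lr * mhat / (np.sqrt(vhat) + self.eps)
            ).astype(np.float32)
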