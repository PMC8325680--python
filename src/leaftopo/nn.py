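"""Minimal reverse-mode layer stack used by the fusion classifier.

Implements exactly the layer types the topological branches and fusion
head need -- the trainable PD-vectorization input layer, 1-D convolution,
max-pooling along the filter dimension, dropout, batch normalisation,
ReLU, dense -- with hand-written gradients, an RMSProp optimizer, and a
reduce-on-plateau learning-rate schedule.  Arrays are float32 throughout.
"""

from __future__ import annotations

import numpy as np

F32 = np.float32


class Layer:
    """Base layer; parameters and gradients are parallel dicts."""

    def params(self) -> dict:
        return {}

    def grads(self) -> dict:
        return {}

    def constrain(self) -> None:
        """Project parameters back into their valid set after a step."""

    def forward(self, x, train: bool):  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, dy):  # pragma: no cover - abstract
        raise NotImplementedError


class Vectorization(Layer):
    """Trainable structure-element input layer.

    Input: points (B, C, N, 2) of (birth, lifetime) and mask (B, C, N);
    output (B, C, M) with out[b,c,m] = sum over real points of
    exp(-(s0^2 (birth-mu0)^2 + s1^2 (life-mu1)^2)).
    """

    MIN_SHARPNESS = 1e-3

    def __init__(self, n_channels: int, centers: np.ndarray,
                 sharpness: np.ndarray):
        # one set of elements per channel
        self.mu = np.tile(centers.astype(F32)[None], (n_channels, 1, 1))
        self.s = np.tile(sharpness.astype(F32)[None], (n_channels, 1, 1))

    def params(self):
        return {"mu": self.mu, "s": self.s}

    def grads(self):
        return {"mu": self.dmu, "s": self.ds}

    def constrain(self):
        np.maximum(self.s, self.MIN_SHARPNESS, out=self.s)

    def forward(self, x, train):
        pts, mask = x
        if pts.shape[1] != self.mu.shape[0]:
            raise ValueError(
                f"expected {self.mu.shape[0]}-channel point sets, "
                f"got {pts.shape[1]}")
        pts = pts.astype(F32)
        mask = mask.astype(F32)
        # (B, C, N, M) differences
        d0 = pts[..., 0:1] - self.mu[None, :, None, :, 0]
        d1 = pts[..., 1:2] - self.mu[None, :, None, :, 1]
        s0 = self.s[None, :, None, :, 0]
        s1 = self.s[None, :, None, :, 1]
        resp = np.exp(-((s0 * d0) ** 2 + (s1 * d1) ** 2)) * mask[..., None]
        self._cache = (d0, d1, resp)
        return resp.sum(axis=2)

    def backward(self, dy):
        d0, d1, resp = self._cache
        s0 = self.s[None, :, None, :, 0]
        s1 = self.s[None, :, None, :, 1]
        g = dy[:, :, None, :] * resp  # (B, C, N, M)
        self.dmu = np.stack([
            (g * 2.0 * s0 ** 2 * d0).sum(axis=(0, 2)),
            (g * 2.0 * s1 ** 2 * d1).sum(axis=(0, 2)),
        ], axis=-1)
        self.ds = np.stack([
            (g * -2.0 * s0 * d0 ** 2).sum(axis=(0, 2)),
            (g * -2.0 * s1 * d1 ** 2).sum(axis=(0, 2)),
        ], axis=-1)
        self._cache = None
        return None  # input layer


class Conv1D(Layer):
    """Same-padded 1-D convolution; accepts (B, L) or (B, C, L)."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int, rng):
        scale = np.sqrt(2.0 / (in_ch * kernel))
        self.w = (rng.standard_normal((out_ch, in_ch, kernel)) * scale).astype(F32)
        self.b = np.zeros(out_ch, F32)
        self.kernel = kernel
        self.in_ch = in_ch

    def params(self):
        return {"w": self.w, "b": self.b}

    def grads(self):
        return {"w": self.dw, "b": self.db}

    @staticmethod
    def _shifted(xp, k, L):
        # (B, C, K, L) view of the padded signal
        return np.stack([xp[:, :, i:i + L] for i in range(k)], axis=2)

    def forward(self, x, train):
        self._expanded = x.ndim == 2
        if self._expanded:
            x = x[:, None, :]
        if x.shape[1] != self.in_ch:
            raise ValueError(
                f"expected {self.in_ch}-channel input, got {x.shape[1]}")
        B, C, L = x.shape
        pad = self.kernel // 2
        xp = np.pad(x, ((0, 0), (0, 0), (pad, pad)))
        xs = self._shifted(xp, self.kernel, L)
        self._cache = (xs, L)
        return np.einsum("bckl,fck->bfl", xs, self.w) + self.b[None, :, None]

    def backward(self, dy):
        xs, L = self._cache
        self.dw = np.einsum("bckl,bfl->fck", xs, dy)
        self.db = dy.sum(axis=(0, 2))
        pad = self.kernel // 2
        B, C = xs.shape[0], xs.shape[1]
        dxp = np.zeros((B, C, L + 2 * pad), F32)
        for i in range(self.kernel):
            dxp[:, :, i:i + L] += np.einsum("bfl,fc->bcl", dy, self.w[:, :, i])
        dx = dxp[:, :, pad:pad + L]
        self._cache = None
        if self._expanded:
            dx = dx[:, 0, :]
        return dx


class FilterMaxPool(Layer):
    """Max over the filter dimension: (B, F, L) -> (B, L)."""

    def forward(self, x, train):
        self._arg = x.argmax(axis=1)
        self._shape = x.shape
        return x.max(axis=1)

    def backward(self, dy):
        B, F, L = self._shape
        dx = np.zeros((B, F, L), F32)
        bi, li = np.meshgrid(np.arange(B), np.arange(L), indexing="ij")
        dx[bi, self._arg, li] = dy
        return dx


class Dropout(Layer):
    def __init__(self, rate: float, rng):
        self.rate = rate
        self.rng = rng

    def forward(self, x, train):
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.rate).astype(F32) / \
            F32(1.0 - self.rate)
        return x * self._mask

    def backward(self, dy):
        if self._mask is None:
            return dy
        return dy * self._mask


class BatchNorm(Layer):
    """Per-feature normalisation over the batch axis for (B, L) input."""

    def __init__(self, n_features: int, momentum: float = 0.9,
                 eps: float = 1e-5):
        self.gamma = np.ones(n_features, F32)
        self.beta = np.zeros(n_features, F32)
        self.run_mean = np.zeros(n_features, F32)
        self.run_var = np.ones(n_features, F32)
        self.momentum = momentum
        self.eps = eps

    def params(self):
        return {"gamma": self.gamma, "beta": self.beta}

    def grads(self):
        return {"gamma": self.dgamma, "beta": self.dbeta}

    def forward(self, x, train):
        if train:
            mean = x.mean(axis=0)
            var = x.var(axis=0)
            self.run_mean = self.momentum * self.run_mean + \
                (1 - self.momentum) * mean
            self.run_var = self.momentum * self.run_var + \
                (1 - self.momentum) * var
        else:
            mean, var = self.run_mean, self.run_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * inv
        self._cache = (xhat, inv, train)
        return self.gamma * xhat + self.beta

    def backward(self, dy):
        xhat, inv, trained = self._cache
        self.dgamma = (dy * xhat).sum(axis=0)
        self.dbeta = dy.sum(axis=0)
        if not trained:
            return dy * self.gamma * inv
        B = dy.shape[0]
        dxhat = dy * self.gamma
        dx = (inv / B) * (B * dxhat - dxhat.sum(axis=0) -
                          xhat * (dxhat * xhat).sum(axis=0))
        self._cache = None
        return dx.astype(F32)


class ReLU(Layer):
    def forward(self, x, train):
        self._pos = x > 0
        return x * self._pos

    def backward(self, dy):
        return dy * self._pos


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng):
        scale = np.sqrt(2.0 / n_in)
        self.w = (rng.standard_normal((n_in, n_out)) * scale).astype(F32)
        self.b = np.zeros(n_out, F32)

    def params(self):
        return {"w": self.w, "b": self.b}

    def grads(self):
        return {"w": self.dw, "b": self.db}

    def forward(self, x, train):
        self._x = x
        return x @ self.w + self.b

    def backward(self, dy):
        self.dw = self._x.T @ dy
        self.db = dy.sum(axis=0)
        dx = dy @ self.w.T
        self._x = None
        return dx


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x, train):
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, dy):
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy

    def named_params(self, prefix=""):
        for i, layer in enumerate(self.layers):
            for k, v in layer.params().items():
                yield f"{prefix}{i}.{type(layer).__name__}.{k}", layer, k, v


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy(probs: np.ndarray, labels: np.ndarray) -> float:
    eps = 1e-12
    return float(-np.log(probs[np.arange(len(labels)), labels] + eps).mean())


class RMSProp:
    """RMSProp with reduce-on-plateau halving handled by the caller."""

    def __init__(self, lr: float = 1e-3, rho: float = 0.9, eps: float = 1e-7):
        self.lr = lr
        self.rho = rho
        self.eps = eps
        self.state: dict[int, dict[str, np.ndarray]] = {}

    def step(self, layers: list[Layer]) -> None:
        for layer in layers:
            ps = layer.params()
            if not ps:
                continue
            gs = layer.grads()
            st = self.state.setdefault(id(layer), {})
            for name, p in ps.items():
                g = gs[name].astype(F32)
                sq = st.setdefault(name, np.zeros_like(p))
                sq *= self.rho
                sq += (1 - self.rho) * g * g
                p -= (self.lr * g / (np.sqrt(sq) + self.eps)).astype(F32)
            layer.constrain()


def collect_layers(root) -> list[Layer]:
    """Flatten Sequentials into a layer list."""
    out = []
    stack = [root]
    while stack:
        item = stack.pop()
        if isinstance(item, Sequential):
            stack.extend(reversed(item.layers))
        else:
            out.append(item)
    return out


def get_param_state(layers: list[Layer]) -> list[dict]:
    state = []
    for layer in layers:
        d = {k: v.copy() for k, v in layer.params().items()}
        if isinstance(layer, BatchNorm):
            d["run_mean"] = layer.run_mean.copy()
            d["run_var"] = layer.run_var.copy()
        state.append(d)
    return state


def set_param_state(layers: list[Layer], state: list[dict]) -> None:
    for layer, d in zip(layers, state):
        for k, v in layer.params().items():
            v[...] = d[k]
        if isinstance(layer, BatchNorm):
            layer.run_mean[...] = d["run_mean"]
            layer.run_var[...] = d["run_var"]
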