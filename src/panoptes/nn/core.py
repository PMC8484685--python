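"""Minimal CPU neural-network engine: layers, containers, Adam.

Implements exactly the pieces the architecture zoo needs — im2col
convolution, dense layers, ReLU, dropout (keep-probability convention),
global average pooling, channel concatenation, scaled residual connections —
each with an explicit, cached backward pass.  Arrays are (N, C, H, W)
float64; parameters live in :class:`Param` objects collected recursively
through module attributes.

A layer's ``forward`` stores whatever its ``backward`` needs; the training
loop always calls them in matched pairs.  Gradients accumulate into
``Param.grad`` and are zeroed by the optimizer step.
"""

from __future__ import annotations

import hashlib
from typing import Iterable, Optional, Sequence

import numpy as np


class Param:
    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = np.zeros_like(self.value)


class Module:
    """Base class; submodules and Params are discovered via attributes."""

    def params(self) -> list[Param]:
        out: list[Param] = []
        seen: set[int] = set()
        self._collect(out, seen)
        return out

    def _collect(self, out: list[Param], seen: set[int]) -> None:
        for v in self.__dict__.values():
            self._collect_value(v, out, seen)

    @staticmethod
    def _collect_value(v, out, seen):
        if isinstance(v, Param):
            if id(v) not in seen:
                seen.add(id(v))
                out.append(v)
        elif isinstance(v, Module):
            v._collect(out, seen)
        elif isinstance(v, (list, tuple)):
            for item in v:
                Module._collect_value(item, out, seen)

    def forward(self, x, train: bool = False):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dout):  # pragma: no cover - interface
        raise NotImplementedError

    def __call__(self, x, train: bool = False):
        return self.forward(x, train)

    # -- state ------------------------------------------------------------

    #: attribute names of non-trained state arrays (e.g. batchnorm stats)
    buffer_names: tuple = ()

    def modules(self) -> list["Module"]:
        out: list[Module] = [self]
        seen = {id(self)}
        self._walk(out, seen)
        return out

    def _walk(self, out, seen):
        for v in self.__dict__.values():
            Module._walk_value(v, out, seen)

    @staticmethod
    def _walk_value(v, out, seen):
        if isinstance(v, Module):
            if id(v) not in seen:
                seen.add(id(v))
                out.append(v)
                v._walk(out, seen)
        elif isinstance(v, (list, tuple)):
            for item in v:
                Module._walk_value(item, out, seen)

    def buffers(self) -> list[tuple["Module", str]]:
        return [(m, name) for m in self.modules() for name in m.buffer_names]

    def get_state(self) -> list[np.ndarray]:
        state = [p.value.copy() for p in self.params()]
        state.extend(np.asarray(getattr(m, n)).copy() for m, n in self.buffers())
        return state

    def set_state(self, state: Sequence[np.ndarray]) -> None:
        ps = self.params()
        bufs = self.buffers()
        if len(ps) + len(bufs) != len(state):
            raise ValueError(
                f"state has {len(state)} arrays, model has {len(ps)} params "
                f"+ {len(bufs)} buffers"
            )
        for p, v in zip(ps, state):
            if p.value.shape != v.shape:
                raise ValueError(f"shape mismatch {p.value.shape} vs {v.shape}")
            p.value = np.asarray(v, dtype=np.float64).copy()
        for (m, n), v in zip(bufs, state[len(ps) :]):
            setattr(m, n, np.asarray(v, dtype=np.float64).copy())

    def state_digest(self) -> str:
        h = hashlib.sha256()
        for a in self.get_state():
            h.update(np.ascontiguousarray(a).tobytes())
        return h.hexdigest()

    def n_params(self) -> int:
        return int(sum(p.value.size for p in self.params()))


def he_init(rng: np.random.Generator, shape: tuple, fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


class Conv2d(Module):
    """k x k convolution via im2col; integer zero padding."""

    def __init__(self, rng, c_in: int, c_out: int, k: int = 3, stride: int = 1,
                 pad: Optional[int] = None):
        self.k, self.stride = k, stride
        self.pad = k // 2 if pad is None else pad
        self.c_in, self.c_out = c_in, c_out
        self.W = Param(he_init(rng, (c_out, c_in * k * k), c_in * k * k))
        self.b = Param(np.zeros(c_out))

    def forward(self, x, train=False):
        N, C, H, W = x.shape
        k, s, p = self.k, self.stride, self.pad
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p))) if p else x
        Ho = (H + 2 * p - k) // s + 1
        Wo = (W + 2 * p - k) // s + 1
        win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
        win = win[:, :, ::s, ::s][:, :, :Ho, :Wo]
        cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(
            N * Ho * Wo, C * k * k
        )
        out = cols @ self.W.value.T + self.b.value
        self._cache = (x.shape, cols, Ho, Wo)
        return out.reshape(N, Ho, Wo, self.c_out).transpose(0, 3, 1, 2)

    def backward(self, dout):
        (N, C, H, W), cols, Ho, Wo = self._cache
        k, s, p = self.k, self.stride, self.pad
        dflat = np.ascontiguousarray(dout.transpose(0, 2, 3, 1)).reshape(-1, self.c_out)
        self.W.grad += dflat.T @ cols
        self.b.grad += dflat.sum(axis=0)
        dcols = dflat @ self.W.value
        dwin = dcols.reshape(N, Ho, Wo, C, k, k).transpose(0, 3, 1, 2, 4, 5)
        dxp = np.zeros((N, C, H + 2 * p, W + 2 * p))
        for ki in range(k):
            for kj in range(k):
                dxp[:, :, ki : ki + s * Ho : s, kj : kj + s * Wo : s] += dwin[..., ki, kj]
        self._cache = None
        return dxp[:, :, p : p + H, p : p + W] if p else dxp


class Dense(Module):
    def __init__(self, rng, d_in: int, d_out: int):
        self.W = Param(he_init(rng, (d_out, d_in), d_in))
        self.b = Param(np.zeros(d_out))

    def forward(self, x, train=False):
        self._x = x
        return x @ self.W.value.T + self.b.value

    def backward(self, dout):
        self.W.grad += dout.T @ self._x
        self.b.grad += dout.sum(axis=0)
        dx = dout @ self.W.value
        self._x = None
        return dx


class ReLU(Module):
    def forward(self, x, train=False):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        dx = dout * self._mask
        self._mask = None
        return dx


class Dropout(Module):
    """Inverted dropout with the *keep-probability* convention."""

    def __init__(self, rng: np.random.Generator, keep: float):
        if not (0 < keep <= 1):
            raise ValueError("keep probability must be in (0, 1]")
        self.keep = keep
        self.rng = rng

    def forward(self, x, train=False):
        if not train or self.keep >= 1.0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) < self.keep) / self.keep
        return x * self._mask

    def backward(self, dout):
        if self._mask is None:
            return dout
        dx = dout * self._mask
        self._mask = None
        return dx


class BatchNorm2d(Module):
    """Per-channel batch normalization over (N, H, W) with running stats."""

    buffer_names = ("running_mean", "running_var")

    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = Param(np.ones(channels))
        self.beta = Param(np.zeros(channels))
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)
        self.momentum = momentum
        self.eps = eps

    def forward(self, x, train=False):
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv[None, :, None, None]
        self._cache = (xhat, inv, train)
        return self.gamma.value[None, :, None, None] * xhat + self.beta.value[None, :, None, None]

    def backward(self, dout):
        xhat, inv, train = self._cache
        self.gamma.grad += (dout * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += dout.sum(axis=(0, 2, 3))
        dxhat = dout * self.gamma.value[None, :, None, None]
        if not train:
            self._cache = None
            return dxhat * inv[None, :, None, None]
        n = xhat.shape[0] * xhat.shape[2] * xhat.shape[3]
        s1 = dxhat.sum(axis=(0, 2, 3))[None, :, None, None]
        s2 = (dxhat * xhat).sum(axis=(0, 2, 3))[None, :, None, None]
        dx = (dxhat - s1 / n - xhat * s2 / n) * inv[None, :, None, None]
        self._cache = None
        return dx


class GlobalAvgPool(Module):
    def forward(self, x, train=False):
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, dout):
        N, C, H, W = self._shape
        return np.broadcast_to(dout[:, :, None, None], self._shape) / (H * W)


class Sequential(Module):
    def __init__(self, *layers: Module):
        self.layers = list(layers)

    def forward(self, x, train=False):
        for l in self.layers:
            x = l.forward(x, train)
        return x

    def backward(self, dout):
        for l in reversed(self.layers):
            dout = l.backward(dout)
        return dout


class ParallelConcat(Module):
    """Run paths on the same input; concatenate outputs on the channel axis."""

    def __init__(self, *paths: Module):
        self.paths = list(paths)

    def forward(self, x, train=False):
        outs = [p.forward(x, train) for p in self.paths]
        self._splits = np.cumsum([o.shape[1] for o in outs])[:-1]
        return np.concatenate(outs, axis=1)

    def backward(self, dout):
        parts = np.split(dout, self._splits, axis=1)
        dx = None
        for p, g in zip(self.paths, parts):
            d = p.backward(np.ascontiguousarray(g))
            dx = d if dx is None else dx + d
        return dx


class Residual(Module):
    """x + scale * inner(x); the scaled shortcut of inception-resnet blocks."""

    def __init__(self, inner: Module, scale: float = 0.2):
        self.inner = inner
        self.scale = scale

    def forward(self, x, train=False):
        return x + self.scale * self.inner.forward(x, train)

    def backward(self, dout):
        return dout + self.inner.backward(self.scale * dout)


def concat_features(arrays: Sequence[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    """Channel-axis concat returning the split points for backward."""
    splits = np.cumsum([a.shape[1] for a in arrays])[:-1]
    return np.concatenate(arrays, axis=1), splits


class Adam:
    """Adam with the framework-default moments (b1 0.9, b2 0.999, eps 1e-8)."""

    def __init__(self, params: Iterable[Param], lr: float = 1e-4,
                 b1: float = 0.9, b2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.b1, self.b2, self.eps = lr, b1, b2, eps
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        bc1 = 1 - self.b1**self.t
        bc2 = 1 - self.b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * p.grad
            v *= self.b2
            v += (1 - self.b2) * p.grad**2
            p.value -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
            p.grad[...] = 0.0


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def weighted_cross_entropy(
    logits: np.ndarray, labels: np.ndarray, class_weights: Optional[np.ndarray] = None
) -> tuple[float, np.ndarray]:
    """Mean of per-sample class-weighted CE; returns (loss, dlogits)."""
    n, k = logits.shape
    p = softmax(logits)
    w = np.ones(n) if class_weights is None else np.asarray(class_weights)[labels]
    logp = np.log(np.clip(p[np.arange(n), labels], 1e-300, None))
    loss = float(-(w * logp).mean())
    dlogits = p * w[:, None]
    dlogits[np.arange(n), labels] -= w
    return loss, dlogits / n
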