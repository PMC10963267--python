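"""Minimal reverse-mode automatic differentiation on numpy arrays.

Supports exactly the operations the package's transformer and MLP need:
broadcast add/mul, batched matmul, reshape/transpose, elementwise exp/tanh/
erf/power, reductions, embedding gather, plus layer modules (Linear,
Embedding, LayerNorm, Dropout), activations, softmax/cross-entropy losses and
an Adam optimizer.  Everything is float32 and seeded; there is no
GPU/threading machinery.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.special import erf as _erf


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Reduce ``grad`` back to ``shape`` after numpy broadcasting."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for i, s in enumerate(shape):
        if s == 1 and grad.shape[i] != 1:
            grad = grad.sum(axis=i, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False, _prev=()):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad = None
        self.requires_grad = requires_grad
        self._backward = None
        self._prev = _prev

    # -- graph plumbing ----------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    def _new(self, data, prev, backward):
        out = Tensor(data, requires_grad=any(p.requires_grad for p in prev), _prev=prev)
        if out.requires_grad:
            out._backward = backward
        return out

    def backward(self):
        topo, visited = [], set()

        def build(t):
            if id(t) in visited:
                return
            visited.add(id(t))
            for p in t._prev:
                build(p)
            topo.append(t)

        build(self)
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    def _accum(self, g):
        if not self.requires_grad:
            return
        g = _unbroadcast(np.asarray(g, dtype=np.float32), self.data.shape)
        self.grad = g if self.grad is None else self.grad + g

    # -- arithmetic ---------------------------------------------------------
    @staticmethod
    def _coerce(x):
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other):
        other = self._coerce(other)
        out = self._new(self.data + other.data, (self, other),
                        lambda g: (self._accum(g), other._accum(g)))
        return out

    __radd__ = __add__

    def __neg__(self):
        return self._new(-self.data, (self,), lambda g: self._accum(-g))

    def __sub__(self, other):
        return self + (-self._coerce(other))

    def __rsub__(self, other):
        return self._coerce(other) + (-self)

    def __mul__(self, other):
        other = self._coerce(other)

        def backward(g):
            self._accum(g * other.data)
            other._accum(g * self.data)

        return self._new(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._coerce(other)

        def backward(g):
            self._accum(g / other.data)
            other._accum(-g * self.data / (other.data ** 2))

        return self._new(self.data / other.data, (self, other), backward)

    def __pow__(self, p: float):
        def backward(g):
            self._accum(g * p * self.data ** (p - 1))

        return self._new(self.data ** p, (self,), backward)

    def matmul(self, other):
        other = self._coerce(other)

        def backward(g):
            self._accum(g @ np.swapaxes(other.data, -1, -2))
            other._accum(np.swapaxes(self.data, -1, -2) @ g)

        return self._new(self.data @ other.data, (self, other), backward)

    __matmul__ = matmul

    # -- elementwise --------------------------------------------------------
    def exp(self):
        out_data = np.exp(self.data)

        def backward(g):
            self._accum(g * out_data)

        return self._new(out_data, (self,), backward)

    def log(self):
        def backward(g):
            self._accum(g / self.data)

        return self._new(np.log(self.data), (self,), backward)

    def tanh(self):
        out_data = np.tanh(self.data)

        def backward(g):
            self._accum(g * (1.0 - out_data ** 2))

        return self._new(out_data, (self,), backward)

    def erf(self):
        def backward(g):
            self._accum(g * (2.0 / math.sqrt(math.pi)) * np.exp(-self.data ** 2))

        return self._new(_erf(self.data), (self,), backward)

    def relu(self):
        mask = self.data > 0

        def backward(g):
            self._accum(g * mask)

        return self._new(self.data * mask, (self,), backward)

    # -- shape & reductions ---------------------------------------------------
    def reshape(self, *shape):
        old = self.data.shape

        def backward(g):
            self._accum(g.reshape(old))

        return self._new(self.data.reshape(*shape), (self,), backward)

    def transpose(self, axes):
        inv = np.argsort(axes)

        def backward(g):
            self._accum(g.transpose(inv))

        return self._new(self.data.transpose(axes), (self,), backward)

    def sum(self, axis=None, keepdims: bool = False):
        def backward(g):
            gg = g
            if axis is not None and not keepdims:
                gg = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(gg, self.data.shape))

        return self._new(self.data.sum(axis=axis, keepdims=keepdims),
                         (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def take_rows(self, index: np.ndarray):
        """Embedding gather: rows of a (V, D) table for an integer index array."""
        index = np.asarray(index)

        def backward(g):
            if not self.requires_grad:
                return
            acc = np.zeros_like(self.data)
            np.add.at(acc, index.reshape(-1),
                      g.reshape(-1, self.data.shape[-1]))
            self._accum(acc)

        return self._new(self.data[index], (self,), backward)


# -- functional ops ----------------------------------------------------------

def softmax(x: Tensor, axis: int = -1) -> Tensor:
    shifted = x + (-x.data.max(axis=axis, keepdims=True))  # detached max
    e = shifted.exp()
    return e / e.sum(axis=axis, keepdims=True)


def gelu(x: Tensor) -> Tensor:
    return x * ((x * (1.0 / math.sqrt(2.0))).erf() + 1.0) * 0.5


def log_softmax(x: Tensor, axis: int = -1) -> Tensor:
    shifted = x + (-x.data.max(axis=axis, keepdims=True))
    return shifted - shifted.exp().sum(axis=axis, keepdims=True).log()


def cross_entropy(logits: Tensor, targets: np.ndarray,
                  class_weights=None, ignore_index: int = -100) -> Tensor:
    """Weighted mean negative log-likelihood over non-ignored targets.

    ``logits`` has shape (N, C) (flatten sequence dims first); ``targets``
    is an int array of shape (N,).  Entries equal to ``ignore_index`` do not
    contribute.  Weighted mean follows the convention sum(w_i * nll_i) /
    sum(w_i).
    """
    targets = np.asarray(targets).reshape(-1)
    n, c = logits.shape
    keep = targets != ignore_index
    if not keep.any():
        raise ValueError("no unmasked targets in batch")
    safe = np.where(keep, targets, 0)
    onehot = np.zeros((n, c), dtype=np.float32)
    onehot[np.arange(n), safe] = 1.0
    onehot[~keep] = 0.0
    if class_weights is not None:
        w = np.asarray(class_weights, dtype=np.float32)[safe] * keep
    else:
        w = keep.astype(np.float32)
    logp = log_softmax(logits, axis=-1)
    nll_sum = -(logp * (onehot * w[:, None])).sum()
    return nll_sum * (1.0 / float(w.sum()))


def mse_loss(pred: Tensor, targets: np.ndarray) -> Tensor:
    diff = pred + (-np.asarray(targets, dtype=np.float32))
    return (diff * diff).mean()


# -- modules -----------------------------------------------------------------

class Module:
    def parameters(self):
        out = []
        for v in self.__dict__.values():
            if isinstance(v, Tensor) and v.requires_grad:
                out.append(v)
            elif isinstance(v, Module):
                out.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        out.extend(item.parameters())
                    elif isinstance(item, Tensor) and item.requires_grad:
                        out.append(item)
        return out

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def state(self):
        return [p.data.copy() for p in self.parameters()]

    def load_state(self, state):
        for p, s in zip(self.parameters(), state):
            p.data = s.copy()


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, bias: bool = True,
                 rng: np.random.Generator | None = None, init_std: float = 0.02):
        rng = rng or np.random.default_rng(0)
        self.weight = Tensor(rng.normal(0, init_std, size=(d_in, d_out)),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(d_out), requires_grad=True) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        out = x @ self.weight
        return out + self.bias if self.bias is not None else out


class Embedding(Module):
    def __init__(self, vocab: int, dim: int,
                 rng: np.random.Generator | None = None, init_std: float = 0.02):
        rng = rng or np.random.default_rng(0)
        self.weight = Tensor(rng.normal(0, init_std, size=(vocab, dim)),
                             requires_grad=True)

    def __call__(self, ids: np.ndarray) -> Tensor:
        return self.weight.take_rows(np.asarray(ids, dtype=np.int64))


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        self.gain = Tensor(np.ones(dim), requires_grad=True)
        self.offset = Tensor(np.zeros(dim), requires_grad=True)
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        centred = x - mu
        var = (centred * centred).mean(axis=-1, keepdims=True)
        inv = (var + self.eps) ** -0.5
        return centred * inv * self.gain + self.offset


class Dropout(Module):
    """Inverted dropout; active only when a generator is passed to __call__."""

    def __init__(self, p: float):
        if not 0.0 <= p < 1.0:
            raise ValueError("dropout p must be in [0, 1)")
        self.p = p

    def __call__(self, x: Tensor, rng: np.random.Generator | None = None) -> Tensor:
        if rng is None or self.p == 0.0:
            return x
        mask = (rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * mask.astype(np.float32)


class Adam:
    """Adam with the conventional defaults (lr 1e-4 for the package's models)."""

    def __init__(self, params, lr: float = 1e-4, betas=(0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 0.0):
        self.params = list(params)
        self.lr, self.betas, self.eps, self.wd = lr, betas, eps, weight_decay
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def step(self):
        self.t += 1
        b1, b2 = self.betas
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            if self.wd:
                g = g + self.wd * p.data
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1 ** self.t)
            vhat = self.v[i] / (1 - b2 ** self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None
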