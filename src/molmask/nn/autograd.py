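"""Minimal reverse-mode automatic differentiation on NumPy arrays.

Provides exactly the operations the graph encoder and pretraining objectives
need: dense linear algebra, embedding lookups, segment scatter/gather for
message passing and graph pooling, batch normalization, dropout, and
cross-entropy.  Float64 throughout for reproducibility at desk scale.
"""

from __future__ import annotations

from typing import Callable, List, Optional, Sequence

import numpy as np


class Tensor:
    """A node in the computation tape."""

    __slots__ = ("data", "grad", "parents", "_backward", "requires_grad")

    def __init__(self, data, parents=(), backward=None, requires_grad=True):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: Optional[np.ndarray] = None
        self.parents = parents
        self._backward: Optional[Callable] = backward
        self.requires_grad = requires_grad

    @property
    def shape(self):
        return self.data.shape

    def _accum(self, g):
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: List[Tensor] = []
        seen = set()

        def visit(t: Tensor):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t.parents:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is not None:
                t._backward()
        # break closure<->tensor reference cycles so the tape is freed
        # immediately instead of waiting on the cyclic garbage collector
        for t in topo:
            t._backward = None
            t.parents = ()
            if not isinstance(t, Parameter):
                t.grad = None

    # -- arithmetic ---------------------------------------------------------
    def __add__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other, requires_grad=False)
        out = Tensor(self.data + other.data, (self, other))

        def bw():
            if self.requires_grad:
                self._accum(_unbroadcast(out.grad, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(out.grad, other.data.shape))

        out._backward = bw
        return out

    def __mul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other, requires_grad=False)
        out = Tensor(self.data * other.data, (self, other))

        def bw():
            if self.requires_grad:
                self._accum(_unbroadcast(out.grad * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(out.grad * self.data, other.data.shape))

        out._backward = bw
        return out

    __radd__ = __add__
    __rmul__ = __mul__

    def __sub__(self, other):
        return self + (other * -1.0 if isinstance(other, Tensor) else -np.asarray(other))

    def matmul(self, other: "Tensor") -> "Tensor":
        out = Tensor(self.data @ other.data, (self, other))

        def bw():
            if self.requires_grad:
                self._accum(out.grad @ other.data.T)
            if other.requires_grad:
                other._accum(self.data.T @ out.grad)

        out._backward = bw
        return out

    def relu(self) -> "Tensor":
        mask = self.data > 0
        out = Tensor(self.data * mask, (self,))

        def bw():
            if self.requires_grad:
                self._accum(out.grad * mask)

        out._backward = bw
        return out

    def sum(self) -> "Tensor":
        out = Tensor(self.data.sum(), (self,))

        def bw():
            if self.requires_grad:
                self._accum(np.full_like(self.data, out.grad))

        out._backward = bw
        return out

    def mean(self) -> "Tensor":
        n = self.data.size
        out = Tensor(self.data.mean(), (self,))

        def bw():
            if self.requires_grad:
                self._accum(np.full_like(self.data, out.grad / n))

        out._backward = bw
        return out


def _unbroadcast(g: np.ndarray, shape) -> np.ndarray:
    """Sum gradient g down to the given broadcast-source shape."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, s in enumerate(shape):
        if s == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


class Parameter(Tensor):
    """A trainable leaf tensor."""

    def __init__(self, data):
        super().__init__(data, parents=(), backward=None, requires_grad=True)


# ---------------------------------------------------------------------------
# functional ops
# ---------------------------------------------------------------------------

def embedding(table: Tensor, idx: np.ndarray) -> Tensor:
    """Row lookup table[idx]; gradients scatter-add back into the table."""
    idx = np.asarray(idx, dtype=np.int64)
    out = Tensor(table.data[idx], (table,))

    def bw():
        if table.requires_grad:
            if table.grad is None:
                table.grad = np.zeros_like(table.data)
            np.add.at(table.grad, idx, out.grad)

    out._backward = bw
    return out


def segment_sum(x: Tensor, seg: np.ndarray, n_segments: int) -> Tensor:
    """out[s] = sum of rows of x whose segment id is s (scatter-add)."""
    seg = np.asarray(seg, dtype=np.int64)
    data = np.zeros((n_segments,) + x.data.shape[1:])
    np.add.at(data, seg, x.data)
    out = Tensor(data, (x,))

    def bw():
        if x.requires_grad:
            x._accum(out.grad[seg])

    out._backward = bw
    return out


def segment_mean(x: Tensor, seg: np.ndarray, n_segments: int) -> Tensor:
    seg = np.asarray(seg, dtype=np.int64)
    counts = np.bincount(seg, minlength=n_segments).astype(np.float64)
    counts = np.maximum(counts, 1.0)
    s = segment_sum(x, seg, n_segments)
    return s * Tensor((1.0 / counts)[:, None], requires_grad=False)


def segment_max(x: Tensor, seg: np.ndarray, n_segments: int) -> Tensor:
    seg = np.asarray(seg, dtype=np.int64)
    data = np.full((n_segments,) + x.data.shape[1:], -np.inf)
    np.maximum.at(data, seg, x.data)
    out = Tensor(data, (x,))
    argmax_mask = x.data == data[seg]

    def bw():
        if x.requires_grad:
            # gradient flows to every row attaining the max (ties share)
            x._accum(out.grad[seg] * argmax_mask)

    out._backward = bw
    return out


def gather_rows(x: Tensor, idx: np.ndarray) -> Tensor:
    """Select rows x[idx] with scatter-add backward."""
    idx = np.asarray(idx, dtype=np.int64)
    out = Tensor(x.data[idx], (x,))

    def bw():
        if x.requires_grad:
            if x.grad is None:
                x.grad = np.zeros_like(x.data)
            np.add.at(x.grad, idx, out.grad)

    out._backward = bw
    return out


def replace_rows(x: Tensor, idx: np.ndarray, v: Tensor) -> Tensor:
    """Copy of x with rows idx replaced by the (broadcast) vector v."""
    idx = np.asarray(idx, dtype=np.int64)
    data = x.data.copy()
    data[idx] = v.data
    out = Tensor(data, (x, v))

    def bw():
        if x.requires_grad:
            g = out.grad.copy()
            g[idx] = 0.0
            x._accum(g)
        if v.requires_grad:
            v._accum(out.grad[idx].sum(axis=0))

    out._backward = bw
    return out


def linear(x: Tensor, w: Tensor, b: Optional[Tensor] = None) -> Tensor:
    out = x.matmul(w)
    if b is not None:
        out = out + b
    return out


def batch_norm(
    x: Tensor,
    gamma: Tensor,
    beta: Tensor,
    running_mean: np.ndarray,
    running_var: np.ndarray,
    training: bool,
    momentum: float = 0.1,
    eps: float = 1e-5,
) -> Tensor:
    """1-D batch normalization over rows; updates running stats in place."""
    if training:
        mu = x.data.mean(axis=0)
        var = x.data.var(axis=0)
        n = x.data.shape[0]
        running_mean *= 1 - momentum
        running_mean += momentum * mu
        unbiased = var * n / max(n - 1, 1)
        running_var *= 1 - momentum
        running_var += momentum * unbiased
    else:
        mu, var = running_mean, running_var
    inv_std = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu) * inv_std
    out = Tensor(gamma.data * xhat + beta.data, (x, gamma, beta))

    def bw():
        g = out.grad
        if gamma.requires_grad:
            gamma._accum((g * xhat).sum(axis=0))
        if beta.requires_grad:
            beta._accum(g.sum(axis=0))
        if x.requires_grad:
            if training:
                n = x.data.shape[0]
                gxh = g * gamma.data
                dx = (
                    gxh
                    - gxh.mean(axis=0)
                    - xhat * (gxh * xhat).mean(axis=0)
                ) * inv_std
            else:
                dx = g * gamma.data * inv_std
            x._accum(dx)

    out._backward = bw
    return out


def dropout(x: Tensor, p: float, rng: np.random.Generator, training: bool) -> Tensor:
    if not training or p <= 0.0:
        return x
    keep = (rng.random(x.data.shape) >= p) / (1.0 - p)
    return x * Tensor(keep, requires_grad=False)


def log_softmax(x: Tensor) -> Tensor:
    m = x.data.max(axis=-1, keepdims=True)
    z = x.data - m
    lse = np.log(np.exp(z).sum(axis=-1, keepdims=True))
    out = Tensor(z - lse, (x,))

    def bw():
        if x.requires_grad:
            g = out.grad
            x._accum(g - np.exp(out.data) * g.sum(axis=-1, keepdims=True))

    out._backward = bw
    return out


def cross_entropy(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Mean negative log-likelihood of integer class targets."""
    targets = np.asarray(targets, dtype=np.int64)
    ls = log_softmax(logits)
    n = targets.shape[0]
    picked = Tensor(ls.data[np.arange(n), targets], (ls,))

    def bw():
        if ls.requires_grad:
            if ls.grad is None:
                ls.grad = np.zeros_like(ls.data)
            np.add.at(ls.grad, (np.arange(n), targets), picked.grad)

    picked._backward = bw
    return picked.mean() * -1.0


def bce_with_logits_masked(logits: Tensor, targets: np.ndarray, valid: np.ndarray) -> Tensor:
    """Mean binary cross-entropy over entries where ``valid`` is True.

    Numerically stable formulation; invalid (missing-label) entries carry
    zero weight in both loss and gradient.
    """
    y = np.nan_to_num(np.asarray(targets, dtype=np.float64))
    w = valid.astype(np.float64)
    total = max(w.sum(), 1.0)
    x = logits.data
    loss_mat = np.maximum(x, 0) - x * y + np.log1p(np.exp(-np.abs(x)))
    out = Tensor((loss_mat * w).sum() / total, (logits,))

    def bw():
        if logits.requires_grad:
            sig = 1.0 / (1.0 + np.exp(-x))
            logits._accum(out.grad * w * (sig - y) / total)

    out._backward = bw
    return out


def scaled_cosine_error(pred: Tensor, target: np.ndarray, gamma: float = 2.0) -> Tensor:
    """Mean (1 - cosine similarity)**gamma between rows of pred and target."""
    t = np.asarray(target, dtype=np.float64)
    tn = t / np.maximum(np.linalg.norm(t, axis=1, keepdims=True), 1e-12)
    pnorm = np.maximum(np.linalg.norm(pred.data, axis=1, keepdims=True), 1e-12)
    pn = pred.data / pnorm
    cos = (pn * tn).sum(axis=1)
    base = np.maximum(1.0 - cos, 1e-12)
    out = Tensor((base**gamma).mean(), (pred,))

    def bw():
        if pred.requires_grad:
            n = pred.data.shape[0]
            dcos = -gamma * base ** (gamma - 1.0) / n
            # d cos / d pred = (tn - cos * pn) / |pred|
            grad = dcos[:, None] * (tn - cos[:, None] * pn) / pnorm
            pred._accum(out.grad * grad)

    out._backward = bw
    return out


# ---------------------------------------------------------------------------
# optimizer
# ---------------------------------------------------------------------------

class Adam:
    """Adaptive-moment estimation optimizer."""

    def __init__(self, params: Sequence[Parameter], lr=1e-3, betas=(0.9, 0.999), eps=1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def xavier_uniform(rng: np.random.Generator, fan_in: int, fan_out: int, shape=None):
    """Glorot-uniform initialization."""
    bound = np.sqrt(6.0 / (fan_in + fan_out))
    if shape is None:
        shape = (fan_in, fan_out)
    return rng.uniform(-bound, bound, size=shape)
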