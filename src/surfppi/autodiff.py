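"""Minimal reverse-mode automatic differentiation on NumPy arrays.

Supports exactly the operations the surface network needs: broadcasting
arithmetic, dense matmul, elementwise nonlinearities, row gather, fixed-k
mean pooling, sparse neighborhood aggregation with a precomputed sparsity
pattern, and a fused binary cross-entropy-with-logits loss. Gradients are
accumulated by topological traversal from a scalar loss. Everything is
deterministic; tests check each operation against central finite
differences.

Also home of the AMSGrad variant of Adam, the optimizer used for training.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np
from scipy import sparse as _sparse

__all__ = [
    "Tensor",
    "param",
    "constant",
    "matmul",
    "relu",
    "tanh",
    "sigmoid",
    "softplus",
    "absolute",
    "concat",
    "gather_rows",
    "mean_pool",
    "mean_all",
    "sum_all",
    "SparsePattern",
    "spmm",
    "bce_with_logits",
    "Amsgrad",
]


class Tensor:
    """An array node in the computation graph."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(
        self,
        data,
        requires_grad: bool = False,
        parents: tuple["Tensor", ...] = (),
        backward: Callable[[np.ndarray], None] | None = None,
    ):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = parents
        self._backward = backward

    @property
    def shape(self):
        return self.data.shape

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.array(g, dtype=self.data.dtype, copy=True)
        else:
            self.grad += g

    def backward(self) -> None:
        """Backpropagate from this scalar through the graph."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self._accumulate(np.ones_like(self.data))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # operator sugar
    def __add__(self, other):
        return add(self, _wrap(other))

    def __sub__(self, other):
        return add(self, neg(_wrap(other)))

    def __mul__(self, other):
        return mul(self, _wrap(other))

    def __matmul__(self, other):
        return matmul(self, other)

    def __neg__(self):
        return neg(self)


def _wrap(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def param(data) -> Tensor:
    return Tensor(np.array(data, dtype=np.float64), requires_grad=True)


def constant(data) -> Tensor:
    return Tensor(data)


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Reduce a broadcasted gradient back to ``shape``."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, size in enumerate(shape):
        if size == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


def add(a: Tensor, b: Tensor) -> Tensor:
    out = Tensor(a.data + b.data, parents=(a, b))

    def bw(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g, a.data.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g, b.data.shape))

    out._backward = bw
    return out


def neg(a: Tensor) -> Tensor:
    out = Tensor(-a.data, parents=(a,))
    out._backward = lambda g: a._accumulate(-g) if a.requires_grad else None
    return out


def mul(a: Tensor, b: Tensor) -> Tensor:
    out = Tensor(a.data * b.data, parents=(a, b))

    def bw(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g * b.data, a.data.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g * a.data, b.data.shape))

    out._backward = bw
    return out


def matmul(a: Tensor, b: Tensor) -> Tensor:
    out = Tensor(a.data @ b.data, parents=(a, b))

    def bw(g):
        if a.requires_grad:
            a._accumulate(g @ b.data.T)
        if b.requires_grad:
            b._accumulate(a.data.T @ g)

    out._backward = bw
    return out


def relu(a: Tensor) -> Tensor:
    mask = a.data > 0
    out = Tensor(np.where(mask, a.data, 0.0), parents=(a,))
    out._backward = lambda g: a._accumulate(g * mask) if a.requires_grad else None
    return out


def tanh(a: Tensor) -> Tensor:
    t = np.tanh(a.data)
    out = Tensor(t, parents=(a,))
    out._backward = lambda g: a._accumulate(g * (1.0 - t * t)) if a.requires_grad else None
    return out


def sigmoid(a: Tensor) -> Tensor:
    s = _stable_sigmoid(a.data)
    out = Tensor(s, parents=(a,))
    out._backward = lambda g: a._accumulate(g * s * (1.0 - s)) if a.requires_grad else None
    return out


def _stable_sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def softplus(a: Tensor) -> Tensor:
    sp = np.logaddexp(0.0, a.data)
    out = Tensor(sp, parents=(a,))
    s = _stable_sigmoid(a.data)
    out._backward = lambda g: a._accumulate(g * s) if a.requires_grad else None
    return out


def absolute(a: Tensor) -> Tensor:
    out = Tensor(np.abs(a.data), parents=(a,))
    sign = np.sign(a.data)
    out._backward = lambda g: a._accumulate(g * sign) if a.requires_grad else None
    return out


def concat(tensors: Sequence[Tensor], axis: int = 1) -> Tensor:
    datas = [t.data for t in tensors]
    out = Tensor(np.concatenate(datas, axis=axis), parents=tuple(tensors))
    sizes = [d.shape[axis] for d in datas]
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accumulate(g[tuple(sl)])

    out._backward = bw
    return out


def gather_rows(a: Tensor, idx: np.ndarray) -> Tensor:
    """Select rows ``a[idx]``; backward scatter-adds (suitable for small idx)."""
    out = Tensor(a.data[idx], parents=(a,))

    def bw(g):
        if a.requires_grad:
            acc = np.zeros_like(a.data)
            np.add.at(acc, idx, g)
            a._accumulate(acc)

    out._backward = bw
    return out


def mean_pool(a: Tensor, k: int) -> Tensor:
    """Mean over fixed-size groups: (P*k, C) -> (P, C)."""
    n, c = a.data.shape
    if n % k:
        raise ValueError(f"row count {n} not divisible by group size {k}")
    out = Tensor(a.data.reshape(n // k, k, c).mean(axis=1), parents=(a,))

    def bw(g):
        if a.requires_grad:
            a._accumulate(np.repeat(g / k, k, axis=0))

    out._backward = bw
    return out


def sum_all(a: Tensor) -> Tensor:
    out = Tensor(a.data.sum(), parents=(a,))
    out._backward = lambda g: a._accumulate(np.full_like(a.data, float(g))) \
        if a.requires_grad else None
    return out


def mean_all(a: Tensor) -> Tensor:
    n = a.data.size
    out = Tensor(a.data.mean(), parents=(a,))
    out._backward = lambda g: a._accumulate(np.full_like(a.data, float(g) / n)) \
        if a.requires_grad else None
    return out


class SparsePattern:
    """Fixed sparsity structure of a (n_dst x n_src) edge-weight matrix.

    Built once per point set from an edge list ``(dst, src)``; forward passes
    then only supply the edge values. Stores CSR index structure for both the
    matrix and its transpose together with the edge permutations mapping the
    caller's edge order onto each CSR data layout.
    """

    def __init__(self, dst: np.ndarray, src: np.ndarray, n_dst: int, n_src: int):
        dst = np.asarray(dst, dtype=np.int64)
        src = np.asarray(src, dtype=np.int64)
        if len(dst) != len(src):
            raise ValueError("dst and src must have equal length")
        self.dst, self.src = dst, src
        self.n_dst, self.n_src = int(n_dst), int(n_src)
        self.n_edges = len(dst)
        self.perm = np.lexsort((src, dst))
        self.indptr = np.bincount(dst, minlength=n_dst).cumsum()
        self.indptr = np.concatenate([[0], self.indptr]).astype(np.int64)
        self.indices = src[self.perm]
        self.perm_t = np.lexsort((dst, src))
        self.indptr_t = np.bincount(src, minlength=n_src).cumsum()
        self.indptr_t = np.concatenate([[0], self.indptr_t]).astype(np.int64)
        self.indices_t = dst[self.perm_t]

    def matmul(self, values: np.ndarray, x: np.ndarray) -> np.ndarray:
        m = _sparse.csr_matrix(
            (values[self.perm], self.indices, self.indptr),
            shape=(self.n_dst, self.n_src),
        )
        return m @ x

    def rmatmul(self, values: np.ndarray, g: np.ndarray) -> np.ndarray:
        mt = _sparse.csr_matrix(
            (values[self.perm_t], self.indices_t, self.indptr_t),
            shape=(self.n_src, self.n_dst),
        )
        return mt @ g


def spmm(pattern: SparsePattern, values: Tensor, x: Tensor) -> Tensor:
    """Weighted neighborhood aggregation ``out[i] = sum_j w_ij x[j]``.

    ``values`` holds one scalar per edge of ``pattern`` (shape (E,) or
    (E, 1)); ``x`` is dense (n_src, C). Gradients flow to both the edge
    values and the dense features.
    """
    vals = values.data.reshape(-1)
    if vals.shape[0] != pattern.n_edges:
        raise ValueError("edge value count does not match the sparsity pattern")
    out = Tensor(pattern.matmul(vals, x.data), parents=(values, x))

    def bw(g):
        if values.requires_grad:
            dv = np.einsum("ec,ec->e", g[pattern.dst], x.data[pattern.src])
            values._accumulate(dv.reshape(values.data.shape))
        if x.requires_grad:
            x._accumulate(pattern.rmatmul(vals, g))

    out._backward = bw
    return out


def bce_with_logits(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Mean binary cross-entropy, fused with the logistic link for stability.

    ``loss = mean( softplus(z) - y * z )``; gradient ``(sigmoid(z) - y)/n``.
    """
    z = logits.data.reshape(-1)
    y = np.asarray(targets, dtype=np.float64).reshape(-1)
    if z.shape != y.shape:
        raise ValueError(f"logits {z.shape} vs targets {y.shape}")
    loss = float(np.mean(np.logaddexp(0.0, z) - y * z))
    out = Tensor(loss, parents=(logits,))

    def bw(g):
        if logits.requires_grad:
            d = (_stable_sigmoid(z) - y) / len(z) * float(g)
            logits._accumulate(d.reshape(logits.data.shape))

    out._backward = bw
    return out


class Amsgrad:
    """AMSGrad variant of Adam (maintains the running max of the second
    moment, guaranteeing a non-increasing effective step size)."""

    def __init__(
        self,
        params: Iterable[Tensor],
        lr: float = 1e-3,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
    ):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.vhat = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1 ** self.t
        bc2 = 1.0 - self.b2 ** self.t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * p.grad
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * p.grad ** 2
            np.maximum(self.vhat[i], self.v[i], out=self.vhat[i])
            m_hat = self.m[i] / bc1
            v_hat = self.vhat[i] / bc2
            p.data -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)
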