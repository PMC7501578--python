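"""Minimal reverse-mode automatic differentiation on NumPy arrays.

All model components in this package (recurrent encoders, language model,
CRF) are expressed as compositions of the primitives below.  Arrays are
float64 throughout: every model here runs at batch size 1 or on tiny
batches, so exactness is preferred over speed, and float64 keeps the
finite-difference gradient checks sharp.

The design is the usual dynamic tape: each :class:`Tensor` records the
operation that produced it and a closure that accumulates gradients into
its parents; :meth:`Tensor.backward` runs the tape in reverse topological
order.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = ["Tensor", "Linear", "concat", "stack", "transpose", "SGD", "Adam",
           "no_grad"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Reduce ``grad`` back to ``shape`` after NumPy broadcasting."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, n in enumerate(shape) if n == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class _GradMode:
    enabled = True


class no_grad:
    """Context manager disabling tape construction (pure inference)."""

    def __enter__(self):
        self._prev = _GradMode.enabled
        _GradMode.enabled = False
        return self

    def __exit__(self, *exc):
        _GradMode.enabled = self._prev
        return False


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad and _GradMode.enabled
        self._backward: Callable[[np.ndarray], None] | None = None
        self._parents: tuple[Tensor, ...] = ()

    # -- construction helpers -------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.shape}, grad={self.requires_grad})"

    # -- tape machinery -------------------------------------------------------
    @staticmethod
    def _wrap(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    @staticmethod
    def _make(data: np.ndarray, parents: Sequence["Tensor"],
              backward: Callable[[np.ndarray], None]) -> "Tensor":
        out = Tensor(data)
        if _GradMode.enabled and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def _accum(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = grad.copy()
        else:
            self.grad += grad

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
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
        self._accum(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
        _flush_pending()

    # -- arithmetic -----------------------------------------------------------
    def __add__(self, other) -> "Tensor":
        other = self._wrap(other)
        out_data = self.data + other.data

        def bwd(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.shape))

        return self._make(out_data, (self, other), bwd)

    __radd__ = __add__

    def __neg__(self) -> "Tensor":
        def bwd(g):
            self._accum(-g)

        return self._make(-self.data, (self,), bwd)

    def __sub__(self, other) -> "Tensor":
        return self + (-self._wrap(other))

    def __rsub__(self, other) -> "Tensor":
        return self._wrap(other) + (-self)

    def __mul__(self, other) -> "Tensor":
        other = self._wrap(other)
        out_data = self.data * other.data

        def bwd(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.shape))

        return self._make(out_data, (self, other), bwd)

    __rmul__ = __mul__

    def __truediv__(self, other) -> "Tensor":
        other = self._wrap(other)
        out_data = self.data / other.data

        def bwd(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g / other.data, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(-g * self.data / other.data ** 2,
                                          other.shape))

        return self._make(out_data, (self, other), bwd)

    def __matmul__(self, other) -> "Tensor":
        other = self._wrap(other)
        out_data = self.data @ other.data

        a_vec = self.ndim == 1
        b_vec = other.ndim == 1

        def bwd(g):
            ga = g[..., None, :] if a_vec and not b_vec else g
            if self.requires_grad:
                if b_vec:
                    da = (g[..., None] * other.data) if not a_vec \
                        else g * other.data
                else:
                    da = ga @ other.data.swapaxes(-1, -2)
                    if a_vec:
                        da = da[..., 0, :]
                self._accum(_unbroadcast(da, self.shape))
            if other.requires_grad:
                if a_vec and b_vec:
                    db = g * self.data
                elif a_vec:
                    db = np.outer(self.data, g)
                elif b_vec:
                    db = (self.data * g[..., None]).sum(
                        axis=tuple(range(self.ndim - 1)))
                else:
                    db = self.data.swapaxes(-1, -2) @ g
                other._accum(_unbroadcast(db, other.shape))

        return self._make(out_data, (self, other), bwd)

    def __getitem__(self, idx) -> "Tensor":
        out_data = self.data[idx]

        def bwd(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            self._accum(full)

        return self._make(out_data, (self,), bwd)

    def reshape(self, shape) -> "Tensor":
        def bwd(g):
            self._accum(g.reshape(self.shape))

        return self._make(self.data.reshape(shape), (self,), bwd)

    # -- nonlinearities -------------------------------------------------------
    def sigmoid(self) -> "Tensor":
        out_data = 1.0 / (1.0 + np.exp(-self.data))

        def bwd(g):
            self._accum(g * out_data * (1.0 - out_data))

        return self._make(out_data, (self,), bwd)

    def tanh(self) -> "Tensor":
        out_data = np.tanh(self.data)

        def bwd(g):
            self._accum(g * (1.0 - out_data ** 2))

        return self._make(out_data, (self,), bwd)

    def exp(self) -> "Tensor":
        out_data = np.exp(self.data)

        def bwd(g):
            self._accum(g * out_data)

        return self._make(out_data, (self,), bwd)

    def log(self) -> "Tensor":
        def bwd(g):
            self._accum(g / self.data)

        return self._make(np.log(self.data), (self,), bwd)

    # -- reductions -----------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def bwd(g):
            if axis is None:
                self._accum(np.broadcast_to(g, self.shape).copy())
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                self._accum(np.broadcast_to(gg, self.shape).copy())

        return self._make(out_data, (self,), bwd)

    def mean(self, axis=None) -> "Tensor":
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis) * (1.0 / n)

    def logsumexp(self, axis: int = -1, keepdims: bool = False) -> "Tensor":
        m = self.data.max(axis=axis, keepdims=True)
        e = np.exp(self.data - m)
        s = e.sum(axis=axis, keepdims=True)
        out_data = (m + np.log(s))
        soft = e / s
        if not keepdims:
            out_data = np.squeeze(out_data, axis=axis)

        def bwd(g):
            gg = g if keepdims else np.expand_dims(g, axis)
            self._accum(gg * soft)

        return self._make(out_data, (self,), bwd)

    def softmax(self, axis: int = -1) -> "Tensor":
        return (self - self.logsumexp(axis=axis, keepdims=True)).exp()


#: Linear layers with weight-gradient contributions awaiting accumulation
_PENDING: list["Linear"] = []


def _flush_pending() -> None:
    while _PENDING:
        _PENDING.pop().flush()


class Linear:
    """Affine map ``x -> x @ W.T + b`` with deferred weight gradients.

    A recurrent model applies the same weight matrix at every time step;
    accumulating an outer-product gradient per step is memory-bound.  This
    op instead records the (input, output-gradient) pairs during the
    backward sweep and accumulates all of them with a single GEMM when the
    sweep finishes (:meth:`Tensor.backward` flushes automatically).
    """

    def __init__(self, W: Tensor, b: Tensor | None = None):
        if W.ndim != 2:
            raise ValueError("Linear weight must be 2-D (out, in)")
        self.W = W
        self.b = b
        self._zs: list[np.ndarray] = []
        self._gs: list[np.ndarray] = []

    def __call__(self, x: Tensor) -> Tensor:
        out_data = x.data @ self.W.data.T
        if self.b is not None:
            out_data = out_data + self.b.data
        parents = (x, self.W) if self.b is None else (x, self.W, self.b)

        def bwd(g):
            if x.requires_grad:
                x._accum(g @ self.W.data)
            if self.W.requires_grad:
                if not self._zs:
                    _PENDING.append(self)
                self._zs.append(x.data.reshape(-1, self.W.shape[1]))
                self._gs.append(g.reshape(-1, self.W.shape[0]))
            if self.b is not None and self.b.requires_grad:
                self.b._accum(_unbroadcast(g, self.b.shape))

        return Tensor._make(out_data, parents, bwd)

    def flush(self) -> None:
        if not self._zs:
            return
        Z = np.concatenate(self._zs, axis=0)
        G = np.concatenate(self._gs, axis=0)
        self._zs.clear()
        self._gs.clear()
        self.W._accum(G.T @ Z)

    def params(self) -> list[Tensor]:
        return [self.W] if self.b is None else [self.W, self.b]


def transpose(w: Tensor) -> Tensor:
    """Transpose of a 2-D tensor (gradient-aware)."""

    def bwd(g):
        w._accum(g.T)

    return Tensor._make(w.data.T, (w,), bwd)


def concat(tensors: Sequence[Tensor], axis: int = -1) -> Tensor:
    tensors = [Tensor._wrap(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bwd(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis if axis >= 0 else g.ndim + axis] = slice(a, b)
                t._accum(g[tuple(sl)])

    return Tensor._make(out_data, tensors, bwd)


def stack(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [Tensor._wrap(t) for t in tensors]
    out_data = np.stack([t.data for t in tensors], axis=axis)

    def bwd(g):
        slices = np.moveaxis(g, axis, 0)
        for t, gi in zip(tensors, slices):
            if t.requires_grad:
                t._accum(gi)

    return Tensor._make(out_data, tensors, bwd)


# -- optimizers ---------------------------------------------------------------


class SGD:
    """Plain stochastic gradient descent with optional gradient-norm clipping."""

    def __init__(self, params: Iterable[Tensor], lr: float,
                 clip_norm: float | None = 50.0):
        self.params = list(params)
        self.lr = lr
        self.clip_norm = clip_norm

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        grads = [p.grad for p in self.params if p.grad is not None]
        scale = 1.0
        if self.clip_norm is not None and grads:
            total = float(np.sqrt(sum(float((g ** 2).sum()) for g in grads)))
            if total > self.clip_norm:
                scale = self.clip_norm / (total + 1e-12)
        for p in self.params:
            if p.grad is not None:
                p.data -= self.lr * scale * p.grad


class Adam:
    def __init__(self, params: Iterable[Tensor], lr: float = 1e-2,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
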