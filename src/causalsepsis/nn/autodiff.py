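"""Reverse-mode automatic differentiation on numpy arrays.

A :class:`Tensor` wraps a float64 ``ndarray`` and records the operations
applied to it; :meth:`Tensor.backward` walks the tape in reverse topological
order and accumulates gradients into every tensor with ``requires_grad``.
Broadcasting follows numpy semantics; gradients of broadcast operands are
summed back to the operand's shape.

Only the operations the package's networks need are provided.  Everything is
float64: the loss-arithmetic contracts elsewhere in the package are asserted
to 1e-10 and the engine should not be the limiting factor.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = ["Tensor", "concat", "no_grad", "is_grad_enabled", "default_dtype"]

_GRAD_ENABLED = [True]
_DEFAULT_DTYPE = [np.float64]


class default_dtype:
    """Context manager selecting the dtype of newly created tensors.

    Float64 is the package default (the arithmetic contracts are asserted to
    1e-10); training loops switch to float32 for throughput.
    """

    def __init__(self, dtype):
        self.dtype = np.dtype(dtype)

    def __enter__(self):
        _DEFAULT_DTYPE.append(self.dtype)
        return self

    def __exit__(self, *exc):
        _DEFAULT_DTYPE.pop()
        return False


class no_grad:
    """Context manager disabling graph construction (inference mode)."""

    def __enter__(self):
        _GRAD_ENABLED.append(False)
        return self

    def __exit__(self, *exc):
        _GRAD_ENABLED.pop()
        return False


def is_grad_enabled() -> bool:
    return _GRAD_ENABLED[-1]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` over axes that were broadcast to reach ``grad.shape``."""
    if grad.shape == shape:
        return grad
    # sum leading extra dims
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    # sum axes where original dim was 1
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward_fn")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=_DEFAULT_DTYPE[-1])
        self.requires_grad = bool(requires_grad)
        self.grad: np.ndarray | None = None
        self._parents: tuple = ()
        self._backward_fn: Callable | None = None

    # -- construction helpers ------------------------------------------------
    @staticmethod
    def _make(data, parents, backward_fn) -> "Tensor":
        out = Tensor(data)
        if is_grad_enabled() and any(p.requires_grad or p._parents for p in parents):
            out._parents = tuple(parents)
            out._backward_fn = backward_fn
        return out

    @staticmethod
    def as_tensor(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    # -- bookkeeping ---------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __len__(self):
        return len(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def item(self) -> float:
        return float(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self) -> None:
        self.grad = None

    # -- backward ------------------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad, dtype=self.data.dtype)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node.requires_grad:
                node.grad = g if node.grad is None else node.grad + g
            if node._backward_fn is None:
                continue
            parent_grads = node._backward_fn(g)
            for p, pg in zip(node._parents, parent_grads):
                if pg is None:
                    continue
                if id(p) in grads:
                    grads[id(p)] = grads[id(p)] + pg
                else:
                    grads[id(p)] = pg

    # -- arithmetic ----------------------------------------------------------
    def __add__(self, other):
        other = Tensor.as_tensor(other)
        out = Tensor._make(
            self.data + other.data,
            (self, other),
            lambda g: (_unbroadcast(g, self.data.shape), _unbroadcast(g, other.data.shape)),
        )
        return out

    __radd__ = __add__

    def __neg__(self):
        return Tensor._make(-self.data, (self,), lambda g: (-g,))

    def __sub__(self, other):
        return self + (-Tensor.as_tensor(other))

    def __rsub__(self, other):
        return Tensor.as_tensor(other) + (-self)

    def __mul__(self, other):
        other = Tensor.as_tensor(other)
        a, b = self.data, other.data
        return Tensor._make(
            a * b,
            (self, other),
            lambda g: (_unbroadcast(g * b, a.shape), _unbroadcast(g * a, b.shape)),
        )

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = Tensor.as_tensor(other)
        a, b = self.data, other.data
        return Tensor._make(
            a / b,
            (self, other),
            lambda g: (
                _unbroadcast(g / b, a.shape),
                _unbroadcast(-g * a / (b * b), b.shape),
            ),
        )

    def __rtruediv__(self, other):
        return Tensor.as_tensor(other) / self

    def __pow__(self, p: float):
        a = self.data
        return Tensor._make(a**p, (self,), lambda g: (g * p * a ** (p - 1),))

    def __matmul__(self, other):
        other = Tensor.as_tensor(other)
        a, b = self.data, other.data

        def back(g):
            if b.ndim == 1:
                ga = np.outer(g, b) if a.ndim == 2 else g[..., None] * b
                gb = (a * g[..., None]).reshape(-1, a.shape[-1]).sum(0) if a.ndim >= 2 else g * a
                return ga, gb
            ga = g @ np.swapaxes(b, -1, -2)
            gb = np.swapaxes(a, -1, -2) @ g
            return _unbroadcast(ga, a.shape), _unbroadcast(gb, b.shape)

        return Tensor._make(a @ b, (self, other), back)

    # -- elementwise ---------------------------------------------------------
    def exp(self):
        out_data = np.exp(self.data)
        return Tensor._make(out_data, (self,), lambda g: (g * out_data,))

    def log(self):
        return Tensor._make(np.log(self.data), (self,), lambda g: (g / self.data,))

    def tanh(self):
        out_data = np.tanh(self.data)
        return Tensor._make(out_data, (self,), lambda g: (g * (1.0 - out_data**2),))

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-self.data))
        return Tensor._make(out_data, (self,), lambda g: (g * out_data * (1.0 - out_data),))

    def relu(self):
        mask = self.data > 0
        return Tensor._make(self.data * mask, (self,), lambda g: (g * mask,))

    def softplus(self):
        # log(1 + e^x), numerically stable
        out_data = np.logaddexp(0.0, self.data)
        sig = 1.0 / (1.0 + np.exp(-self.data))
        return Tensor._make(out_data, (self,), lambda g: (g * sig,))

    def sqrt(self):
        out_data = np.sqrt(self.data)
        return Tensor._make(out_data, (self,), lambda g: (g * 0.5 / out_data,))

    # -- reductions / shape --------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        a = self.data

        def back(g):
            if axis is None:
                return (np.broadcast_to(g, a.shape).copy(),)
            gg = g
            if not keepdims:
                gg = np.expand_dims(gg, axis)
            return (np.broadcast_to(gg, a.shape).copy(),)

        return Tensor._make(a.sum(axis=axis, keepdims=keepdims), (self,), back)

    def mean(self, axis=None, keepdims: bool = False):
        a = self.data
        if axis is None:
            n = a.size
        elif isinstance(axis, tuple):
            n = int(np.prod([a.shape[ax] for ax in axis]))
        else:
            n = a.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        a = self.data
        return Tensor._make(a.reshape(shape), (self,), lambda g: (g.reshape(a.shape),))

    def transpose(self, *axes):
        if not axes:
            axes = tuple(range(self.data.ndim))[::-1]
        elif len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)
        return Tensor._make(
            self.data.transpose(axes), (self,), lambda g: (g.transpose(inv),)
        )

    def swapaxes(self, a1: int, a2: int):
        return Tensor._make(
            np.swapaxes(self.data, a1, a2), (self,), lambda g: (np.swapaxes(g, a1, a2),)
        )

    def __getitem__(self, idx):
        a = self.data

        def back(g):
            out = np.zeros_like(a)
            np.add.at(out, idx, g)
            return (out,)

        return Tensor._make(a[idx], (self,), back)

    def max_last(self):
        """Max over the last axis, with subgradient to the (first) argmax."""
        a = self.data
        idx = np.argmax(a, axis=-1)

        def back(g):
            out = np.zeros_like(a)
            np.put_along_axis(out, idx[..., None], g[..., None], axis=-1)
            return (out,)

        return Tensor._make(np.take_along_axis(a, idx[..., None], -1)[..., 0], (self,), back)

    def logsumexp(self, axis: int = -1, keepdims: bool = False):
        m = np.max(self.data, axis=axis, keepdims=True)  # constant shift
        shifted = self - Tensor(m)
        out = shifted.exp().sum(axis=axis, keepdims=True).log() + Tensor(m)
        if not keepdims:
            out = out.reshape(tuple(np.delete(out.shape, axis)))
        return out


def concat(tensors: Sequence[Tensor], axis: int = -1) -> Tensor:
    tensors = [Tensor.as_tensor(t) for t in tensors]
    datas = [t.data for t in tensors]
    sizes = [d.shape[axis] for d in datas]
    splits = np.cumsum(sizes)[:-1]

    def back(g):
        return tuple(np.split(g, splits, axis=axis))

    return Tensor._make(np.concatenate(datas, axis=axis), tuple(tensors), back)
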