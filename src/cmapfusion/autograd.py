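"""Minimal reverse-mode automatic differentiation over numpy arrays.

A :class:`Tensor` wraps an ``ndarray`` and records the operations applied to
it; calling :meth:`Tensor.backward` on a scalar output accumulates gradients
into every upstream tensor created with ``requires_grad=True``. The op set is
exactly what the fusion model needs (elementwise arithmetic, matmul with
batching, reductions, softmax, the activations, reshape/transpose/concat/
indexing, and ``detach`` for straight-through estimators); gradients are
verified against central finite differences in the test suite.

All computation is float64. Broadcasting follows numpy semantics; gradients
of broadcast operands are summed back to the operand's shape.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "as_tensor", "concat", "no_grad_mode"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape`, undoing numpy broadcasting."""
    if grad.shape == shape:
        return grad
    # sum away prepended axes
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    # sum axes that were broadcast from size 1
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev", "name")

    def __init__(self, data, requires_grad: bool = False, _prev=(), name: str | None = None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._prev = _prev
        self.name = name

    # ------------------------------------------------------------------ infra
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            # copy: g may be a read-only broadcast view reused elsewhere
            self.grad = np.array(g, dtype=np.float64)
        else:
            self.grad += g

    def zero_grad(self) -> None:
        self.grad = None

    def detach(self) -> "Tensor":
        """A constant view of this tensor: blocks gradient flow."""
        return Tensor(self.data)

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
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
            for p in node._prev:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # ------------------------------------------------------------- arithmetic
    def __add__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data + other.data, _prev=(self, other))

        def bw(g):
            self._accum(_unbroadcast(g, self.data.shape))
            other._accum(_unbroadcast(g, other.data.shape))

        out._backward = bw
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, _prev=(self,))
        out._backward = lambda g: self._accum(-g)
        return out

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data * other.data, _prev=(self, other))

        def bw(g):
            self._accum(_unbroadcast(g * other.data, self.data.shape))
            other._accum(_unbroadcast(g * self.data, other.data.shape))

        out._backward = bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data / other.data, _prev=(self, other))

        def bw(g):
            self._accum(_unbroadcast(g / other.data, self.data.shape))
            other._accum(_unbroadcast(-g * self.data / other.data**2, other.data.shape))

        out._backward = bw
        return out

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __pow__(self, p: float):
        out = Tensor(self.data**p, _prev=(self,))
        out._backward = lambda g: self._accum(g * p * self.data ** (p - 1))
        return out

    def __matmul__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data @ other.data, _prev=(self, other))
        a, b = self.data, other.data

        def bw(g):
            if a.ndim == 1 and b.ndim == 1:  # inner product
                self._accum(g * b)
                other._accum(g * a)
                return
            ga = np.matmul(g, np.swapaxes(b, -1, -2)) if b.ndim > 1 else np.multiply.outer(g, b)
            gb = np.matmul(np.swapaxes(a, -1, -2), g) if a.ndim > 1 else np.multiply.outer(a, g)
            self._accum(_unbroadcast(ga, a.shape))
            other._accum(_unbroadcast(gb, b.shape))

        out._backward = bw
        return out

    # ------------------------------------------------------------- reductions
    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), _prev=(self,))

        def bw(g):
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.data.shape))

        out._backward = bw
        return out

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            axes = (axis,) if isinstance(axis, int) else tuple(axis)
            n = int(np.prod([self.data.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # ------------------------------------------------------------ activations
    def exp(self):
        e = np.exp(self.data)
        out = Tensor(e, _prev=(self,))
        out._backward = lambda g: self._accum(g * e)
        return out

    def log(self):
        out = Tensor(np.log(self.data), _prev=(self,))
        out._backward = lambda g: self._accum(g / self.data)
        return out

    def sqrt(self):
        r = np.sqrt(self.data)
        out = Tensor(r, _prev=(self,))
        out._backward = lambda g: self._accum(g * 0.5 / r)
        return out

    def relu(self):
        out = Tensor(np.maximum(self.data, 0.0), _prev=(self,))
        out._backward = lambda g: self._accum(g * (self.data > 0))
        return out

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor(s, _prev=(self,))
        out._backward = lambda g: self._accum(g * s * (1.0 - s))
        return out

    def tanh(self):
        t = np.tanh(self.data)
        out = Tensor(t, _prev=(self,))
        out._backward = lambda g: self._accum(g * (1.0 - t**2))
        return out

    def gelu(self):
        # tanh approximation of GELU (the transformer-standard form)
        c = np.sqrt(2.0 / np.pi)
        x = self.data
        inner = c * (x + 0.044715 * x**3)
        t = np.tanh(inner)
        out = Tensor(0.5 * x * (1.0 + t), _prev=(self,))

        def bw(g):
            dt = (1.0 - t**2) * c * (1.0 + 3 * 0.044715 * x**2)
            self._accum(g * (0.5 * (1.0 + t) + 0.5 * x * dt))

        out._backward = bw
        return out

    def softmax(self, axis: int = -1):
        z = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(z)
        s = e / e.sum(axis=axis, keepdims=True)
        out = Tensor(s, _prev=(self,))

        def bw(g):
            dot = (g * s).sum(axis=axis, keepdims=True)
            self._accum(s * (g - dot))

        out._backward = bw
        return out

    def maximum(self, floor: float):
        """Elementwise max with a constant; gradient is zero where clamped."""
        out = Tensor(np.maximum(self.data, floor), _prev=(self,))
        out._backward = lambda g: self._accum(g * (self.data > floor))
        return out

    # ------------------------------------------------------------ shape ops
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = Tensor(self.data.reshape(shape), _prev=(self,))
        out._backward = lambda g: self._accum(g.reshape(self.data.shape))
        return out

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        axes = axes or tuple(reversed(range(self.data.ndim)))
        inv = np.argsort(axes)
        out = Tensor(self.data.transpose(axes), _prev=(self,))
        out._backward = lambda g: self._accum(g.transpose(inv))
        return out

    def __getitem__(self, idx):
        out = Tensor(self.data[idx], _prev=(self,))

        def bw(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            self._accum(full)

        out._backward = bw
        return out


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def concat(tensors, axis: int = -1) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), _prev=tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bw(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            t._accum(piece)

    out._backward = bw
    return out


def no_grad_mode(t: Tensor) -> np.ndarray:
    """Convenience: raw array of a tensor (alias for ``t.data``)."""
    return t.data
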