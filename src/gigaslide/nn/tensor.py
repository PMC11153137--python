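"""Minimal reverse-mode automatic differentiation over numpy arrays.

The whole training stack (slide encoder, MAE decoder, ABMIL heads,
contrastive projections) is small enough that a vectorized numpy tape is
fast at desk scale. The engine supports the handful of primitives a
pre-norm transformer needs: broadcasting arithmetic, batched matmul,
reshape/transpose, fancy-index gather, concatenation and reductions.
Gradients are accumulated by topological traversal of the tape.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "stack", "softmax", "gelu", "sigmoid", "layer_norm"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` over axes that numpy broadcasting introduced or stretched."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, _parents=(), _backward=None):
        self.data = np.asarray(data)
        self.requires_grad = bool(requires_grad) or any(p.requires_grad for p in _parents)
        self.grad = None
        self._parents = _parents if self.requires_grad else ()
        self._backward = _backward if self.requires_grad else None

    # ------------------------------------------------------------------ infra
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data, dtype=np.result_type(self.data, np.float32))
        self.grad += g

    def backward(self, grad: np.ndarray | None = None) -> None:
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [self]
        while stack:  # iterative DFS; tapes can be deep for many-layer loops
            node = stack[-1]
            if id(node) in seen:
                stack.pop()
                continue
            unvisited = [p for p in node._parents if id(p) not in seen and p.requires_grad]
            if unvisited:
                stack.extend(unvisited)
            else:
                seen.add(id(node))
                topo.append(node)
                stack.pop()
        self.grad = np.ones_like(self.data) if grad is None else np.asarray(grad)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)

    # ------------------------------------------------------------- arithmetic
    @staticmethod
    def _lift(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def __add__(self, other):
        other = self._lift(other)
        out = Tensor(self.data + other.data, _parents=(self, other))

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))

        out._backward = bw
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, _parents=(self,))
        out._backward = lambda g: self._accum(-g)
        return out

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        out = Tensor(self.data * other.data, _parents=(self, other))

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))

        out._backward = bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)
        out = Tensor(self.data / other.data, _parents=(self, other))

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g / other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(-g * self.data / other.data**2, other.data.shape))

        out._backward = bw
        return out

    def __rtruediv__(self, other):
        return self._lift(other) / self

    def __pow__(self, p: float):
        out = Tensor(self.data**p, _parents=(self,))
        out._backward = lambda g: self._accum(g * p * self.data ** (p - 1))
        return out

    def __matmul__(self, other):
        other = self._lift(other)
        out = Tensor(self.data @ other.data, _parents=(self, other))

        def bw(g):
            if self.requires_grad:
                ga = g @ np.swapaxes(other.data, -1, -2)
                self._accum(_unbroadcast(ga, self.data.shape))
            if other.requires_grad:
                gb = np.swapaxes(self.data, -1, -2) @ g
                other._accum(_unbroadcast(gb, other.data.shape))

        out._backward = bw
        return out

    # ------------------------------------------------------------ elementwise
    def exp(self):
        val = np.exp(self.data)
        out = Tensor(val, _parents=(self,))
        out._backward = lambda g: self._accum(g * val)
        return out

    def log(self):
        out = Tensor(np.log(self.data), _parents=(self,))
        out._backward = lambda g: self._accum(g / self.data)
        return out

    def tanh(self):
        val = np.tanh(self.data)
        out = Tensor(val, _parents=(self,))
        out._backward = lambda g: self._accum(g * (1.0 - val**2))
        return out

    def sqrt(self):
        val = np.sqrt(self.data)
        out = Tensor(val, _parents=(self,))
        out._backward = lambda g: self._accum(g * 0.5 / val)
        return out

    # -------------------------------------------------------------- reductions
    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), _parents=(self,))

        def bw(g):
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.data.shape).copy())

        out._backward = bw
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    # ------------------------------------------------------------------ shape
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = Tensor(self.data.reshape(shape), _parents=(self,))
        out._backward = lambda g: self._accum(g.reshape(self.data.shape))
        return out

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)
        out = Tensor(self.data.transpose(axes), _parents=(self,))
        out._backward = lambda g: self._accum(g.transpose(inv))
        return out

    def __getitem__(self, idx):
        out = Tensor(self.data[idx], _parents=(self,))

        def bw(g):
            full = np.zeros_like(self.data, dtype=g.dtype)
            np.add.at(full, idx, g)
            self._accum(full)

        out._backward = bw
        return out

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"


# ------------------------------------------------------------------ functions
def concat(tensors: list, axis: int = 0) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), _parents=tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(a, b)
                t._accum(g[tuple(sl)])

    out._backward = bw
    return out


def stack(tensors: list, axis: int = 0) -> Tensor:
    expanded = []
    for t in tensors:
        t = Tensor._lift(t)
        sh = list(t.data.shape)
        sh.insert(axis if axis >= 0 else axis + t.ndim + 1, 1)
        expanded.append(t.reshape(sh))
    return concat(expanded, axis=axis)


def softmax(x: Tensor, axis: int = -1, additive_mask: np.ndarray | None = None) -> Tensor:
    """Numerically stable softmax; `additive_mask` (e.g. -inf on padding) is a constant."""
    if additive_mask is not None:
        x = x + Tensor(additive_mask)
    shift = Tensor(np.max(x.data, axis=axis, keepdims=True))  # constant shift
    e = (x - shift).exp()
    return e / e.sum(axis=axis, keepdims=True)


def sigmoid(x: Tensor) -> Tensor:
    # expressed through tanh for a single stable primitive
    return (x * 0.5).tanh() * 0.5 + 0.5


def gelu(x: Tensor) -> Tensor:
    # tanh approximation
    c = float(np.sqrt(2.0 / np.pi))
    return x * 0.5 * ((c * (x + x**3 * 0.044715)).tanh() + 1.0)


def layer_norm(x: Tensor, gain: Tensor, bias: Tensor, eps: float = 1e-5) -> Tensor:
    mu = x.mean(axis=-1, keepdims=True)
    xc = x - mu
    var = (xc**2).mean(axis=-1, keepdims=True)
    return xc / ((var + eps) ** 0.5) * gain + bias
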