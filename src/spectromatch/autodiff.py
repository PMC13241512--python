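"""Minimal reverse-mode automatic differentiation over NumPy arrays.

Supports exactly the operations the spectrum/molecule encoders and the
contrastive loss need: broadcasting arithmetic, (batched) matrix products,
elementwise nonlinearities, axis reductions, reshapes and embedding lookups.
Gradients are accumulated in float64 for reproducibility; correctness is
covered by numerical gradient checks in the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "Adam", "parameter", "constant"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape`, inverting NumPy broadcasting."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A node in the computation graph wrapping a float64 ndarray."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents = tuple(parents)
        self._backward = backward

    # ---- graph plumbing -------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    @staticmethod
    def _wrap(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def _needs(self, *others: "Tensor") -> bool:
        return self.requires_grad or any(o.requires_grad for o in others)

    # ---- arithmetic -----------------------------------------------------

    def __add__(self, other):
        other = self._wrap(other)
        out_data = self.data + other.data

        def bwd(g, a=self, b=other):
            if a.requires_grad:
                a._accum(_unbroadcast(g, a.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g, b.shape))

        if self._needs(other):
            return Tensor(out_data, True, (self, other), bwd)
        return Tensor(out_data)

    __radd__ = __add__

    def __neg__(self):
        def bwd(g, a=self):
            if a.requires_grad:
                a._accum(-g)

        if self.requires_grad:
            return Tensor(-self.data, True, (self,), bwd)
        return Tensor(-self.data)

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        other = self._wrap(other)
        out_data = self.data * other.data

        def bwd(g, a=self, b=other):
            if a.requires_grad:
                a._accum(_unbroadcast(g * b.data, a.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g * a.data, b.shape))

        if self._needs(other):
            return Tensor(out_data, True, (self, other), bwd)
        return Tensor(out_data)

    __rmul__ = __mul__

    def __truediv__(self, other):
        return self * self._wrap(other).pow(-1.0)

    def pow(self, exponent: float) -> "Tensor":
        out_data = self.data**exponent

        def bwd(g, a=self, e=exponent):
            if a.requires_grad:
                a._accum(g * e * a.data ** (e - 1.0))

        if self.requires_grad:
            return Tensor(out_data, True, (self,), bwd)
        return Tensor(out_data)

    def exp(self) -> "Tensor":
        out_data = np.exp(self.data)

        def bwd(g, a=self, o=out_data):
            if a.requires_grad:
                a._accum(g * o)

        if self.requires_grad:
            return Tensor(out_data, True, (self,), bwd)
        return Tensor(out_data)

    def log(self) -> "Tensor":
        def bwd(g, a=self):
            if a.requires_grad:
                a._accum(g / a.data)

        if self.requires_grad:
            return Tensor(np.log(self.data), True, (self,), bwd)
        return Tensor(np.log(self.data))

    def relu(self) -> "Tensor":
        mask = self.data > 0

        def bwd(g, a=self, m=mask):
            if a.requires_grad:
                a._accum(g * m)

        if self.requires_grad:
            return Tensor(self.data * mask, True, (self,), bwd)
        return Tensor(self.data * mask)

    # ---- linear algebra -------------------------------------------------

    def matmul(self, other: "Tensor") -> "Tensor":
        other = self._wrap(other)
        out_data = self.data @ other.data

        def bwd(g, a=self, b=other):
            if a.requires_grad:
                ga = g @ np.swapaxes(b.data, -1, -2)
                a._accum(_unbroadcast(ga, a.shape))
            if b.requires_grad:
                gb = np.swapaxes(a.data, -1, -2) @ g
                b._accum(_unbroadcast(gb, b.shape))

        if self._needs(other):
            return Tensor(out_data, True, (self, other), bwd)
        return Tensor(out_data)

    __matmul__ = matmul

    def swapaxes(self, ax1: int, ax2: int) -> "Tensor":
        def bwd(g, a=self):
            if a.requires_grad:
                a._accum(np.swapaxes(g, ax1, ax2))

        if self.requires_grad:
            return Tensor(np.swapaxes(self.data, ax1, ax2), True, (self,), bwd)
        return Tensor(np.swapaxes(self.data, ax1, ax2))

    def reshape(self, *shape) -> "Tensor":
        orig = self.shape

        def bwd(g, a=self):
            if a.requires_grad:
                a._accum(g.reshape(orig))

        if self.requires_grad:
            return Tensor(self.data.reshape(*shape), True, (self,), bwd)
        return Tensor(self.data.reshape(*shape))

    # ---- reductions -----------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def bwd(g, a=self):
            if not a.requires_grad:
                return
            if axis is None:
                a._accum(np.broadcast_to(g, a.shape).copy())
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                a._accum(np.broadcast_to(gg, a.shape).copy())

        if self.requires_grad:
            return Tensor(out_data, True, (self,), bwd)
        return Tensor(out_data)

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # ---- lookup ---------------------------------------------------------

    def take_rows(self, idx: np.ndarray) -> "Tensor":
        """Embedding lookup: rows of a 2-D table by an integer index array."""
        idx = np.asarray(idx)
        out_data = self.data[idx]

        def bwd(g, a=self, i=idx):
            if a.requires_grad:
                if a.grad is None:
                    a.grad = np.zeros_like(a.data)
                np.add.at(a.grad, i.reshape(-1), g.reshape(-1, a.data.shape[1]))

        if self.requires_grad:
            return Tensor(out_data, True, (self,), bwd)
        return Tensor(out_data)

    # ---- composites -----------------------------------------------------

    def l2_normalize(self, eps: float = 1e-12) -> "Tensor":
        norm_sq = (self * self).sum(axis=-1, keepdims=True) + eps
        return self * norm_sq.pow(-0.5)

    def softmax_lastaxis(self) -> "Tensor":
        # stabilised with a detached max; gradient is exact
        m = self.data.max(axis=-1, keepdims=True)
        e = (self - m).exp()
        return e / e.sum(axis=-1, keepdims=True)

    def logsumexp_lastaxis(self) -> "Tensor":
        m = self.data.max(axis=-1, keepdims=True)
        return (self - m).exp().sum(axis=-1, keepdims=True).log() + m

    def item(self) -> float:
        return float(self.data)


def parameter(data) -> Tensor:
    return Tensor(data, requires_grad=True)


def constant(data) -> Tensor:
    return Tensor(data)


class Adam:
    """Adam optimizer over a flat list of parameter tensors."""

    def __init__(self, params: list[Tensor], lr: float = 1e-4,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.beta1 * self.m[i] + (1 - self.beta1) * g
            self.v[i] = self.beta2 * self.v[i] + (1 - self.beta2) * g * g
            mhat = self.m[i] / b1t
            vhat = self.v[i] / b2t
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
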