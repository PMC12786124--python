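"""Minimal reverse-mode automatic differentiation on NumPy arrays.

Supports exactly the operations the package's neural layers need:
broadcasting arithmetic, matmul, the usual pointwise nonlinearities,
axis reductions, reshapes/transposes, slicing and concatenation.
Float32 throughout; gradients accumulate into ``Tensor.grad``.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concatenate"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward = None
        self._prev: tuple[Tensor, ...] = ()

    # -- construction helpers -------------------------------------------------

    @staticmethod
    def _from_op(data: np.ndarray, prev, backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in prev):
            out.requires_grad = True
            out._prev = tuple(prev)
            out._backward = backward
        return out

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    # -- arithmetic -----------------------------------------------------------

    def _coerce(self, other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def __add__(self, other):
        other = self._coerce(other)

        def backward(g, a=self, b=other):
            if a.requires_grad:
                a._accum(_unbroadcast(g, a.data.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g, b.data.shape))

        return Tensor._from_op(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g, a=self):
            if a.requires_grad:
                a._accum(-g)

        return Tensor._from_op(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-self._coerce(other))

    def __rsub__(self, other):
        return self._coerce(other) + (-self)

    def __mul__(self, other):
        other = self._coerce(other)

        def backward(g, a=self, b=other):
            if a.requires_grad:
                a._accum(_unbroadcast(g * b.data, a.data.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g * a.data, b.data.shape))

        return Tensor._from_op(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._coerce(other)

        def backward(g, a=self, b=other):
            if a.requires_grad:
                a._accum(_unbroadcast(g / b.data, a.data.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(-g * a.data / (b.data * b.data), b.data.shape))

        return Tensor._from_op(self.data / other.data, (self, other), backward)

    def __pow__(self, p: float):
        def backward(g, a=self):
            if a.requires_grad:
                a._accum(g * p * a.data ** (p - 1))

        return Tensor._from_op(self.data**p, (self,), backward)

    def __matmul__(self, other):
        other = self._coerce(other)
        A, B = self.data, other.data

        if A.ndim > 2 and B.ndim == 2:
            # (..., k) @ (k, n): flatten to one GEMM
            lead = A.shape[:-1]
            A2 = A.reshape(-1, A.shape[-1])
            out = (A2 @ B).reshape(*lead, B.shape[1])

            def backward(g, a=self, b=other, A2=A2, B=B):
                g2 = g.reshape(-1, g.shape[-1])
                if a.requires_grad:
                    a._accum((g2 @ B.T).reshape(a.data.shape))
                if b.requires_grad:
                    b._accum(A2.T @ g2)

            return Tensor._from_op(out, (self, other), backward)

        if A.ndim == 2 and B.ndim > 2:
            # (m, k) @ (..., k, n): move the contraction axis out, one GEMM
            m, k = A.shape
            Bt = np.moveaxis(B, -2, 0).reshape(k, -1)      # (k, batch*n)
            out2 = A @ Bt                                   # (m, batch*n)
            out = np.moveaxis(out2.reshape(m, *B.shape[:-2], B.shape[-1]), 0, -2)

            def backward(g, a=self, b=other, A=A, Bt=Bt, m=m, k=k):
                g2 = np.moveaxis(g, -2, 0).reshape(m, -1)
                if a.requires_grad:
                    a._accum(g2 @ Bt.T)
                if b.requires_grad:
                    gb = (A.T @ g2).reshape(k, *b.data.shape[:-2], b.data.shape[-1])
                    b._accum(np.moveaxis(gb, 0, -2))

            return Tensor._from_op(out, (self, other), backward)

        def backward(g, a=self, b=other):
            if a.requires_grad:
                ga = g @ np.swapaxes(b.data, -1, -2)
                a._accum(_unbroadcast(ga, a.data.shape))
            if b.requires_grad:
                gb = np.swapaxes(a.data, -1, -2) @ g
                b._accum(_unbroadcast(gb, b.data.shape))

        return Tensor._from_op(self.data @ other.data, (self, other), backward)

    # -- pointwise nonlinearities ---------------------------------------------

    def exp(self):
        out_data = np.exp(self.data)

        def backward(g, a=self, o=out_data):
            if a.requires_grad:
                a._accum(g * o)

        return Tensor._from_op(out_data, (self,), backward)

    def log(self):
        def backward(g, a=self):
            if a.requires_grad:
                a._accum(g / a.data)

        return Tensor._from_op(np.log(self.data), (self,), backward)

    def tanh(self):
        out_data = np.tanh(self.data)

        def backward(g, a=self, o=out_data):
            if a.requires_grad:
                a._accum(g * (1.0 - o * o))

        return Tensor._from_op(out_data, (self,), backward)

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-self.data))

        def backward(g, a=self, o=out_data):
            if a.requires_grad:
                a._accum(g * o * (1.0 - o))

        return Tensor._from_op(out_data, (self,), backward)

    def relu(self):
        mask = self.data > 0

        def backward(g, a=self, m=mask):
            if a.requires_grad:
                a._accum(g * m)

        return Tensor._from_op(self.data * mask, (self,), backward)

    def silu(self):
        sig = 1.0 / (1.0 + np.exp(-self.data))
        out_data = self.data * sig

        def backward(g, a=self, s=sig):
            if a.requires_grad:
                a._accum(g * (s * (1.0 + a.data * (1.0 - s))))

        return Tensor._from_op(out_data, (self,), backward)

    def maximum(self, other):
        other = self._coerce(other)
        # ties route the gradient to ``self`` (subgradient choice)
        mask = self.data >= other.data

        def backward(g, a=self, b=other, m=mask):
            if a.requires_grad:
                a._accum(_unbroadcast(g * m, a.data.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g * (~m), b.data.shape))

        return Tensor._from_op(np.maximum(self.data, other.data), (self, other), backward)

    # -- reductions -----------------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        def backward(g, a=self):
            if not a.requires_grad:
                return
            if axis is None:
                a._accum(np.broadcast_to(g, a.data.shape).copy())
            else:
                if not keepdims:
                    g = np.expand_dims(g, axis)
                a._accum(np.broadcast_to(g, a.data.shape).copy())

        return Tensor._from_op(self.data.sum(axis=axis, keepdims=keepdims), (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            n = self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- shape ops ------------------------------------------------------------

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.data.shape

        def backward(g, a=self, o=old):
            if a.requires_grad:
                a._accum(g.reshape(o))

        return Tensor._from_op(self.data.reshape(shape), (self,), backward)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)

        def backward(g, a=self, inv=tuple(inv)):
            if a.requires_grad:
                a._accum(g.transpose(inv))

        return Tensor._from_op(self.data.transpose(axes), (self,), backward)

    def __getitem__(self, idx):
        def backward(g, a=self, idx=idx):
            if a.requires_grad:
                full = np.zeros_like(a.data)
                np.add.at(full, idx, g)
                a._accum(full)

        return Tensor._from_op(self.data[idx], (self,), backward)

    # -- composites -----------------------------------------------------------

    def softmax(self, axis: int = -1):
        shifted = self - Tensor(self.data.max(axis=axis, keepdims=True))
        # clamp the tail: exp of anything below -60 would land in the
        # float32 subnormal range, and subnormal arithmetic is an order
        # of magnitude slower on x86; the clamped probabilities (<1e-26)
        # and their gradients are numerically zero either way
        shifted = shifted.maximum(Tensor(np.float32(-60.0)))
        e = shifted.exp()
        return e / e.sum(axis=axis, keepdims=True)

    def log_softmax(self, axis: int = -1):
        shifted = self - Tensor(self.data.max(axis=axis, keepdims=True))
        return shifted - shifted.exp().sum(axis=axis, keepdims=True).log()

    # -- backprop -------------------------------------------------------------

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.astype(np.float32, copy=True)
        else:
            self.grad += g

    def backward(self, grad: np.ndarray | None = None) -> None:
        topo: list[Tensor] = []
        visited: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in visited:
                continue
            visited.add(id(node))
            stack.append((node, True))
            for child in node._prev:
                if id(child) not in visited and child.requires_grad:
                    stack.append((child, False))
        if grad is None:
            grad = np.ones_like(self.data)
        self.grad = np.asarray(grad, dtype=np.float32)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)


def concatenate(tensors: list[Tensor], axis: int = -1) -> Tensor:
    datas = [t.data for t in tensors]
    sizes = [d.shape[axis] for d in datas]
    offsets = np.cumsum([0] + sizes)

    def backward(g, ts=tensors, offs=offsets, ax=axis):
        for t, lo, hi in zip(ts, offs[:-1], offs[1:]):
            if t.requires_grad:
                idx = [slice(None)] * g.ndim
                idx[ax] = slice(lo, hi)
                t._accum(g[tuple(idx)])

    return Tensor._from_op(np.concatenate(datas, axis=axis), tuple(tensors), backward)
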