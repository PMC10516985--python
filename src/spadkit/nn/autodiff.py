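"""A compact reverse-mode automatic-differentiation core on numpy arrays.

Provides exactly the operator set the gated-fusion transformer needs:
broadcasting arithmetic, matmul (batched), reshape/transpose/concat/roll,
reductions, stable softmax, tanh, and a stride-1 2-D convolution (im2col).
Gradients are accumulated by topological sort over the recorded graph.

Arrays are float64 throughout: the models here are small and run on CPU,
where the extra precision is free and makes gradient checks tight.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "conv2d", "no_grad"]


class _NoGrad:
    """Context manager disabling graph recording (inference mode)."""

    _enabled = True

    def __enter__(self):
        self._prev = _NoGrad._enabled
        _NoGrad._enabled = False
        return self

    def __exit__(self, *exc):
        _NoGrad._enabled = self._prev
        return False


def no_grad() -> _NoGrad:
    return _NoGrad()


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum a gradient down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum away leading axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, size in enumerate(shape):
        if size == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False,
                 _parents: tuple = (), _backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = requires_grad and _NoGrad._enabled
        self.grad: np.ndarray | None = None
        self._parents = _parents if self.requires_grad else ()
        self._backward = _backward if self.requires_grad else None

    # ---- construction helpers -------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    @property
    def size(self) -> int:
        return self.data.size

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def __repr__(self) -> str:
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    # ---- autograd engine -------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        if not self.requires_grad:
            raise RuntimeError("backward() on a tensor that does not require grad")
        if grad is None:
            if self.size != 1:
                raise RuntimeError("backward() without an explicit gradient "
                                   "is only defined for scalar outputs")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS: graphs can exceed the recursion limit
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
        self.grad = grad.astype(np.float64)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = grad.copy()
        else:
            self.grad += grad

    def zero_grad(self) -> None:
        self.grad = None

    # ---- arithmetic ------------------------------------------------------
    @staticmethod
    def _lift(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def __add__(self, other):
        other = self._lift(other)
        out = Tensor(self.data + other.data,
                     self.requires_grad or other.requires_grad,
                     (self, other))

        def _bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.shape))
        out._backward = _bw
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, self.requires_grad, (self,))
        out._backward = lambda g: self._accumulate(-g) if self.requires_grad else None
        return out

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        out = Tensor(self.data * other.data,
                     self.requires_grad or other.requires_grad,
                     (self, other))

        def _bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.shape))
        out._backward = _bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)
        return self * other ** -1.0

    def __rtruediv__(self, other):
        return self._lift(other) * self ** -1.0

    def __pow__(self, exponent: float):
        out = Tensor(self.data ** exponent, self.requires_grad, (self,))

        def _bw(g):
            self._accumulate(g * exponent * self.data ** (exponent - 1.0))
        out._backward = _bw
        return out

    def __matmul__(self, other):
        other = self._lift(other)
        out = Tensor(self.data @ other.data,
                     self.requires_grad or other.requires_grad,
                     (self, other))

        def _bw(g):
            if self.requires_grad:
                ga = g @ np.swapaxes(other.data, -1, -2)
                self._accumulate(_unbroadcast(ga, self.shape))
            if other.requires_grad:
                gb = np.swapaxes(self.data, -1, -2) @ g
                other._accumulate(_unbroadcast(gb, other.shape))
        out._backward = _bw
        return out

    # ---- elementwise functions ------------------------------------------
    def exp(self):
        y = np.exp(self.data)
        out = Tensor(y, self.requires_grad, (self,))
        out._backward = lambda g: self._accumulate(g * y)
        return out

    def log(self):
        out = Tensor(np.log(self.data), self.requires_grad, (self,))
        out._backward = lambda g: self._accumulate(g / self.data)
        return out

    def sqrt(self):
        y = np.sqrt(self.data)
        out = Tensor(y, self.requires_grad, (self,))
        out._backward = lambda g: self._accumulate(g * 0.5 / y)
        return out

    def abs(self):
        out = Tensor(np.abs(self.data), self.requires_grad, (self,))
        out._backward = lambda g: self._accumulate(g * np.sign(self.data))
        return out

    def tanh(self):
        y = np.tanh(self.data)
        out = Tensor(y, self.requires_grad, (self,))
        out._backward = lambda g: self._accumulate(g * (1.0 - y * y))
        return out

    def relu(self):
        mask = self.data > 0
        out = Tensor(self.data * mask, self.requires_grad, (self,))
        out._backward = lambda g: self._accumulate(g * mask)
        return out

    # ---- shape ops -------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = Tensor(self.data.reshape(shape), self.requires_grad, (self,))
        out._backward = lambda g: self._accumulate(g.reshape(self.shape))
        return out

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = tuple(np.argsort(axes))
        out = Tensor(self.data.transpose(axes), self.requires_grad, (self,))
        out._backward = lambda g: self._accumulate(g.transpose(inv))
        return out

    def roll(self, shifts, axes):
        out = Tensor(np.roll(self.data, shifts, axis=axes),
                     self.requires_grad, (self,))
        neg = tuple(-s for s in np.atleast_1d(shifts))
        out._backward = lambda g: self._accumulate(np.roll(g, neg, axis=axes))
        return out

    # ---- reductions ------------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims),
                     self.requires_grad, (self,))

        def _bw(g):
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.shape).copy())
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.shape).copy())
        out._backward = _bw
        return out

    def mean(self, axis=None, keepdims=False):
        if axis is None:
            denom = self.size
        else:
            axes = (axis,) if isinstance(axis, int) else tuple(axis)
            denom = int(np.prod([self.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / denom)

    def softmax(self, axis: int = -1):
        z = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(z)
        y = e / e.sum(axis=axis, keepdims=True)
        out = Tensor(y, self.requires_grad, (self,))

        def _bw(g):
            dot = (g * y).sum(axis=axis, keepdims=True)
            self._accumulate(y * (g - dot))
        out._backward = _bw
        return out


def concat(tensors: list[Tensor], axis: int = 0) -> Tensor:
    data = np.concatenate([t.data for t in tensors], axis=axis)
    requires = any(t.requires_grad for t in tensors)
    out = Tensor(data, requires, tuple(tensors))
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def _bw(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                idx = [slice(None)] * g.ndim
                idx[axis] = slice(lo, hi)
                t._accumulate(g[tuple(idx)])
    out._backward = _bw
    return out


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None,
           padding: int = 0) -> Tensor:
    """Stride-1 2-D convolution (cross-correlation), NCHW layout.

    ``x``: (N, C, H, W); ``w``: (O, C, kh, kw); ``b``: (O,) or None.
    Implemented as im2col + matmul; the column matrix is cached for the
    backward pass.
    """
    n, c, h, width = x.shape
    o, c_w, kh, kw = w.shape
    if c != c_w:
        raise ValueError(f"input channels {c} != weight channels {c_w}")
    xp = x.data
    if padding:
        xp = np.pad(xp, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    ho = xp.shape[2] - kh + 1
    wo = xp.shape[3] - kw + 1
    if ho < 1 or wo < 1:
        raise ValueError(
            f"kernel {kh}x{kw} larger than (padded) input {xp.shape[2]}x{xp.shape[3]}"
        )
    windows = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(2, 3))
    # (N, C, Ho, Wo, kh, kw) -> (N, Ho*Wo, C*kh*kw)
    cols = np.ascontiguousarray(windows.transpose(0, 2, 3, 1, 4, 5)
                                ).reshape(n, ho * wo, c * kh * kw)
    w_mat = w.data.reshape(o, c * kh * kw)
    out_data = cols @ w_mat.T  # (N, L, O)
    if b is not None:
        out_data = out_data + b.data
    out_data = out_data.transpose(0, 2, 1).reshape(n, o, ho, wo)

    parents = (x, w) if b is None else (x, w, b)
    requires = any(t.requires_grad for t in parents)
    out = Tensor(out_data, requires, parents)

    def _bw(g):
        gl = g.reshape(n, o, ho * wo).transpose(0, 2, 1)  # (N, L, O)
        if b is not None and b.requires_grad:
            b._accumulate(gl.sum(axis=(0, 1)))
        if w.requires_grad:
            gw = np.einsum("nlk,nlo->ok", cols, gl)
            w._accumulate(gw.reshape(o, c, kh, kw))
        if x.requires_grad:
            gcols = (gl @ w_mat).reshape(n, ho, wo, c, kh, kw)
            gxp = np.zeros_like(xp)
            for i in range(kh):
                for j in range(kw):
                    gxp[:, :, i:i + ho, j:j + wo] += gcols[:, :, :, :, i, j
                                                          ].transpose(0, 3, 1, 2)
            if padding:
                gxp = gxp[:, :, padding:-padding, padding:-padding]
            x._accumulate(gxp)
    out._backward = _bw
    return out
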