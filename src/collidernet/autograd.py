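"""Minimal reverse-mode automatic differentiation over numpy arrays.

Implements exactly the operations the constrained CNN needs: broadcast
arithmetic, matmul, ReLU, reshape/transpose/slicing, reductions, 3x3
same-padding convolution, 2x2 max-pooling, and a symmetric linear solve
whose gradient flows through the in-minibatch least-squares fit of the
independence regularizer.  Gradients are accumulated by topological
traversal of the recorded graph; every operation is checked against
central finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "conv2d", "maxpool2x2", "solve_sym"]


def _as_array(x) -> np.ndarray:
    return x.data if isinstance(x, Tensor) else np.asarray(x, dtype=np.float64)


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
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
    """A numpy array with an optional gradient tape."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        data = np.asarray(data)
        if data.dtype != np.float32:  # float32 preserved for speed, rest promoted
            data = data.astype(np.float64, copy=False)
        self.data = data
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple = ()
        self._backward = None

    # -- graph plumbing ----------------------------------------------------

    @classmethod
    def _node(cls, data, parents, backward) -> "Tensor":
        out = cls(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def backward(self, grad=None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar")
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(node):
            if id(node) in seen or not node.requires_grad:
                return
            seen.add(id(node))
            for p in node._parents:
                visit(p)
            topo.append(node)

        visit(self)
        grads = {id(self): np.asarray(grad, dtype=self.data.dtype)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node._backward is None:
                node.grad = g if node.grad is None else node.grad + g
                continue
            for parent, pg in zip(node._parents, node._backward(g)):
                if not parent.requires_grad or pg is None:
                    continue
                key = id(parent)
                grads[key] = pg if key not in grads else grads[key] + pg
        # leaves reached through the loop above already stored their grads

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    # -- arithmetic --------------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    def _coerce(self, other) -> "Tensor":
        if isinstance(other, Tensor):
            return other
        arr = np.asarray(other)
        if arr.ndim == 0 and arr.dtype != self.data.dtype:
            arr = arr.astype(self.data.dtype)  # scalars follow the tensor dtype
        return Tensor(arr)

    def __add__(self, other):
        o = self._coerce(other)
        data = self.data + o.data
        return Tensor._node(
            data,
            (self, o),
            lambda g: (_unbroadcast(g, self.data.shape), _unbroadcast(g, o.data.shape)),
        )

    __radd__ = __add__

    def __neg__(self):
        return Tensor._node(-self.data, (self,), lambda g: (-g,))

    def __sub__(self, other):
        return self + (-self._coerce(other))

    def __rsub__(self, other):
        return Tensor(other) + (-self)

    def __mul__(self, other):
        o = self._coerce(other)
        data = self.data * o.data
        return Tensor._node(
            data,
            (self, o),
            lambda g: (
                _unbroadcast(g * o.data, self.data.shape),
                _unbroadcast(g * self.data, o.data.shape),
            ),
        )

    __rmul__ = __mul__

    def __truediv__(self, other):
        o = self._coerce(other)
        data = self.data / o.data
        return Tensor._node(
            data,
            (self, o),
            lambda g: (
                _unbroadcast(g / o.data, self.data.shape),
                _unbroadcast(-g * self.data / o.data**2, o.data.shape),
            ),
        )

    def __pow__(self, p: float):
        data = self.data**p
        return Tensor._node(data, (self,), lambda g: (g * p * self.data ** (p - 1),))

    def __matmul__(self, other):
        o = self._coerce(other)
        a, b = self.data, o.data
        data = a @ b

        def backward(g):
            if a.ndim == 1 and b.ndim == 1:  # inner product
                return g * b, g * a
            if a.ndim == 1:  # (k,) @ (k,m)
                return g @ b.T, np.outer(a, g)
            if b.ndim == 1:  # (n,k) @ (k,)
                return np.outer(g, b), a.T @ g
            return g @ b.swapaxes(-1, -2), a.swapaxes(-1, -2) @ g

        return Tensor._node(data, (self, o), backward)

    # -- shape ops ---------------------------------------------------------

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.data.shape
        return Tensor._node(
            self.data.reshape(shape), (self,), lambda g: (g.reshape(old),)
        )

    def transpose(self, *axes):
        axes = axes or tuple(reversed(range(self.data.ndim)))
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)
        return Tensor._node(
            self.data.transpose(axes), (self,), lambda g: (g.transpose(inv),)
        )

    @property
    def T(self):
        return self.transpose()

    def __getitem__(self, key):
        data = self.data[key]

        def backward(g):
            out = np.zeros_like(self.data)
            np.add.at(out, key, g)
            return (out,)

        return Tensor._node(data, (self,), backward)

    # -- nonlinearities and reductions ------------------------------------

    def relu(self):
        mask = self.data > 0
        return Tensor._node(self.data * mask, (self,), lambda g: (g * mask,))

    def sum(self, axis=None, keepdims=False):
        data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            if axis is None:
                return (np.broadcast_to(g, self.data.shape).copy(),)
            g2 = g if keepdims else np.expand_dims(g, axis)
            return (np.broadcast_to(g2, self.data.shape).copy(),)

        return Tensor._node(data, (self,), backward)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)


def concat(tensors, axis: int = 0) -> Tensor:
    tensors = [t if isinstance(t, Tensor) else Tensor(t) for t in tensors]
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        return tuple(np.split(g, splits, axis=axis))

    return Tensor._node(data, tensors, backward)


# ---------------------------------------------------------------------------
# Convolution / pooling


def conv2d(x: Tensor, w: Tensor, b: Tensor, pad: int = 1) -> Tensor:
    """Same-padding 2-D convolution (cross-correlation convention).

    ``x``: (N, C, H, W); ``w``: (O, C, k, k); ``b``: (O,).  Implemented
    as an accumulation of k*k shifted tensordots so every inner product
    runs through BLAS without materializing an im2col matrix.
    """
    k = w.data.shape[-1]
    n, _, h, wd = x.data.shape
    ho, wo = h + 2 * pad - k + 1, wd + 2 * pad - k + 1
    xp = np.pad(x.data, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    acc = np.zeros((n, ho, wo, w.data.shape[0]), dtype=np.result_type(xp, w.data))
    for i in range(k):
        for j in range(k):
            # (N, C, ho, wo) . (O, C) summed over C -> (N, ho, wo, O)
            acc += np.tensordot(
                xp[:, :, i : i + ho, j : j + wo], w.data[:, :, i, j], axes=([1], [1])
            )
    data = (acc + b.data).transpose(0, 3, 1, 2)

    def backward(g):
        db = g.sum(axis=(0, 2, 3))
        dw = np.empty_like(w.data)
        for i in range(k):
            for j in range(k):
                dw[:, :, i, j] = np.tensordot(
                    g, xp[:, :, i : i + ho, j : j + wo], axes=([0, 2, 3], [0, 2, 3])
                )
        dx = None
        if x.requires_grad:
            dxp = np.zeros_like(xp)
            for i in range(k):
                for j in range(k):
                    dxp[:, :, i : i + ho, j : j + wo] += np.tensordot(
                        g, w.data[:, :, i, j], axes=([1], [0])
                    ).transpose(0, 3, 1, 2)
            dx = dxp[:, :, pad : pad + h, pad : pad + wd] if pad else dxp
        return dx, dw, db

    return Tensor._node(data, (x, w, b), backward)


def maxpool2x2(x: Tensor) -> Tensor:
    """2x2 max-pool, stride 2, floor mode (odd trailing row/col dropped).

    Within-window ties share the incoming gradient (a valid subgradient;
    ties have measure zero for continuous inputs, and tied zeros are
    blocked by the preceding ReLU anyway).
    """
    n, c, h, w = x.data.shape
    hc, wc = h // 2, w // 2
    # (hc, 2, wc, 2) reshapes to (2hc, 2wc) and back as pure views
    r = x.data[:, :, : 2 * hc, : 2 * wc].reshape(n, c, hc, 2, wc, 2)
    data = r.max(axis=(3, 5))
    mask = r == data[:, :, :, None, :, None]

    def backward(g):
        d = np.where(mask, g[:, :, :, None, :, None], np.zeros((), dtype=g.dtype))
        if 2 * hc == h and 2 * wc == w:
            return (d.reshape(n, c, h, w),)
        dx = np.zeros_like(x.data)
        dx[:, :, : 2 * hc, : 2 * wc] = d.reshape(n, c, 2 * hc, 2 * wc)
        return (dx,)

    return Tensor._node(data, (x,), backward)


def solve_sym(a: Tensor, b: Tensor) -> Tensor:
    """Solve the symmetric system ``a @ x = b`` with gradient support.

    For ``x = a^{-1} b``: dL/db = a^{-1} g and dL/da = -(a^{-1} g) x^T.
    """
    sol = np.linalg.solve(a.data, b.data)

    def backward(g):
        gb = np.linalg.solve(a.data, g)
        ga = -np.outer(gb, sol) if sol.ndim == 1 else -gb @ sol.T
        return ga, gb

    return Tensor._node(sol, (a, b), backward)
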