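"""Minimal reverse-mode automatic differentiation on numpy arrays.

This tape-based engine provides exactly the primitives the graph attention
auto-encoder needs: broadcast-aware arithmetic, matrix products, ELU /
sigmoid / exp / log, row gathering and scatter-addition (the sparse
message-passing pair), column concatenation/slicing, reductions and a
numerically safe per-row Euclidean norm.  Gradients accumulate in
``Tensor.grad`` after calling :meth:`Tensor.backward` on a scalar result.
"""

from __future__ import annotations

import numpy as np
from scipy import sparse as _sp

__all__ = ["Tensor", "Parameter"]

# Scatter-addition as a sparse incidence-matrix product: much faster than
# np.add.at for the repeated message-passing pattern.  Matrices are cached
# per (index vector, size); the cache is tiny (one entry per graph role).
_CSR_CACHE: dict = {}


def _incidence(idx: np.ndarray, n: int, dtype) -> _sp.csr_matrix:
    key = (idx.tobytes(), n, np.dtype(dtype).str)
    mat = _CSR_CACHE.get(key)
    if mat is None:
        if len(_CSR_CACHE) > 64:
            _CSR_CACHE.clear()
        e = len(idx)
        mat = _sp.csr_matrix(
            (np.ones(e, dtype=dtype), (idx, np.arange(e))), shape=(n, e)
        )
        _CSR_CACHE[key] = mat
    return mat


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, s in enumerate(shape):
        if s == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """An array node on the autodiff tape.

    Floating dtypes are preserved (float32 inputs stay float32 — the model
    trains in single precision for speed); anything else is promoted to
    float64.  Scalar reductions (:meth:`sum`, :meth:`row_norms`) always
    accumulate in float64 so loss bookkeeping is exact.
    """

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward", "_seq")

    _counter = 0

    def __init__(self, data, requires_grad: bool = False):
        arr = np.asarray(data)
        if arr.dtype not in (np.float32, np.float64):
            arr = arr.astype(np.float64)
        self.data = arr
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents: tuple = ()
        self._backward = None
        Tensor._counter += 1
        self._seq = Tensor._counter

    # -- construction helpers ------------------------------------------------
    @staticmethod
    def _wrap(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    @classmethod
    def _make(cls, data, parents, backward) -> "Tensor":
        out = cls(data, requires_grad=any(p.requires_grad for p in parents))
        if out.requires_grad:
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @property
    def shape(self):
        return self.data.shape

    @property
    def T(self) -> "Tensor":
        return Tensor._make(
            self.data.T, (self,), lambda g, a=self: _accum(a, g.T)
        )

    # -- arithmetic ----------------------------------------------------------
    # Python scalars take a fast path (no wrapping) so float32 data is not
    # silently promoted and no gradient is tracked for the constant.
    def __add__(self, other):
        if isinstance(other, (int, float)):
            return Tensor._make(
                self.data + other,
                (self,),
                lambda g, a=self: _accum(a, _unbroadcast(g, a.data.shape)),
            )
        other = Tensor._wrap(other)

        def back(g, a=self, b=other):
            _accum(a, _unbroadcast(g, a.data.shape))
            _accum(b, _unbroadcast(g, b.data.shape))

        return Tensor._make(self.data + other.data, (self, other), back)

    __radd__ = __add__

    def __neg__(self):
        return Tensor._make(
            -self.data, (self,), lambda g, a=self: _accum(a, -g, own=True)
        )

    def __sub__(self, other):
        if isinstance(other, (int, float)):
            return self + (-other)
        return self + (-Tensor._wrap(other))

    def __rsub__(self, other):
        return (-self) + other

    def __mul__(self, other):
        if isinstance(other, (int, float)):
            return Tensor._make(
                self.data * other,
                (self,),
                lambda g, a=self, k=other: _accum(
                    a, _unbroadcast(g * k, a.data.shape), own=True
                ),
            )
        other = Tensor._wrap(other)

        def back(g, a=self, b=other):
            _accum(a, _unbroadcast(g * b.data, a.data.shape), own=True)
            _accum(b, _unbroadcast(g * a.data, b.data.shape), own=True)

        return Tensor._make(self.data * other.data, (self, other), back)

    __rmul__ = __mul__

    def __truediv__(self, other):
        if isinstance(other, (int, float)):
            return self * (1.0 / other)
        other = Tensor._wrap(other)

        def back(g, a=self, b=other):
            _accum(a, _unbroadcast(g / b.data, a.data.shape), own=True)
            _accum(b, _unbroadcast(-g * a.data / b.data**2, b.data.shape), own=True)

        return Tensor._make(self.data / other.data, (self, other), back)

    def __matmul__(self, other):
        other = Tensor._wrap(other)

        def back(g, a=self, b=other):
            _accum(a, g @ b.data.T, own=True)
            _accum(b, a.data.T @ g, own=True)

        return Tensor._make(self.data @ other.data, (self, other), back)

    # -- nonlinearities ------------------------------------------------------
    def elu(self, alpha: float = 1.0) -> "Tensor":
        x = self.data
        neg = alpha * np.expm1(np.minimum(x, 0.0))
        y = np.where(x > 0, x, neg)

        def back(g, a=self, alpha=alpha, neg=neg, x=x):
            _accum(a, g * np.where(x > 0, 1.0, neg + alpha), own=True)

        return Tensor._make(y, (self,), back)

    def sigmoid(self) -> "Tensor":
        y = 1.0 / (1.0 + np.exp(-self.data))

        def back(g, a=self, y=y):
            _accum(a, g * y * (1.0 - y), own=True)

        return Tensor._make(y, (self,), back)

    def exp(self) -> "Tensor":
        y = np.exp(self.data)

        def back(g, a=self, y=y):
            _accum(a, g * y, own=True)

        return Tensor._make(y, (self,), back)

    def log(self) -> "Tensor":
        def back(g, a=self):
            _accum(a, g / a.data, own=True)

        return Tensor._make(np.log(self.data), (self,), back)

    def clamp(self, lo: float, hi: float) -> "Tensor":
        """Clamp values to [lo, hi]; the gradient is zero outside the band."""
        inside = (self.data >= lo) & (self.data <= hi)

        def back(g, a=self, inside=inside):
            _accum(a, g * inside, own=True)

        return Tensor._make(np.clip(self.data, lo, hi), (self,), back)

    # -- structure -----------------------------------------------------------
    def gather_rows(self, idx: np.ndarray) -> "Tensor":
        idx = np.asarray(idx)
        nrows = self.data.shape[0]

        def back(g, a=self, idx=idx, nrows=nrows):
            _accum(
                a,
                _incidence(idx, nrows, g.dtype) @ np.ascontiguousarray(g),
                own=True,
            )

        return Tensor._make(self.data[idx], (self,), back)

    def scatter_add(self, idx: np.ndarray, n: int) -> "Tensor":
        """out[i] = sum of rows with idx == i; the adjoint of gather_rows."""
        idx = np.asarray(idx)
        out = _incidence(idx, n, self.data.dtype) @ np.ascontiguousarray(self.data)

        def back(g, a=self, idx=idx):
            _accum(a, g[idx], own=True)

        return Tensor._make(out, (self,), back)

    def cols(self, start: int, stop: int) -> "Tensor":
        def back(g, a=self, start=start, stop=stop):
            ga = np.zeros_like(a.data)
            ga[:, start:stop] = g
            _accum(a, ga, own=True)

        return Tensor._make(self.data[:, start:stop], (self,), back)

    @staticmethod
    def concat_cols(a: "Tensor", b: "Tensor") -> "Tensor":
        na = a.data.shape[1]

        def back(g, a=a, b=b, na=na):
            _accum(a, g[:, :na])
            _accum(b, g[:, na:])

        return Tensor._make(np.concatenate([a.data, b.data], axis=1), (a, b), back)

    # -- reductions ----------------------------------------------------------
    def sum(self) -> "Tensor":
        def back(g, a=self):
            _accum(a, np.full(a.data.shape, g, dtype=a.data.dtype), own=True)

        return Tensor._make(self.data.sum(dtype=np.float64), (self,), back)

    def mean_rows(self) -> "Tensor":
        """Column-wise mean over rows: (n, f) -> (f,)."""
        n = self.data.shape[0]

        def back(g, a=self, n=n):
            _accum(
                a,
                np.broadcast_to((g / n).astype(a.data.dtype), a.data.shape).copy(),
                own=True,
            )

        return Tensor._make(self.data.mean(axis=0), (self,), back)

    def row_norms(self, eps: float = 1e-12) -> "Tensor":
        """Euclidean norm of each row in float64; eps-guarded backward."""
        x = self.data.astype(np.float64, copy=False)
        norms = np.sqrt(np.einsum("ij,ij->i", x, x))

        def back(g, a=self, norms=norms, eps=eps):
            scale = (g / np.maximum(norms, eps)).astype(a.data.dtype)
            _accum(a, scale[:, None] * a.data, own=True)

        return Tensor._make(norms, (self,), back)

    # -- autodiff driver -----------------------------------------------------
    def backward(self) -> None:
        """Reverse sweep in decreasing creation order.

        Creation order is a topological order (operands exist before their
        result), and unlike a DFS ordering it does not depend on whether
        additional downstream branches hang off shared nodes — gradient
        accumulation order, and hence float rounding, is reproducible.
        """
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar")
        nodes: list[Tensor] = []
        seen: set[int] = set()
        stack = [self]
        while stack:
            node = stack.pop()
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            nodes.append(node)
            stack.extend(node._parents)
        nodes.sort(key=lambda t: t._seq, reverse=True)
        self.grad = np.ones_like(self.data)
        for node in nodes:
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def item(self) -> float:
        return float(self.data)


def _accum(t: Tensor, g: np.ndarray, own: bool = False) -> None:
    """Accumulate gradient; ``own=True`` promises g is a fresh array that
    the caller will not reuse, allowing storage without a defensive copy."""
    if not t.requires_grad:
        return
    if t.grad is None:
        t.grad = g if own and isinstance(g, np.ndarray) else np.array(g, copy=True)
    else:
        t.grad += g


class Parameter(Tensor):
    """A trainable tensor (requires_grad always on)."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)
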