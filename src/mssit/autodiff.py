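"""Minimal reverse-mode automatic differentiation over numpy arrays.

A :class:`Tensor` wraps a float64 ndarray and records the operation that
produced it; :meth:`Tensor.backward` runs the reverse sweep over the
topologically sorted graph.  The op set is exactly what the transformer
needs: broadcasting arithmetic, (batched) matmul, reshapes/transposes,
reductions, softmax/log-softmax, layer norm, GELU, cyclic roll, 4-fold
token repetition and a scatter-mean.  Gradients are checked against central
finite differences in the test suite.

Shapes follow numpy broadcasting; gradients of broadcast operands are summed
over the broadcast axes.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np
from scipy.special import erf

__all__ = ["Tensor", "concat"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
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
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev", "name", "_grad_owned")

    def __init__(self, data, requires_grad: bool = False, name: str | None = None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self._grad_owned = False
        self.requires_grad = bool(requires_grad)
        self._backward: Callable[[np.ndarray], None] | None = None
        self._prev: tuple[Tensor, ...] = ()
        self.name = name

    # ------------------------------------------------------------------ infra
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        tag = f" name={self.name}" if self.name else ""
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad}{tag})"

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def _make(self, data: np.ndarray, parents: Sequence["Tensor"],
              backward: Callable[[np.ndarray], None]) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._prev = tuple(p for p in parents if p.requires_grad)
            out._backward = backward
        return out

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
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._prev:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.asarray(grad, dtype=np.float64)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accum(self, g: np.ndarray, owned: bool = True) -> None:
        # ``owned`` marks arrays allocated by (and private to) the caller;
        # unowned arrays (views / pass-through grads) are only copied if a
        # second contribution actually arrives.
        if self.grad is None:
            self.grad = g
            self._grad_owned = owned
        elif self._grad_owned:
            self.grad += g
        else:
            self.grad = self.grad + g
            self._grad_owned = True

    def zero_grad(self) -> None:
        self.grad = None

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    # ------------------------------------------------------------- arithmetic
    def __add__(self, other) -> "Tensor":
        a, b = self, self._lift(other)
        out_data = a.data + b.data

        def backward(g: np.ndarray) -> None:
            if a.requires_grad:
                ga = _unbroadcast(g, a.shape)
                a._accum(ga, owned=ga is not g)
            if b.requires_grad:
                gb = _unbroadcast(g, b.shape)
                b._accum(gb, owned=gb is not g)

        return self._make(out_data, (a, b), backward)

    __radd__ = __add__

    def __neg__(self) -> "Tensor":
        a = self

        def backward(g: np.ndarray) -> None:
            a._accum(-g)

        return self._make(-a.data, (a,), backward)

    def __sub__(self, other) -> "Tensor":
        return self + (-self._lift(other))

    def __rsub__(self, other) -> "Tensor":
        return self._lift(other) + (-self)

    def __mul__(self, other) -> "Tensor":
        a, b = self, self._lift(other)
        out_data = a.data * b.data

        def backward(g: np.ndarray) -> None:
            if a.requires_grad:
                a._accum(_unbroadcast(g * b.data, a.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g * a.data, b.shape))

        return self._make(out_data, (a, b), backward)

    __rmul__ = __mul__

    def __truediv__(self, other) -> "Tensor":
        b = self._lift(other)
        return self * b ** -1.0 if isinstance(other, Tensor) else self * (1.0 / b.data)

    def __pow__(self, p: float) -> "Tensor":
        a = self

        def backward(g: np.ndarray) -> None:
            a._accum(g * p * a.data ** (p - 1))

        return self._make(a.data ** p, (a,), backward)

    def __matmul__(self, other) -> "Tensor":
        a, b = self, self._lift(other)
        out_data = a.data @ b.data

        def backward(g: np.ndarray) -> None:
            if a.requires_grad:
                ga = g @ np.swapaxes(b.data, -1, -2)
                a._accum(_unbroadcast(ga, a.shape))
            if b.requires_grad:
                gb = np.swapaxes(a.data, -1, -2) @ g
                b._accum(_unbroadcast(gb, b.shape))

        return self._make(out_data, (a, b), backward)

    # -------------------------------------------------------------- reshaping
    def reshape(self, *shape: int) -> "Tensor":
        a = self
        old = a.shape

        def backward(g: np.ndarray) -> None:
            a._accum(g.reshape(old), owned=False)

        return self._make(a.data.reshape(*shape), (a,), backward)

    def transpose(self, *axes: int) -> "Tensor":
        a = self
        inv = np.argsort(axes)

        def backward(g: np.ndarray) -> None:
            a._accum(g.transpose(*inv), owned=False)

        return self._make(a.data.transpose(*axes), (a,), backward)

    def roll(self, shift: int, axis: int) -> "Tensor":
        a = self

        def backward(g: np.ndarray) -> None:
            a._accum(np.roll(g, -shift, axis=axis))

        return self._make(np.roll(a.data, shift, axis=axis), (a,), backward)

    def repeat(self, n: int, axis: int) -> "Tensor":
        """Repeat each slice along ``axis`` ``n`` times (token -> children upsampling)."""
        a = self
        ax = axis % a.ndim

        def backward(g: np.ndarray) -> None:
            shp = list(a.shape)
            shp[ax:ax + 1] = [a.shape[ax], n]
            a._accum(g.reshape(shp).sum(axis=ax + 1))

        return self._make(np.repeat(a.data, n, axis=ax), (a,), backward)

    # -------------------------------------------------------------- reductions
    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        a = self
        out_data = a.data.sum(axis=axis, keepdims=keepdims)

        def backward(g: np.ndarray) -> None:
            if axis is None:
                a._accum(np.broadcast_to(g, a.shape), owned=False)
                return
            axes = (axis,) if isinstance(axis, int) else tuple(axis)
            gg = g if keepdims else np.expand_dims(g, axes)
            a._accum(np.broadcast_to(gg, a.shape), owned=False)

        return self._make(out_data, (a,), backward)

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        if axis is None:
            n = self.data.size
        else:
            axes = (axis,) if isinstance(axis, int) else tuple(axis)
            n = int(np.prod([self.shape[ax] for ax in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # ------------------------------------------------------------ nonlinearity
    def exp(self) -> "Tensor":
        a = self
        out_data = np.exp(a.data)

        def backward(g: np.ndarray) -> None:
            a._accum(g * out_data)

        return self._make(out_data, (a,), backward)

    def log(self) -> "Tensor":
        a = self

        def backward(g: np.ndarray) -> None:
            a._accum(g / a.data)

        return self._make(np.log(a.data), (a,), backward)

    def gelu(self) -> "Tensor":
        """Exact GELU: x * Phi(x) with the Gaussian CDF."""
        a = self
        x = a.data
        phi = 0.5 * (1.0 + erf(x / np.sqrt(2.0)))
        out_data = x * phi

        def backward(g: np.ndarray) -> None:
            pdf = np.exp(-0.5 * x * x) / np.sqrt(2.0 * np.pi)
            a._accum(g * (phi + x * pdf))

        return self._make(out_data, (a,), backward)

    def softmax(self, axis: int = -1) -> "Tensor":
        a = self
        z = a.data - a.data.max(axis=axis, keepdims=True)
        e = np.exp(z)
        s = e / e.sum(axis=axis, keepdims=True)

        def backward(g: np.ndarray) -> None:
            dot = (g * s).sum(axis=axis, keepdims=True)
            a._accum(s * (g - dot))

        return self._make(s, (a,), backward)

    def log_softmax(self, axis: int = -1) -> "Tensor":
        a = self
        z = a.data - a.data.max(axis=axis, keepdims=True)
        lse = np.log(np.exp(z).sum(axis=axis, keepdims=True))
        out_data = z - lse
        s = np.exp(out_data)

        def backward(g: np.ndarray) -> None:
            a._accum(g - s * g.sum(axis=axis, keepdims=True))

        return self._make(out_data, (a,), backward)

    def layer_norm(self, eps: float = 1e-5) -> "Tensor":
        """Normalise the last axis to zero mean / unit variance (no affine)."""
        a = self
        x = a.data
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        inv = 1.0 / np.sqrt(var + eps)
        y = xc * inv
        n = x.shape[-1]

        def backward(g: np.ndarray) -> None:
            gm = g.mean(axis=-1, keepdims=True)
            gym = (g * y).mean(axis=-1, keepdims=True)
            a._accum(inv * (g - gm - y * gym))

        return self._make(y, (a,), backward)

    # ------------------------------------------------------------ index ops
    def scatter_mean(self, index: np.ndarray, n_out: int, axis: int = -2) -> "Tensor":
        """Average entries sharing an index along ``axis`` (must be -2).

        ``self`` has shape (..., P, K); ``index`` maps each of the P rows to
        one of ``n_out`` output rows; the result (..., n_out, K) holds the
        mean of contributing rows.  Used to reduce patch-corner logits onto
        shared mesh vertices.
        """
        if axis != -2:
            raise ValueError("scatter_mean supports axis=-2 only")
        a = self
        counts = np.bincount(index, minlength=n_out).astype(np.float64)
        if (counts == 0).any():
            raise ValueError("every output row must receive at least one entry")
        out_shape = a.shape[:-2] + (n_out, a.shape[-1])
        flatb = int(np.prod(a.shape[:-2], dtype=np.int64)) if a.ndim > 2 else 1
        src = a.data.reshape(flatb, a.shape[-2], a.shape[-1])
        out = np.zeros((flatb, n_out, a.shape[-1]))
        for b in range(flatb):
            np.add.at(out[b], index, src[b])
        out /= counts[None, :, None]

        def backward(g: np.ndarray) -> None:
            gf = g.reshape(flatb, n_out, a.shape[-1]) / counts[None, :, None]
            a._accum(gf[:, index, :].reshape(a.shape))

        return self._make(out.reshape(out_shape), (a,), backward)


def concat(tensors: Iterable[Tensor], axis: int = -1) -> Tensor:
    """Concatenate tensors along ``axis`` with gradient splitting."""
    ts = [Tensor._lift(t) for t in tensors]
    data = np.concatenate([t.data for t in ts], axis=axis)
    sizes = [t.shape[axis] for t in ts]
    splits = np.cumsum(sizes)[:-1]

    out = Tensor(data)
    if any(t.requires_grad for t in ts):
        out.requires_grad = True
        out._prev = tuple(t for t in ts if t.requires_grad)

        def backward(g: np.ndarray) -> None:
            parts = np.split(g, splits, axis=axis)
            for t, p in zip(ts, parts):
                if t.requires_grad:
                    t._accum(p, owned=False)

        out._backward = backward
    return out
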