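"""Minimal reverse-mode automatic differentiation over numpy arrays.

The engine provides exactly the primitives the sensor-array network needs:
broadcasting arithmetic, matmul (batched), reductions, elementwise
nonlinearities, 1-D convolution/pooling, and a gradient reversal op whose
backward pass multiplies incoming gradients by ``-lambda``.  Gradients are
accumulated by topological traversal of the recorded graph.  Everything is
float64 and single-threaded, so runs are bit-reproducible for a fixed seed.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "grl", "no_grad",
           "set_default_dtype", "get_default_dtype"]

_DEFAULT_DTYPE = np.float32
_GRAD_ENABLED = True


class no_grad:
    """Context manager disabling graph recording (fast inference)."""

    def __enter__(self):
        global _GRAD_ENABLED
        self._prev = _GRAD_ENABLED
        _GRAD_ENABLED = False
        return self

    def __exit__(self, *exc):
        global _GRAD_ENABLED
        _GRAD_ENABLED = self._prev
        return False


def set_default_dtype(dtype):
    """Set the dtype new tensors are created with.

    float32 is the training default; switch to float64 for high-precision
    work such as finite-difference gradient verification.
    """
    global _DEFAULT_DTYPE
    _DEFAULT_DTYPE = np.dtype(dtype).type


def get_default_dtype():
    return _DEFAULT_DTYPE


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Reduce ``grad`` back to ``shape`` after numpy broadcasting."""
    if grad.shape == shape:
        return grad
    # sum over leading added axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, s in enumerate(shape):
        if s == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """An ndarray plus the closure needed to backpropagate through it."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=_DEFAULT_DTYPE)
        self.requires_grad = bool(requires_grad)
        self.grad: np.ndarray | None = None
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def _make(self, data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if _GRAD_ENABLED and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def item(self) -> float:
        return float(self.data)

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- arithmetic -----------------------------------------------------------
    def __add__(self, other):
        other = self._lift(other)
        out = self._make(self.data + other.data, (self, other), None)

        def backward(g):
            return (_unbroadcast(g, self.data.shape), _unbroadcast(g, other.data.shape))

        out._backward = backward
        return out

    __radd__ = __add__

    def __neg__(self):
        out = self._make(-self.data, (self,), None)
        out._backward = lambda g: (-g,)
        return out

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        out = self._make(self.data * other.data, (self, other), None)

        def backward(g):
            return (
                _unbroadcast(g * other.data, self.data.shape),
                _unbroadcast(g * self.data, other.data.shape),
            )

        out._backward = backward
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)
        out = self._make(self.data / other.data, (self, other), None)

        def backward(g):
            return (
                _unbroadcast(g / other.data, self.data.shape),
                _unbroadcast(-g * self.data / other.data**2, other.data.shape),
            )

        out._backward = backward
        return out

    def __rtruediv__(self, other):
        return self._lift(other) / self

    def __pow__(self, p: float):
        out = self._make(self.data**p, (self,), None)
        out._backward = lambda g: (g * p * self.data ** (p - 1),)
        return out

    def __matmul__(self, other):
        other = self._lift(other)
        out = self._make(np.matmul(self.data, other.data), (self, other), None)

        def backward(g):
            a, b = self.data, other.data
            ga = np.matmul(g, np.swapaxes(b, -1, -2)) if b.ndim > 1 else np.multiply.outer(g, b)
            gb = np.matmul(np.swapaxes(a, -1, -2), g) if a.ndim > 1 else np.multiply.outer(a, g)
            return (_unbroadcast(ga, a.shape), _unbroadcast(gb, b.shape))

        out._backward = backward
        return out

    # -- reductions / shaping -------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out = self._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), None)

        def backward(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            return (np.broadcast_to(g, self.data.shape).copy(),)

        out._backward = backward
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def reshape(self, *shape):
        out = self._make(self.data.reshape(*shape), (self,), None)
        out._backward = lambda g: (g.reshape(self.data.shape),)
        return out

    def transpose(self, *axes):
        axes = axes or tuple(reversed(range(self.data.ndim)))
        inv = np.argsort(axes)
        out = self._make(self.data.transpose(axes), (self,), None)
        out._backward = lambda g: (g.transpose(inv),)
        return out

    def swapaxes(self, a: int, b: int):
        axes = list(range(self.data.ndim))
        axes[a], axes[b] = axes[b], axes[a]
        return self.transpose(*axes)

    def __getitem__(self, idx):
        out = self._make(self.data[idx], (self,), None)

        def backward(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            return (full,)

        out._backward = backward
        return out

    # -- elementwise nonlinearities ------------------------------------------
    def exp(self):
        e = np.exp(self.data)
        out = self._make(e, (self,), None)
        out._backward = lambda g: (g * e,)
        return out

    def log(self):
        out = self._make(np.log(self.data), (self,), None)
        out._backward = lambda g: (g / self.data,)
        return out

    def sqrt(self):
        r = np.sqrt(self.data)
        out = self._make(r, (self,), None)
        out._backward = lambda g: (g * 0.5 / r,)
        return out

    def relu(self):
        mask = self.data > 0
        out = self._make(np.where(mask, self.data, 0.0), (self,), None)
        out._backward = lambda g: (g * mask,)
        return out

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-np.clip(self.data, -500, 500)))
        out = self._make(s, (self,), None)
        out._backward = lambda g: (g * s * (1.0 - s),)
        return out

    def tanh(self):
        t = np.tanh(self.data)
        out = self._make(t, (self,), None)
        out._backward = lambda g: (g * (1.0 - t * t),)
        return out

    def softplus(self):
        """log(1 + exp(x)) computed stably; gradient is sigmoid(x)."""
        x = self.data
        val = np.maximum(x, 0.0) + np.log1p(np.exp(-np.abs(x)))
        out = self._make(val, (self,), None)
        out._backward = lambda g: (g / (1.0 + np.exp(-np.clip(x, -500, 500))),)
        return out

    def contiguous(self) -> "Tensor":
        """C-contiguous copy (identity if already contiguous); identity grad."""
        if self.data.flags["C_CONTIGUOUS"]:
            return self
        out = self._make(np.ascontiguousarray(self.data), (self,), None)
        out._backward = lambda g: (g,)
        return out

    # -- fused primitives (single graph node each, for speed) -----------------
    def softmax(self, axis: int = -1):
        s = self.data - self.data.max(axis=axis, keepdims=True)
        np.exp(s, out=s)
        s /= s.sum(axis=axis, keepdims=True)
        out = self._make(s, (self,), None)

        def backward(g):
            inner = (g * s).sum(axis=axis, keepdims=True)
            return (s * (g - inner),)

        out._backward = backward
        return out

    def log_softmax(self, axis: int = -1):
        shifted = self.data - self.data.max(axis=axis, keepdims=True)
        lse = np.log(np.exp(shifted).sum(axis=axis, keepdims=True))
        logp = shifted - lse
        out = self._make(logp, (self,), None)

        def backward(g):
            return (g - np.exp(logp) * g.sum(axis=axis, keepdims=True),)

        out._backward = backward
        return out

    def moment_normalize(self, axes: tuple[int, ...], eps: float):
        """(x - mean) / sqrt(var + eps) over ``axes`` — the core of batch and
        layer normalisation, fused into one graph node."""
        x = self.data
        mu = x.mean(axis=axes, keepdims=True)
        var = x.var(axis=axes, keepdims=True)
        inv = 1.0 / np.sqrt(var + eps)
        xhat = (x - mu) * inv
        out = self._make(xhat, (self,), None)

        def backward(g):
            gm = g.mean(axis=axes, keepdims=True)
            gx = (g * xhat).mean(axis=axes, keepdims=True)
            return (inv * (g - gm - xhat * gx),)

        out._backward = backward
        return out

    # -- structured primitives ------------------------------------------------
    def conv1d(self, weight: "Tensor", bias: "Tensor", padding: int):
        """1-D cross-correlation, stride 1.  x:(N,Cin,L) w:(Cout,Cin,K)."""
        x, w, b = self.data, weight.data, bias.data
        c_out, c_in, k = w.shape
        n, _, length = x.shape
        xp = np.pad(x, ((0, 0), (0, 0), (padding, padding)))
        cols = np.lib.stride_tricks.sliding_window_view(xp, k, axis=2)  # (N,Cin,Lo,K)
        lo = cols.shape[2]
        cols2 = np.ascontiguousarray(cols.transpose(0, 2, 1, 3)).reshape(n, lo, c_in * k)
        w2 = w.reshape(c_out, c_in * k).T  # (Cin*K, Cout)
        y = (cols2 @ w2).transpose(0, 2, 1) + b[None, :, None]
        out = self._make(y, (self, weight, bias), None)

        def backward(g):
            g2 = np.ascontiguousarray(g.transpose(0, 2, 1))  # (N, Lo, Cout)
            gw = (g2.reshape(-1, c_out).T @ cols2.reshape(-1, c_in * k)).reshape(w.shape)
            gb = g.sum(axis=(0, 2))
            gcols = (g2 @ w2.T).reshape(n, lo, c_in, k).transpose(0, 2, 1, 3)
            gxp = np.zeros_like(xp)
            for kk in range(k):
                gxp[:, :, kk : kk + lo] += gcols[:, :, :, kk]
            gx = gxp[:, :, padding : padding + length] if padding else gxp
            return (gx, gw, gb)

        out._backward = backward
        return out

    def maxpool1d(self, kernel: int = 2):
        """Non-overlapping max pooling along the last axis (stride = kernel)."""
        x = self.data
        n, c, length = x.shape
        lo = length // kernel
        xr = x[:, :, : lo * kernel].reshape(n, c, lo, kernel)
        arg = xr.argmax(axis=3)
        out = self._make(xr.max(axis=3), (self,), None)

        def backward(g):
            gx = np.zeros_like(xr)
            idx = np.indices((n, c, lo))
            gx[idx[0], idx[1], idx[2], arg] = g
            full = np.zeros_like(x)
            full[:, :, : lo * kernel] = gx.reshape(n, c, lo * kernel)
            return (full,)

        out._backward = backward
        return out

    # -- backward engine ------------------------------------------------------
    def backward(self, grad: np.ndarray | None = None):
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
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))

        grads: dict[int, np.ndarray] = {
            id(self): np.asarray(grad, dtype=self.data.dtype)
        }
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node.grad is None:
                node.grad = g
            else:
                node.grad = node.grad + g
            if node._backward is None:
                continue
            for parent, pg in zip(node._parents, node._backward(g)):
                if not parent.requires_grad:
                    continue
                if id(parent) in grads:
                    grads[id(parent)] = grads[id(parent)] + pg
                else:
                    grads[id(parent)] = pg


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    """Concatenate along ``axis`` with gradient routed back by slicing."""
    datas = [t.data for t in tensors]
    out_data = np.concatenate(datas, axis=axis)
    out = Tensor(out_data)
    if _GRAD_ENABLED and any(t.requires_grad for t in tensors):
        out.requires_grad = True
        out._parents = tuple(tensors)
        sizes = [d.shape[axis] for d in datas]
        splits = np.cumsum(sizes)[:-1]

        def backward(g):
            return tuple(np.split(g, splits, axis=axis))

        out._backward = backward
    return out


def grl(x: Tensor, lam: float) -> Tensor:
    """Gradient reversal: identity forward, backward multiplies by ``-lam``."""
    if lam < 0:
        raise ValueError("reversal intensity lambda must be >= 0")
    out = x._make(x.data.copy(), (x,), None)
    out._backward = lambda g: (-lam * g,)
    return out
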