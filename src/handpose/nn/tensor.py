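"""A compact reverse-mode automatic-differentiation engine on NumPy.

Covers exactly the operator set the pose network needs: broadcasting
arithmetic, matmul, 2-D convolution (im2col), 2x max pooling, nearest
up-sampling, sigmoid/ReLU, reductions, reshape/concat and a Huber
(smooth-L1) elementwise op.  Tensors carry float32 data; gradients are
accumulated on a topologically sorted tape.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["Tensor", "concat", "smooth_l1_elem"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum a gradient back down to the shape it was broadcast from."""
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

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    # -- construction helpers -------------------------------------------------

    @staticmethod
    def _make(data, parents, backward):
        out = Tensor(data, requires_grad=any(p.requires_grad for p in parents))
        if out.requires_grad:
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def _accum(self, grad: np.ndarray) -> None:
        if not self.requires_grad:
            return
        if self.grad is None:
            self.grad = grad.astype(np.float32, copy=True)
        else:
            self.grad += grad

    # -- arithmetic -----------------------------------------------------------

    @staticmethod
    def _coerce(x):
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other):
        other = self._coerce(other)
        def back(g, a=self, b=other):
            a._accum(_unbroadcast(g, a.shape))
            b._accum(_unbroadcast(g, b.shape))
        return Tensor._make(self.data + other.data, (self, other), back)

    __radd__ = __add__

    def __neg__(self):
        def back(g, a=self):
            a._accum(-g)
        return Tensor._make(-self.data, (self,), back)

    def __sub__(self, other):
        return self + (-self._coerce(other))

    def __rsub__(self, other):
        return self._coerce(other) + (-self)

    def __mul__(self, other):
        other = self._coerce(other)
        def back(g, a=self, b=other):
            a._accum(_unbroadcast(g * b.data, a.shape))
            b._accum(_unbroadcast(g * a.data, b.shape))
        return Tensor._make(self.data * other.data, (self, other), back)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._coerce(other)
        def back(g, a=self, b=other):
            a._accum(_unbroadcast(g / b.data, a.shape))
            b._accum(_unbroadcast(-g * a.data / (b.data * b.data), b.shape))
        return Tensor._make(self.data / other.data, (self, other), back)

    def matmul(self, other: "Tensor") -> "Tensor":
        def back(g, a=self, b=other):
            a._accum(g @ b.data.T)
            b._accum(a.data.T @ g)
        return Tensor._make(self.data @ other.data, (self, other), back)

    # -- nonlinearities -------------------------------------------------------

    def relu(self) -> "Tensor":
        mask = self.data > 0
        def back(g, a=self, mask=mask):
            a._accum(g * mask)
        return Tensor._make(self.data * mask, (self,), back)

    def sigmoid(self) -> "Tensor":
        d = self.data
        y = np.where(d >= 0, 1.0 / (1.0 + np.exp(-np.abs(d))),
                     np.exp(-np.abs(d)) / (1.0 + np.exp(-np.abs(d))))
        def back(g, a=self, y=y):
            a._accum(g * y * (1.0 - y))
        return Tensor._make(y, (self,), back)

    def sqrt(self) -> "Tensor":
        y = np.sqrt(self.data)
        def back(g, a=self, y=y):
            a._accum(g * 0.5 / y)
        return Tensor._make(y, (self,), back)

    # -- reductions / shaping -------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        def back(g, a=self, axis=axis, keepdims=keepdims):
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            a._accum(np.broadcast_to(g, a.shape))
        return Tensor._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), back)

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        if axis is None:
            n = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape) -> "Tensor":
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        def back(g, a=self):
            a._accum(g.reshape(a.shape))
        return Tensor._make(self.data.reshape(shape), (self,), back)

    # -- spatial ops ----------------------------------------------------------

    def conv2d(self, weight: "Tensor", bias: "Tensor | None" = None,
               stride: int = 1, pad: int = 0) -> "Tensor":
        """2-D convolution; x (N,Cin,H,W), weight (Cout,Cin,kh,kw)."""
        x = self.data
        wgt = weight.data
        n, cin, h, w = x.shape
        cout, cin_w, kh, kw = wgt.shape
        if cin != cin_w:
            raise ValueError(f"channel mismatch: input has {cin}, weight expects {cin_w}")
        xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad))) if pad else x
        ho = (h + 2 * pad - kh) // stride + 1
        wo = (w + 2 * pad - kw) // stride + 1
        win = sliding_window_view(xp, (kh, kw), axis=(2, 3))[:, :, ::stride, ::stride]
        cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(
            n * ho * wo, cin * kh * kw
        )
        wmat = wgt.reshape(cout, -1)
        out = cols @ wmat.T
        if bias is not None:
            out += bias.data
        out = out.reshape(n, ho, wo, cout).transpose(0, 3, 1, 2)

        parents = (self, weight) if bias is None else (self, weight, bias)

        def back(g, a=self, wt=weight, bs=bias, cols=cols, xp_shape=xp.shape):
            g2 = np.ascontiguousarray(g.transpose(0, 2, 3, 1)).reshape(n * ho * wo, cout)
            wt._accum((g2.T @ cols).reshape(wt.shape))
            if bs is not None:
                bs._accum(g2.sum(axis=0))
            if a.requires_grad:
                gcols = (g2 @ wmat).reshape(n, ho, wo, cin, kh, kw).transpose(0, 3, 1, 2, 4, 5)
                gxp = np.zeros(xp_shape, dtype=np.float32)
                for i in range(kh):
                    for j in range(kw):
                        gxp[:, :, i : i + ho * stride : stride, j : j + wo * stride : stride] += gcols[..., i, j]
                a._accum(gxp[:, :, pad : pad + h, pad : pad + w] if pad else gxp)

        return Tensor._make(out, parents, back)

    def maxpool2(self) -> "Tensor":
        x = self.data
        n, c, h, w = x.shape
        if h % 2 or w % 2:
            raise ValueError("maxpool2 requires even spatial dimensions")
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(
            n, c, h // 2, w // 2, 4
        )
        idx = xr.argmax(axis=-1)
        out = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]

        def back(g, a=self, idx=idx):
            gx = np.zeros((n, c, h // 2, w // 2, 4), dtype=np.float32)
            np.put_along_axis(gx, idx[..., None], g[..., None], axis=-1)
            gx = gx.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h, w)
            a._accum(gx)

        return Tensor._make(out, (self,), back)

    def upsample2(self) -> "Tensor":
        x = self.data
        n, c, h, w = x.shape
        out = np.repeat(np.repeat(x, 2, axis=2), 2, axis=3)

        def back(g, a=self):
            a._accum(g.reshape(n, c, h, 2, w, 2).sum(axis=(3, 5)))

        return Tensor._make(out, (self,), back)

    # -- autodiff driver ------------------------------------------------------

    def backward(self, grad=None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.grad = np.asarray(grad, dtype=np.float32).reshape(self.shape)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def zero_grad(self) -> None:
        self.grad = None

    def __repr__(self) -> str:
        return f"Tensor(shape={self.shape}, grad={self.requires_grad})"


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0, *sizes])

    def back(g, ts=tensors, offsets=offsets, axis=axis):
        for t, lo, hi in zip(ts, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(lo, hi)
            t._accum(g[tuple(sl)])

    return Tensor._make(data, tuple(tensors), back)


def smooth_l1_elem(x: Tensor, delta: float = 1.0) -> Tensor:
    """Elementwise Huber: 0.5 x^2 / delta inside |x| < delta, |x| - delta/2 outside."""
    d = x.data
    inside = np.abs(d) < delta
    y = np.where(inside, 0.5 * d * d / delta, np.abs(d) - 0.5 * delta)

    def back(g, a=x, inside=inside, d=d):
        a._accum(g * np.where(inside, d / delta, np.sign(d)).astype(np.float32))

    return Tensor._make(y, (x,), back)
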