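"""Minimal reverse-mode autodiff on numpy arrays.

Supports exactly the operations the model needs: broadcasting arithmetic,
matmul, 2-D convolution (im2col), 2x2 max pooling, reductions, and the
pointwise nonlinearities.  Gradients are accumulated into ``Tensor.grad``
by :meth:`Tensor.backward` over a topologically sorted tape.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "conv2d", "maxpool2x2"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False):
        if isinstance(data, Tensor):
            data = data.data
        self.data = np.asarray(data, dtype=np.float32)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._prev: tuple[Tensor, ...] = ()

    # -- construction helpers ------------------------------------------------

    @staticmethod
    def _make(data, prev, backward, requires_grad):
        out = Tensor(data, requires_grad=requires_grad)
        if requires_grad:
            out._prev = tuple(p for p in prev if isinstance(p, Tensor))
            out._backward = backward
        return out

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data, dtype=np.float64)
        self.grad += g

    # -- arithmetic ----------------------------------------------------------

    def __add__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        rg = self.requires_grad or other.requires_grad
        out_data = self.data + other.data

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.shape))

        return Tensor._make(out_data, (self, other), backward, rg)

    __radd__ = __add__

    def __mul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        rg = self.requires_grad or other.requires_grad
        out_data = self.data * other.data

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.shape))

        return Tensor._make(out_data, (self, other), backward, rg)

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        return self + (-other)

    def __rsub__(self, other):
        return Tensor(other) + (-self)

    def __truediv__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        return self * other ** -1.0

    def __rtruediv__(self, other):
        return Tensor(other) * self ** -1.0

    def __pow__(self, exponent: float):
        """Elementwise power with a *constant* exponent."""
        e = float(exponent)
        out_data = self.data ** e

        def backward(g):
            if self.requires_grad:
                self._accum(g * e * self.data ** (e - 1.0))

        return Tensor._make(out_data, (self,), backward, self.requires_grad)

    def matmul(self, other: "Tensor") -> "Tensor":
        other = other if isinstance(other, Tensor) else Tensor(other)
        rg = self.requires_grad or other.requires_grad
        out_data = self.data @ other.data

        def backward(g):
            if self.requires_grad:
                self._accum(g @ other.data.T)
            if other.requires_grad:
                other._accum(self.data.T @ g)

        return Tensor._make(out_data, (self, other), backward, rg)

    __matmul__ = matmul

    # -- pointwise nonlinearities -------------------------------------------

    def relu(self) -> "Tensor":
        mask = self.data > 0
        out_data = self.data * mask

        def backward(g):
            if self.requires_grad:
                self._accum(g * mask)

        return Tensor._make(out_data, (self,), backward, self.requires_grad)

    def sigmoid(self) -> "Tensor":
        s = 1.0 / (1.0 + np.exp(-self.data.astype(np.float64)))
        # keep the gate strictly inside (0, 1) even after the float32 cast
        s = np.clip(s.astype(np.float32), 1e-7, 1.0 - 1e-7)

        def backward(g):
            if self.requires_grad:
                self._accum(g * s * (1.0 - s))

        return Tensor._make(s, (self,), backward, self.requires_grad)

    def log(self) -> "Tensor":
        out_data = np.log(self.data)

        def backward(g):
            if self.requires_grad:
                self._accum(g / self.data)

        return Tensor._make(out_data, (self,), backward, self.requires_grad)

    def exp(self) -> "Tensor":
        out_data = np.exp(self.data)

        def backward(g):
            if self.requires_grad:
                self._accum(g * out_data)

        return Tensor._make(out_data, (self,), backward, self.requires_grad)

    def sqrt(self, grad_eps: float = 1e-12) -> "Tensor":
        """Elementwise square root; backward denominator clamped for x=0."""
        out_data = np.sqrt(self.data)

        def backward(g):
            if self.requires_grad:
                self._accum(g * 0.5 / np.maximum(out_data, grad_eps))

        return Tensor._make(out_data, (self,), backward, self.requires_grad)

    def clip_min(self, lo: float) -> "Tensor":
        """max(x, lo); subgradient 0 on the clamped region."""
        mask = self.data > lo
        out_data = np.maximum(self.data, lo)

        def backward(g):
            if self.requires_grad:
                self._accum(g * mask)

        return Tensor._make(out_data, (self,), backward, self.requires_grad)

    # -- shape ops -----------------------------------------------------------

    def reshape(self, *shape) -> "Tensor":
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        orig = self.shape
        out_data = self.data.reshape(shape)

        def backward(g):
            if self.requires_grad:
                self._accum(g.reshape(orig))

        return Tensor._make(out_data, (self,), backward, self.requires_grad)

    def transpose(self, *axes) -> "Tensor":
        out_data = self.data.transpose(axes)
        inv = np.argsort(axes)

        def backward(g):
            if self.requires_grad:
                self._accum(g.transpose(inv))

        return Tensor._make(out_data, (self,), backward, self.requires_grad)

    # -- reductions ----------------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out_data = self.data.sum(axis=axis, keepdims=keepdims)
        shape = self.shape

        def backward(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accum(np.full(shape, g, dtype=np.float64))
            else:
                if not keepdims:
                    g = np.expand_dims(g, axis)
                self._accum(np.broadcast_to(g, shape).astype(np.float64))

        return Tensor._make(out_data, (self,), backward, self.requires_grad)

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        if axis is None:
            n = self.data.size
        else:
            ax = (axis,) if isinstance(axis, int) else axis
            n = 1
            for a in ax:
                n *= self.shape[a]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- backprop ------------------------------------------------------------

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar")
            grad = np.ones_like(self.data, dtype=np.float64)
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
        self._accum(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def __repr__(self) -> str:  # pragma: no cover
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    rg = any(t.requires_grad for t in tensors)
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accum(g[tuple(sl)])

    return Tensor._make(out_data, tuple(tensors), backward, rg)


def _im2col(xp: np.ndarray, kh: int, kw: int, stride: int):
    """(N, C, Hp, Wp) -> (N*Ho*Wo, C*kh*kw) view-copy."""
    n, c, hp, wp = xp.shape
    ho = (hp - kh) // stride + 1
    wo = (wp - kw) // stride + 1
    win = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(2, 3))
    win = win[:, :, ::stride, ::stride]            # (N, C, Ho, Wo, kh, kw)
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * ho * wo, c * kh * kw)
    return np.ascontiguousarray(cols), ho, wo


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None = None,
           stride: int = 1, padding: int = 0) -> Tensor:
    """2-D cross-correlation; x (N,C,H,W), weight (O,C,kh,kw)."""
    n, c, h, w = x.shape
    o, ci, kh, kw = weight.shape
    if ci != c:
        raise ValueError(
            f"conv2d channel mismatch: input has {c} channels, weight expects {ci}"
        )
    if padding:
        xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    else:
        xp = x.data
    cols, ho, wo = _im2col(xp, kh, kw, stride)
    wmat = weight.data.reshape(o, -1)
    out = cols @ wmat.T                             # (N*Ho*Wo, O)
    if bias is not None:
        out = out + bias.data
    out_data = out.reshape(n, ho, wo, o).transpose(0, 3, 1, 2)
    rg = x.requires_grad or weight.requires_grad or (
        bias is not None and bias.requires_grad)

    def backward(g):
        gmat = g.transpose(0, 2, 3, 1).reshape(-1, o)   # (N*Ho*Wo, O)
        if bias is not None and bias.requires_grad:
            bias._accum(gmat.sum(axis=0))
        if weight.requires_grad:
            weight._accum((gmat.T @ cols).reshape(weight.shape))
        if x.requires_grad:
            dcols = (gmat @ wmat).reshape(n, ho, wo, c, kh, kw)
            dxp = np.zeros(xp.shape, dtype=np.float64)
            for i in range(kh):
                for j in range(kw):
                    dxp[:, :, i:i + stride * ho:stride, j:j + stride * wo:stride] += \
                        dcols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
            if padding:
                dxp = dxp[:, :, padding:-padding, padding:-padding]
            x._accum(dxp)

    prev = (x, weight) if bias is None else (x, weight, bias)
    return Tensor._make(out_data, prev, backward, rg)


def maxpool2x2(x: Tensor) -> Tensor:
    """2x2 max pooling with stride 2; odd sizes padded with -inf (ceil mode)."""
    n, c, h, w = x.shape
    ph, pw = h % 2, w % 2
    xp = x.data
    if ph or pw:
        xp = np.pad(xp, ((0, 0), (0, 0), (0, ph), (0, pw)),
                    constant_values=-np.inf)
    ho, wo = xp.shape[2] // 2, xp.shape[3] // 2
    win = xp.reshape(n, c, ho, 2, wo, 2).transpose(0, 1, 2, 4, 3, 5)
    win = win.reshape(n, c, ho, wo, 4)
    idx = win.argmax(axis=-1)
    out_data = np.take_along_axis(win, idx[..., None], axis=-1)[..., 0]

    def backward(g):
        if not x.requires_grad:
            return
        dwin = np.zeros((n, c, ho, wo, 4), dtype=np.float64)
        np.put_along_axis(dwin, idx[..., None], g[..., None], axis=-1)
        dxp = dwin.reshape(n, c, ho, wo, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        dxp = dxp.reshape(n, c, ho * 2, wo * 2)
        x._accum(dxp[:, :, :h, :w])

    return Tensor._make(out_data, (x,), backward, x.requires_grad)
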