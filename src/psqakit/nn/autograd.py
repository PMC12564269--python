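"""Minimal reverse-mode automatic differentiation on numpy arrays.

Only the operations the QA network needs are implemented: broadcasting
arithmetic, matmul, conv2d, nearest-neighbour upsampling, reductions,
ReLU/exp/abs, reshape/concat and dropout.  Everything is float64 and fully
deterministic, which the subset-forward equality tests rely on.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "conv2d", "upsample2x", "dropout"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    nd = grad.ndim - len(shape)
    if nd > 0:
        grad = grad.sum(axis=tuple(range(nd)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    """A numpy array plus a backward closure and parent links."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = requires_grad
        self.grad: np.ndarray | None = None
        self._backward = None
        self._prev: tuple[Tensor, ...] = ()

    # -- helpers ---------------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(np.asarray(x))

    def _accum(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = grad.copy()
        else:
            self.grad += grad

    @staticmethod
    def _make(data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._prev = tuple(parents)
            out._backward = backward
        return out

    # -- arithmetic ------------------------------------------------------

    def __add__(self, other):
        other = self._lift(other)
        out_data = self.data + other.data

        def backward(out):
            if self.requires_grad:
                self._accum(_unbroadcast(out.grad, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(out.grad, other.data.shape))

        return self._make(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(out):
            if self.requires_grad:
                self._accum(-out.grad)

        return self._make(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        out_data = self.data * other.data

        def backward(out):
            if self.requires_grad:
                self._accum(_unbroadcast(out.grad * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(out.grad * self.data, other.data.shape))

        return self._make(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)
        out_data = self.data / other.data

        def backward(out):
            if self.requires_grad:
                self._accum(_unbroadcast(out.grad / other.data, self.data.shape))
            if other.requires_grad:
                other._accum(
                    _unbroadcast(
                        -out.grad * self.data / other.data**2, other.data.shape
                    )
                )

        return self._make(out_data, (self, other), backward)

    def matmul(self, other: "Tensor") -> "Tensor":
        other = self._lift(other)
        out_data = self.data @ other.data

        def backward(out):
            if self.requires_grad:
                self._accum(out.grad @ other.data.T)
            if other.requires_grad:
                other._accum(self.data.T @ out.grad)

        return self._make(out_data, (self, other), backward)

    __matmul__ = matmul

    # -- nonlinearities --------------------------------------------------

    def relu(self) -> "Tensor":
        mask = self.data > 0

        def backward(out):
            if self.requires_grad:
                self._accum(out.grad * mask)

        return self._make(self.data * mask, (self,), backward)

    def exp(self) -> "Tensor":
        out_data = np.exp(self.data)

        def backward(out):
            if self.requires_grad:
                self._accum(out.grad * out_data)

        return self._make(out_data, (self,), backward)

    def abs(self) -> "Tensor":
        sign = np.sign(self.data)

        def backward(out):
            if self.requires_grad:
                self._accum(out.grad * sign)

        return self._make(np.abs(self.data), (self,), backward)

    # -- reductions / shape ---------------------------------------------

    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(out):
            if not self.requires_grad:
                return
            g = out.grad
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.data.shape).copy())

        return self._make(out_data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        if axis is None:
            n = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.data.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape) -> "Tensor":
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        orig = self.data.shape

        def backward(out):
            if self.requires_grad:
                self._accum(out.grad.reshape(orig))

        return self._make(self.data.reshape(shape), (self,), backward)

    # -- graph traversal -------------------------------------------------

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        visited: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in visited:
                continue
            visited.add(id(node))
            stack.append((node, True))
            for p in node._prev:
                if id(p) not in visited:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node)


def concat(tensors: list[Tensor], axis: int = 0) -> Tensor:
    datas = [t.data for t in tensors]
    out_data = np.concatenate(datas, axis=axis)
    sizes = [d.shape[axis] for d in datas]
    offsets = np.cumsum([0] + sizes)

    def backward(out):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * out.grad.ndim
                sl[axis] = slice(lo, hi)
                t._accum(out.grad[tuple(sl)])

    return Tensor._make(out_data, tuple(tensors), backward)


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None,
           stride: int = 1, padding: int = 0) -> Tensor:
    """2-D convolution, NCHW layout; kernels (O, C, kh, kw).

    im2col + one GEMM; the column matrix is cached for the backward pass.
    """
    bsz, cin, h, wd = x.data.shape
    cout, cin_w, kh, kw = w.data.shape
    if cin != cin_w:
        raise ValueError(f"channel mismatch: input {cin}, kernel {cin_w}")
    ho = (h + 2 * padding - kh) // stride + 1
    wo = (wd + 2 * padding - kw) // stride + 1
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    # (B, C, Ho, Wo, kh, kw) view -> (B*Ho*Wo, C*kh*kw) copy
    windows = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(2, 3))
    windows = windows[:, :, ::stride, ::stride]
    cols = np.ascontiguousarray(windows.transpose(0, 2, 3, 1, 4, 5)).reshape(
        bsz * ho * wo, cin * kh * kw
    )
    w_mat = w.data.reshape(cout, cin * kh * kw)
    out_data = (cols @ w_mat.T).reshape(bsz, ho, wo, cout).transpose(0, 3, 1, 2)
    if b is not None:
        out_data = out_data + b.data.reshape(1, cout, 1, 1)
    else:
        out_data = np.ascontiguousarray(out_data)

    parents = (x, w) if b is None else (x, w, b)

    def backward(out):
        g = out.grad
        if b is not None and b.requires_grad:
            b._accum(g.sum(axis=(0, 2, 3)))
        g_mat = np.ascontiguousarray(g.transpose(0, 2, 3, 1)).reshape(
            bsz * ho * wo, cout
        )
        if w.requires_grad:
            gw = (g_mat.T @ cols).reshape(cout, cin, kh, kw)
            if w.grad is None:
                w.grad = gw
            else:
                w.grad += gw
        if x.requires_grad:
            dcols = (g_mat @ w_mat).reshape(bsz, ho, wo, cin, kh, kw)
            dcols = dcols.transpose(0, 3, 1, 2, 4, 5)  # (B, C, Ho, Wo, kh, kw)
            dxp = np.zeros_like(xp)
            for ki in range(kh):
                for kj in range(kw):
                    dxp[:, :, ki:ki + stride * ho:stride,
                        kj:kj + stride * wo:stride] += dcols[..., ki, kj]
            if padding:
                dxp = dxp[:, :, padding:-padding, padding:-padding]
            x._accum(dxp)

    return Tensor._make(out_data, parents, backward)


def upsample2x(x: Tensor) -> Tensor:
    """Nearest-neighbour 2x spatial upsampling (NCHW)."""
    out_data = x.data.repeat(2, axis=2).repeat(2, axis=3)

    def backward(out):
        if x.requires_grad:
            b, c, h2, w2 = out.grad.shape
            g = out.grad.reshape(b, c, h2 // 2, 2, w2 // 2, 2).sum(axis=(3, 5))
            x._accum(g)

    return Tensor._make(out_data, (x,), backward)


def dropout(x: Tensor, p: float, rng: np.random.Generator,
            train: bool) -> Tensor:
    """Inverted dropout; identity when ``train`` is False or ``p == 0``."""
    if not train or p <= 0.0:
        return x
    mask = (rng.random(x.data.shape) >= p) / (1.0 - p)

    def backward(out):
        if x.requires_grad:
            x._accum(out.grad * mask)

    return Tensor._make(x.data * mask, (x,), backward)
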