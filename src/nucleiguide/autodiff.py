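"""Minimal reverse-mode automatic differentiation on NumPy arrays.

The grading network needs end-to-end gradients three times over: for
training, for the finite-difference sanity properties, and for Grad-CAM
(which differentiates a class logit with respect to an *intermediate*
feature map).  This module provides a small tape-based tensor type with
exactly the operators the network uses: broadcasting arithmetic, matmul
(batched), 3x3 "same" convolution, 2x2 max pooling, ReLU, exp/log,
reductions, reshape/transpose and concatenation.

Gradients are accumulated on every node that ``requires_grad``, including
non-leaves, so intermediate activations can be inspected after
``backward()`` without any retain-graph machinery.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "conv2d_3x3", "maxpool2x2"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum away leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """An n-d array node in a dynamically built computation graph."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    #: ids of arrays already serving as some node's .grad in the current
    #: backward pass; prevents two nodes from silently sharing one buffer
    _active_grad_ids: set[int] = set()

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    # -- graph plumbing ---------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            g = np.asarray(g, dtype=np.float64)
            # adopt freshly allocated arrays; copy views/broadcasts (their
            # memory is shared with upstream gradients) and any array some
            # other node already adopted in this pass
            if (
                g.flags["OWNDATA"]
                and g.flags["WRITEABLE"]
                and id(g) not in Tensor._active_grad_ids
            ):
                self.grad = g
            else:
                self.grad = g.copy()
            Tensor._active_grad_ids.add(id(self.grad))
        else:
            self.grad += g

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Backpropagate from this node (default seed: ones)."""
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        if grad is None:
            grad = np.ones_like(self.data)
        Tensor._active_grad_ids = set()
        self._accumulate(np.array(grad, dtype=np.float64))  # private copy
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    @staticmethod
    def _make(data, parents, backward):
        out = Tensor(data)
        out.requires_grad = any(p.requires_grad for p in parents)
        if out.requires_grad:
            out._parents = tuple(p for p in parents if p.requires_grad)
            out._backward = backward
        return out

    # -- arithmetic -------------------------------------------------------
    @staticmethod
    def _coerce(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def __add__(self, other):
        other = self._coerce(other)

        def bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.shape))

        return Tensor._make(self.data + other.data, (self, other), bw)

    __radd__ = __add__

    def __neg__(self):
        def bw(g):
            self._accumulate(-g)

        return Tensor._make(-self.data, (self,), bw)

    def __sub__(self, other):
        return self + (-self._coerce(other))

    def __rsub__(self, other):
        return self._coerce(other) + (-self)

    def __mul__(self, other):
        other = self._coerce(other)

        def bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.shape))

        return Tensor._make(self.data * other.data, (self, other), bw)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._coerce(other)

        def bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g / other.data, self.shape))
            if other.requires_grad:
                other._accumulate(
                    _unbroadcast(-g * self.data / other.data**2, other.shape)
                )

        return Tensor._make(self.data / other.data, (self, other), bw)

    def __matmul__(self, other):
        other = self._coerce(other)
        a, b = self.data, other.data

        def bw(g):
            if self.requires_grad:
                ga = g @ np.swapaxes(b, -1, -2) if b.ndim > 1 else np.outer(g, b)
                self._accumulate(_unbroadcast(ga, self.shape))
            if other.requires_grad:
                gb = np.swapaxes(a, -1, -2) @ g if a.ndim > 1 else np.outer(a, g)
                other._accumulate(_unbroadcast(gb, other.shape))

        return Tensor._make(a @ b, (self, other), bw)

    # -- elementwise nonlinearities ---------------------------------------
    def relu(self):
        mask = self.data > 0

        def bw(g):
            self._accumulate(g * mask)

        return Tensor._make(self.data * mask, (self,), bw)

    def exp(self):
        out_data = np.exp(self.data)

        def bw(g):
            self._accumulate(g * out_data)

        return Tensor._make(out_data, (self,), bw)

    def clamp(self, lo=None, hi=None):
        """Clip values to [lo, hi]; gradient passes only inside the range."""
        mask = np.ones_like(self.data, dtype=bool)
        if lo is not None:
            mask &= self.data >= lo
        if hi is not None:
            mask &= self.data <= hi

        def bw(g):
            self._accumulate(g * mask)

        return Tensor._make(np.clip(self.data, lo, hi), (self,), bw)

    def log(self):
        def bw(g):
            self._accumulate(g / self.data)

        return Tensor._make(np.log(self.data), (self,), bw)

    # -- reductions / shape -----------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        def bw(g):
            if axis is None:
                self._accumulate(np.full(self.shape, g))
                return
            gg = g if keepdims else np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(gg, self.shape))

        return Tensor._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), bw)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.shape[a] for a in np.atleast_1d(axis)]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])

        def bw(g):
            self._accumulate(g.reshape(self.shape))

        return Tensor._make(self.data.reshape(shape), (self,), bw)

    def transpose(self, *axes):
        axes = axes or tuple(reversed(range(self.ndim)))
        inv = np.argsort(axes)

        def bw(g):
            self._accumulate(g.transpose(inv))

        return Tensor._make(self.data.transpose(axes), (self,), bw)

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def softmax(self, axis: int = -1) -> "Tensor":
        """Numerically stable softmax along ``axis`` (max-subtraction).

        Fused forward/backward: ``ds = (g - sum(g*s)) * s``.
        """
        e = np.exp(self.data - self.data.max(axis=axis, keepdims=True))
        s = e / e.sum(axis=axis, keepdims=True)

        def bw(g):
            self._accumulate((g - (g * s).sum(axis=axis, keepdims=True)) * s)

        return Tensor._make(s, (self,), bw)

    def __repr__(self):  # pragma: no cover
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    """Concatenate tensors along ``axis``."""
    datas = [t.data for t in tensors]
    sizes = [d.shape[axis] for d in datas]
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                idx = [slice(None)] * g.ndim
                idx[axis] = slice(lo, hi)
                t._accumulate(g[tuple(idx)])

    return Tensor._make(np.concatenate(datas, axis=axis), tuple(tensors), bw)


def conv2d_3x3(x: Tensor, weight: Tensor, bias: Tensor | None = None) -> Tensor:
    """3x3 'same' convolution, stride 1.

    ``x``: (N, C, H, W); ``weight``: (F, C, 3, 3); ``bias``: (F,).
    Implemented with an im2col matmul forward and a 9-shift scatter
    backward, which keeps everything inside BLAS.
    """
    n, c, h, w = x.shape
    f = weight.shape[0]
    if weight.shape[1] != c:
        raise ValueError(
            f"channel mismatch: input has {c} channels, kernel expects {weight.shape[1]}"
        )
    xp = np.pad(x.data, ((0, 0), (0, 0), (1, 1), (1, 1)))
    # (N, C, H, W, 3, 3) windows -> (N*H*W, C*9)
    win = np.lib.stride_tricks.sliding_window_view(xp, (3, 3), axis=(2, 3))
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * h * w, c * 9)
    wmat = weight.data.reshape(f, c * 9)
    out = (cols @ wmat.T).reshape(n, h, w, f).transpose(0, 3, 1, 2)
    if bias is not None:
        out = out + bias.data[None, :, None, None]

    parents = (x, weight) + ((bias,) if bias is not None else ())

    def bw(g):
        gmat = g.transpose(0, 2, 3, 1).reshape(n * h * w, f)
        if weight.requires_grad:
            weight._accumulate((gmat.T @ cols).reshape(weight.shape))
        if bias is not None and bias.requires_grad:
            bias._accumulate(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            dcols = (gmat @ wmat).reshape(n, h, w, c, 3, 3)
            # one contiguous relayout so the 9 scatter-adds hit contiguous blocks
            dcols = np.ascontiguousarray(dcols.transpose(4, 5, 0, 3, 1, 2))
            dxp = np.zeros_like(xp)
            for dy in range(3):
                for dx in range(3):
                    dxp[:, :, dy : dy + h, dx : dx + w] += dcols[dy, dx]
            x._accumulate(dxp[:, :, 1 : 1 + h, 1 : 1 + w])

    return Tensor._make(out, parents, bw)


def conv2d_1x1(x: Tensor, weight: Tensor, bias: Tensor | None = None) -> Tensor:
    """1x1 convolution: per-pixel linear map over channels.

    ``x``: (N, C, H, W); ``weight``: (F, C); ``bias``: (F,).
    """
    if weight.shape[1] != x.shape[1]:
        raise ValueError(
            f"channel mismatch: input has {x.shape[1]} channels, "
            f"kernel expects {weight.shape[1]}"
        )
    # (N,C,H,W) -> (N,H,W,C) @ (C,F) -> (N,H,W,F) -> (N,F,H,W)
    out = x.transpose(0, 2, 3, 1) @ weight.transpose()
    if bias is not None:
        out = out + bias
    return out.transpose(0, 3, 1, 2)


def maxpool2x2(x: Tensor) -> Tensor:
    """2x2 max pooling, stride 2; spatial dims must be even."""
    n, c, h, w = x.shape
    if h % 2 or w % 2:
        raise ValueError(f"maxpool2x2 needs even spatial dims, got {h}x{w}")
    blocks = x.data.reshape(n, c, h // 2, 2, w // 2, 2)
    out = blocks.max(axis=(3, 5))
    # route gradient to the (first) maximum of each block
    mask = blocks == out[:, :, :, None, :, None]
    norm = mask.sum(axis=(3, 5), keepdims=True)  # split ties evenly

    def bw(g):
        gb = (mask / norm) * g[:, :, :, None, :, None]
        x._accumulate(gb.reshape(n, c, h, w))

    return Tensor._make(out, (x,), bw)
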