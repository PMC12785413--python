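"""Minimal reverse-mode automatic differentiation over numpy arrays.

The engine provides exactly the operations the denoising U-Net, the
transformer mid-block and the SE-U-Net localizer need: broadcast
arithmetic, matmul, 2-D convolution (im2col + GEMM), nearest-neighbour
upsampling, softmax, layer normalisation building blocks and the usual
pointwise nonlinearities.  All tensors are float32; gradients are
accumulated into ``.grad`` by :meth:`Tensor.backward` over a
topologically sorted tape.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "conv2d", "split", "upsample2x", "no_grad"]

_grad_enabled = True


class no_grad:
    """Context manager disabling tape construction (inference mode)."""

    def __enter__(self):
        global _grad_enabled
        self._prev = _grad_enabled
        _grad_enabled = False
        return self

    def __exit__(self, *exc):
        global _grad_enabled
        _grad_enabled = self._prev
        return False


def _as_array(x) -> np.ndarray:
    if isinstance(x, np.ndarray):
        return x.astype(np.float32, copy=False)
    return np.asarray(x, dtype=np.float32)


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndim_extra = grad.ndim - len(shape)
    if ndim_extra > 0:
        grad = grad.sum(axis=tuple(range(ndim_extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = _as_array(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents: tuple = ()

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def _make(data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if _grad_enabled and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(p for p in parents if p.requires_grad)
            out._backward = backward
        return out

    @staticmethod
    def as_tensor(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    # -- introspection --------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def __float__(self) -> float:
        return float(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    # -- autodiff core --------------------------------------------------------
    def backward(self, grad=None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen = set()
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
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = _as_array(grad)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accum(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = grad.astype(np.float32, copy=True)
        else:
            self.grad += grad

    # -- arithmetic -----------------------------------------------------------
    def __add__(self, other):
        other = Tensor.as_tensor(other)
        out_data = self.data + other.data

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))

        return Tensor._make(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            self._accum(-g)

        return Tensor._make(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-Tensor.as_tensor(other))

    def __rsub__(self, other):
        return Tensor.as_tensor(other) + (-self)

    def __mul__(self, other):
        other = Tensor.as_tensor(other)
        out_data = self.data * other.data

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))

        return Tensor._make(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = Tensor.as_tensor(other)
        out_data = self.data / other.data

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g / other.data, self.data.shape))
            if other.requires_grad:
                other._accum(
                    _unbroadcast(-g * self.data / (other.data**2), other.data.shape)
                )

        return Tensor._make(out_data, (self, other), backward)

    def __rtruediv__(self, other):
        return Tensor.as_tensor(other) / self

    def __pow__(self, exponent: float):
        out_data = self.data**exponent

        def backward(g):
            self._accum(g * exponent * self.data ** (exponent - 1))

        return Tensor._make(out_data, (self,), backward)

    def __matmul__(self, other):
        other = Tensor.as_tensor(other)
        out_data = self.data @ other.data

        def backward(g):
            if self.requires_grad:
                ga = g @ np.swapaxes(other.data, -1, -2)
                self._accum(_unbroadcast(ga, self.data.shape))
            if other.requires_grad:
                gb = np.swapaxes(self.data, -1, -2) @ g
                other._accum(_unbroadcast(gb, other.data.shape))

        return Tensor._make(out_data, (self, other), backward)

    # -- pointwise ------------------------------------------------------------
    def exp(self):
        out_data = np.exp(self.data)

        def backward(g):
            self._accum(g * out_data)

        return Tensor._make(out_data, (self,), backward)

    def log(self):
        def backward(g):
            self._accum(g / self.data)

        return Tensor._make(np.log(self.data), (self,), backward)

    def sqrt(self):
        out_data = np.sqrt(self.data)

        def backward(g):
            self._accum(g / (2.0 * out_data))

        return Tensor._make(out_data, (self,), backward)

    def relu(self):
        mask = self.data > 0
        out_data = np.where(mask, self.data, 0.0).astype(np.float32)

        def backward(g):
            self._accum(g * mask)

        return Tensor._make(out_data, (self,), backward)

    def gelu(self):
        """tanh-approximation GELU."""
        x = self.data
        c = np.float32(np.sqrt(2.0 / np.pi))
        inner = c * (x + 0.044715 * x**3)
        t = np.tanh(inner)
        out_data = (0.5 * x * (1.0 + t)).astype(np.float32)

        def backward(g):
            dinner = c * (1.0 + 3 * 0.044715 * x**2)
            dt = (1.0 - t**2) * dinner
            self._accum(g * (0.5 * (1.0 + t) + 0.5 * x * dt))

        return Tensor._make(out_data, (self,), backward)

    def sigmoid(self):
        x = self.data
        out_data = np.empty_like(x)
        pos = x >= 0
        out_data[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
        ex = np.exp(x[~pos])
        out_data[~pos] = ex / (1.0 + ex)

        def backward(g):
            self._accum(g * out_data * (1.0 - out_data))

        return Tensor._make(out_data, (self,), backward)

    def clamp(self, lo: float, hi: float):
        """Clip values; gradient is passed only where lo < value < hi."""
        mask = (self.data > lo) & (self.data < hi)
        out_data = np.clip(self.data, lo, hi)

        def backward(g):
            self._accum(g * mask)

        return Tensor._make(out_data, (self,), backward)

    # -- reductions & shaping -------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            if axis is None:
                self._accum(np.broadcast_to(g, self.data.shape).astype(np.float32))
            else:
                g_exp = g if keepdims else np.expand_dims(g, axis)
                self._accum(np.broadcast_to(g_exp, self.data.shape).astype(np.float32))

        return Tensor._make(out_data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in np.atleast_1d(axis)]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.data.shape
        out_data = self.data.reshape(shape)

        def backward(g):
            self._accum(g.reshape(old))

        return Tensor._make(out_data, (self,), backward)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)

        def backward(g):
            self._accum(np.ascontiguousarray(g.transpose(inv)))

        return Tensor._make(
            np.ascontiguousarray(self.data.transpose(axes)), (self,), backward
        )

    def softmax(self, axis: int = -1):
        z = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(z)
        out_data = e / e.sum(axis=axis, keepdims=True)

        def backward(g):
            dot = (g * out_data).sum(axis=axis, keepdims=True)
            self._accum(out_data * (g - dot))

        return Tensor._make(out_data.astype(np.float32), (self,), backward)


def concat(tensors: list, axis: int = 0) -> Tensor:
    tensors = [Tensor.as_tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                idx = [slice(None)] * g.ndim
                idx[axis] = slice(lo, hi)
                t._accum(np.ascontiguousarray(g[tuple(idx)]))

    out = Tensor(out_data)
    if _grad_enabled and any(t.requires_grad for t in tensors):
        out.requires_grad = True
        out._parents = tuple(t for t in tensors if t.requires_grad)
        out._backward = backward
    return out


def split(x: Tensor, n: int, axis: int = 0) -> list[Tensor]:
    """Split into `n` equal chunks along `axis` (autodiff-aware)."""
    size = x.data.shape[axis]
    if size % n:
        raise ValueError(f"axis size {size} not divisible by {n}")
    step = size // n
    outs = []
    for k in range(n):
        idx = [slice(None)] * x.data.ndim
        idx[axis] = slice(k * step, (k + 1) * step)
        idx = tuple(idx)
        data = np.ascontiguousarray(x.data[idx])

        def backward(g, idx=idx):
            full = np.zeros_like(x.data)
            full[idx] = g
            x._accum(full)

        outs.append(Tensor._make(data, (x,), backward))
    return outs


def _im2col(x: np.ndarray, kh: int, kw: int, stride: int) -> np.ndarray:
    """(B,C,H,W) -> (B*Ho*Wo, C*kh*kw) patch matrix."""
    windows = np.lib.stride_tricks.sliding_window_view(x, (kh, kw), axis=(2, 3))
    windows = windows[:, :, ::stride, ::stride, :, :]  # (B,C,Ho,Wo,kh,kw)
    b, c, ho, wo = windows.shape[:4]
    cols = windows.transpose(0, 2, 3, 1, 4, 5).reshape(b * ho * wo, c * kh * kw)
    return np.ascontiguousarray(cols), (ho, wo)


def conv2d(x: Tensor, w: Tensor, b: Tensor | None, stride: int = 1, padding: int = 0) -> Tensor:
    """2-D convolution (cross-correlation). x:(B,C,H,W), w:(O,C,kh,kw)."""
    xd = x.data
    o, c, kh, kw = w.data.shape
    if padding:
        xd = np.pad(xd, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    cols, (ho, wo) = _im2col(xd, kh, kw, stride)
    w_mat = w.data.reshape(o, c * kh * kw)
    out_mat = cols @ w_mat.T  # (B*Ho*Wo, O)
    bsz = x.data.shape[0]
    out_data = out_mat.reshape(bsz, ho, wo, o).transpose(0, 3, 1, 2)
    if b is not None:
        out_data = out_data + b.data.reshape(1, o, 1, 1)
    out_data = np.ascontiguousarray(out_data)

    def backward(g):
        g_mat = np.ascontiguousarray(g.transpose(0, 2, 3, 1)).reshape(-1, o)
        if b is not None and b.requires_grad:
            b._accum(g_mat.sum(axis=0))
        if w.requires_grad:
            w._accum((g_mat.T @ cols).reshape(o, c, kh, kw))
        if x.requires_grad:
            dcols = g_mat @ w_mat  # (B*Ho*Wo, C*kh*kw)
            dcols = dcols.reshape(bsz, ho, wo, c, kh, kw)
            # one contiguous transpose, then kh*kw block adds
            dcols = np.ascontiguousarray(dcols.transpose(4, 5, 0, 3, 1, 2))
            hp, wp = xd.shape[2], xd.shape[3]
            dx_pad = np.zeros((bsz, c, hp, wp), dtype=np.float32)
            for i in range(kh):
                for j in range(kw):
                    dx_pad[
                        :, :, i : i + ho * stride : stride, j : j + wo * stride : stride
                    ] += dcols[i, j]
            if padding:
                dx_pad = dx_pad[:, :, padding:-padding, padding:-padding]
            x._accum(dx_pad)

    parents = (x, w) if b is None else (x, w, b)
    return Tensor._make(out_data, parents, backward)


def upsample2x(x: Tensor) -> Tensor:
    """Nearest-neighbour 2x spatial upsampling of (B,C,H,W)."""
    out_data = x.data.repeat(2, axis=2).repeat(2, axis=3)

    def backward(g):
        b, c, h2, w2 = g.shape
        x._accum(g.reshape(b, c, h2 // 2, 2, w2 // 2, 2).sum(axis=(3, 5)))

    return Tensor._make(out_data, (x,), backward)
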