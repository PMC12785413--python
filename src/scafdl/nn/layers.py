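"""Neural-network building blocks on the numpy autodiff engine."""

from __future__ import annotations

import numpy as np

from .tensor import Tensor, conv2d

__all__ = [
    "Module",
    "Linear",
    "Conv2d",
    "LayerNorm",
    "SEBlock",
    "MultiHeadSelfAttention",
    "TransformerEncoderLayer",
]


class Module:
    """Base class; collects parameters from attributes recursively."""

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        seen: set[int] = set()
        for value in self.__dict__.values():
            for p in _collect(value):
                if id(p) not in seen:
                    seen.add(id(p))
                    params.append(p)
        return params

    def state_dict(self) -> dict[str, np.ndarray]:
        out: dict[str, np.ndarray] = {}
        _walk_state(self, "", out)
        return out

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        target: dict[str, np.ndarray] = {}
        _walk_state(self, "", target)
        missing = set(target) ^ set(state)
        if missing:
            raise ValueError(f"state dict key mismatch: {sorted(missing)}")
        for key, arr in state.items():
            if target[key].shape != arr.shape:
                raise ValueError(f"shape mismatch for {key}")
            target[key][...] = arr

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def _collect(value):
    if isinstance(value, Tensor) and value.requires_grad:
        yield value
    elif isinstance(value, Module):
        yield from value.parameters()
    elif isinstance(value, (list, tuple)):
        for v in value:
            yield from _collect(v)


def _walk_state(obj, prefix: str, out: dict) -> None:
    if isinstance(obj, Tensor) and obj.requires_grad:
        out[prefix] = obj.data
    elif isinstance(obj, Module):
        for name, value in obj.__dict__.items():
            _walk_state(value, f"{prefix}.{name}" if prefix else name, out)
    elif isinstance(obj, (list, tuple)):
        for i, value in enumerate(obj):
            _walk_state(value, f"{prefix}.{i}", out)


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / n_in)
        self.weight = Tensor(rng.normal(0, scale, (n_in, n_out)), requires_grad=True)
        self.bias = Tensor(np.zeros(n_out), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class Conv2d(Module):
    def __init__(
        self,
        c_in: int,
        c_out: int,
        kernel: int,
        rng: np.random.Generator,
        stride: int = 1,
        padding: int | None = None,
    ):
        fan_in = c_in * kernel * kernel
        scale = np.sqrt(2.0 / fan_in)
        self.weight = Tensor(
            rng.normal(0, scale, (c_out, c_in, kernel, kernel)), requires_grad=True
        )
        self.bias = Tensor(np.zeros(c_out), requires_grad=True)
        self.stride = stride
        self.padding = kernel // 2 if padding is None else padding

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, stride=self.stride, padding=self.padding)


class LayerNorm(Module):
    """Normalisation over the last axis."""

    def __init__(self, dim: int, eps: float = 1e-5):
        self.gamma = Tensor(np.ones(dim), requires_grad=True)
        self.beta = Tensor(np.zeros(dim), requires_grad=True)
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        inv = (var + self.eps) ** -0.5
        return xc * inv * self.gamma + self.beta


class SEBlock(Module):
    """Squeeze-and-excitation channel attention for (B,C,H,W) features.

    Global-average-pools each channel, passes the channel vector through a
    bottleneck MLP (reduction ratio ``r``) and rescales channels by the
    resulting sigmoid gates.
    """

    def __init__(self, channels: int, rng: np.random.Generator, reduction: int = 16):
        hidden = max(channels // reduction, 4)
        self.fc1 = Linear(channels, hidden, rng)
        self.fc2 = Linear(hidden, channels, rng)

    def forward(self, x: Tensor) -> Tensor:
        s = x.mean(axis=(2, 3))  # (B,C)
        s = self.fc2(self.fc1(s).relu()).sigmoid()
        b, c = s.shape
        return x * s.reshape(b, c, 1, 1)


class MultiHeadSelfAttention(Module):
    def __init__(self, dim: int, heads: int, rng: np.random.Generator):
        if dim % heads:
            raise ValueError("dim must be divisible by heads")
        self.heads = heads
        self.dim = dim
        self.qkv = Linear(dim, 3 * dim, rng)
        self.proj = Linear(dim, dim, rng)

    def forward(self, x: Tensor) -> Tensor:
        b, n, d = x.shape
        h = self.heads
        hd = d // h
        qkv = self.qkv(x).reshape(b, n, 3, h, hd).transpose(2, 0, 3, 1, 4)
        q = qkv.reshape(3, b * h, n, hd)
        # split via matmul-free slicing is unsupported; use three separate views
        qd, kd, vd = _split3(q)
        att = (qd @ kd.transpose(0, 2, 1)) * (1.0 / np.sqrt(hd))
        att = att.softmax(axis=-1)
        out = att @ vd  # (b*h, n, hd)
        out = out.reshape(b, h, n, hd).transpose(0, 2, 1, 3).reshape(b, n, d)
        return self.proj(out)


def _split3(x: Tensor) -> tuple[Tensor, Tensor, Tensor]:
    """Split the leading axis of size 3 into three tensors (autodiff-aware)."""
    outs = []
    for i in range(3):
        data = np.ascontiguousarray(x.data[i])

        def backward(g, i=i):
            full = np.zeros_like(x.data)
            full[i] = g
            x._accum(full)

        outs.append(Tensor._make(data, (x,), backward))
    return tuple(outs)


class TransformerEncoderLayer(Module):
    """Pre-norm transformer encoder layer with residual connections."""

    def __init__(self, dim: int, heads: int, rng: np.random.Generator, mlp_ratio: int = 4):
        self.norm1 = LayerNorm(dim)
        self.attn = MultiHeadSelfAttention(dim, heads, rng)
        self.norm2 = LayerNorm(dim)
        self.fc1 = Linear(dim, mlp_ratio * dim, rng)
        self.fc2 = Linear(mlp_ratio * dim, dim, rng)

    def forward(self, x: Tensor) -> Tensor:
        x = x + self.attn(self.norm1(x))
        return x + self.fc2(self.fc1(self.norm2(x)).relu())
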