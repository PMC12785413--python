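"""Network architectures: the noise-prediction U-Net with a transformer
mid-block, and the SE-augmented localization U-Net.

Both are defined at configurable width/depth so that a desk-scale profile
(32x32 inputs, narrow channels, shallow transformer) and a paper-scale
profile (128x128, transformer depth 12) share one implementation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .layers import (
    Conv2d,
    LayerNorm,
    Linear,
    Module,
    SEBlock,
    TransformerEncoderLayer,
)
from .tensor import Tensor, concat, no_grad, upsample2x

__all__ = [
    "DenoiserConfig",
    "LocalizerConfig",
    "DenoiserUNet",
    "SEUNetLocalizer",
    "sinusoidal_time_embedding",
]


def sinusoidal_time_embedding(t: np.ndarray, dim: int) -> np.ndarray:
    """Standard sinusoidal embedding of integer time-steps, shape (B, dim)."""
    t = np.asarray(t, dtype=np.float32).reshape(-1, 1)
    half = dim // 2
    freqs = np.exp(-np.log(10000.0) * np.arange(half, dtype=np.float32) / half)
    args = t * freqs[None, :]
    return np.concatenate([np.sin(args), np.cos(args)], axis=1).astype(np.float32)


@dataclass
class DenoiserConfig:
    base_width: int = 16
    transformer_depth: int = 2
    heads: int = 4
    time_dim: int = 64
    in_channels: int = 1

    def to_dict(self) -> dict:
        return dict(self.__dict__)


@dataclass
class LocalizerConfig:
    base_width: int = 16
    stages: int = 3
    se_reduction: int = 16
    in_channels: int = 2

    def to_dict(self) -> dict:
        return dict(self.__dict__)


class DenoiserUNet(Module):
    """Predicts the noise field eps from (x_t, t).

    Encoder/decoder with skip connections; the bottleneck flattens the
    spatial grid into tokens processed by a stack of transformer encoder
    layers (multi-head self-attention, residual connections, layer norm)
    with an additive sinusoidal time embedding.
    """

    def __init__(self, cfg: DenoiserConfig, rng: np.random.Generator):
        self.cfg = cfg
        w = cfg.base_width
        td = cfg.time_dim
        self.t_fc1 = Linear(td, td, rng)
        self.t_fc2 = Linear(td, td, rng)

        self.enc1a = Conv2d(cfg.in_channels, w, 3, rng)
        self.enc1b = Conv2d(w, w, 3, rng)
        self.t_proj1 = Linear(td, w, rng)
        self.down1 = Conv2d(w, 2 * w, 3, rng, stride=2)
        self.enc2 = Conv2d(2 * w, 2 * w, 3, rng)
        self.t_proj2 = Linear(td, 2 * w, rng)
        self.down2 = Conv2d(2 * w, 4 * w, 3, rng, stride=2)

        self.mid_in_norm = LayerNorm(4 * w)
        self.t_proj_mid = Linear(td, 4 * w, rng)
        self.blocks = [
            TransformerEncoderLayer(4 * w, cfg.heads, rng)
            for _ in range(cfg.transformer_depth)
        ]

        self.up2 = Conv2d(4 * w, 2 * w, 3, rng)
        self.dec2 = Conv2d(4 * w, 2 * w, 3, rng)
        self.up1 = Conv2d(2 * w, w, 3, rng)
        self.dec1 = Conv2d(2 * w, w, 3, rng)
        self.out = Conv2d(w, 1, 1, rng, padding=0)
        self.out.weight.data[...] = 0.0  # start from the noise-mean prediction

    def _temb(self, t: np.ndarray) -> Tensor:
        emb = sinusoidal_time_embedding(t, self.cfg.time_dim)
        return self.t_fc2(self.t_fc1(Tensor(emb)).gelu())

    def forward(self, x, t) -> Tensor:
        """x: Tensor or array (B,1,H,W); t: int array (B,) of time-steps."""
        x = Tensor.as_tensor(x)
        temb = self._temb(np.asarray(t))
        b = x.shape[0]

        h = self.enc1a(x).relu()
        h = self.enc1b(h)
        h = h + self.t_proj1(temb).reshape(b, -1, 1, 1)
        s1 = h.relu()

        h = self.down1(s1).relu()
        h = self.enc2(h)
        h = h + self.t_proj2(temb).reshape(b, -1, 1, 1)
        s2 = h.relu()

        h = self.down2(s2)
        _, c, hh, ww = h.shape
        tokens = h.reshape(b, c, hh * ww).transpose(0, 2, 1)
        tokens = self.mid_in_norm(tokens)
        tokens = tokens + self.t_proj_mid(temb).reshape(b, 1, c)
        for blk in self.blocks:
            tokens = blk(tokens)
        h = tokens.transpose(0, 2, 1).reshape(b, c, hh, ww)

        h = self.up2(upsample2x(h)).relu()
        h = self.dec2(concat([h, s2], axis=1)).relu()
        h = self.up1(upsample2x(h)).relu()
        h = self.dec1(concat([h, s1], axis=1)).relu()
        return self.out(h)

    def predict(self, x: np.ndarray, t) -> np.ndarray:
        """Inference entry point: numpy in, numpy out (no tape)."""
        with no_grad():
            return self.forward(Tensor(x), t).data


class SEUNetLocalizer(Module):
    """Segmentation U-Net with a squeeze-and-excitation block closing each
    encoder stage.  Takes the (input image, reconstruction) pair stacked on
    the channel axis and emits per-pixel logits; a terminal sigmoid (applied
    by the caller or :meth:`saliency`) maps them into (0, 1).
    """

    def __init__(self, cfg: LocalizerConfig, rng: np.random.Generator):
        self.cfg = cfg
        w = cfg.base_width
        chans = [cfg.in_channels] + [w * 2**i for i in range(cfg.stages)]
        self.enc_a = [Conv2d(chans[i], chans[i + 1], 3, rng) for i in range(cfg.stages)]
        self.enc_b = [Conv2d(chans[i + 1], chans[i + 1], 3, rng) for i in range(cfg.stages)]
        self.se = [
            SEBlock(chans[i + 1], rng, reduction=cfg.se_reduction)
            for i in range(cfg.stages)
        ]
        self.down = [
            Conv2d(chans[i + 1], chans[i + 1], 3, rng, stride=2)
            for i in range(cfg.stages)
        ]
        wb = chans[-1]
        self.bottleneck = Conv2d(wb, wb, 3, rng)
        self.up = [
            Conv2d(chans[i + 1], chans[i + 1], 3, rng)
            for i in reversed(range(cfg.stages))
        ]
        self.dec = [
            Conv2d(2 * chans[i + 1], chans[i], 3, rng) if i > 0 else
            Conv2d(2 * chans[1], w, 3, rng)
            for i in reversed(range(cfg.stages))
        ]
        self.out = Conv2d(w, 1, 1, rng, padding=0)

    def forward(self, x) -> Tensor:
        x = Tensor.as_tensor(x)
        skips = []
        h = x
        for a, bconv, se, down in zip(self.enc_a, self.enc_b, self.se, self.down):
            h = a(h).relu()
            h = bconv(h).relu()
            h = se(h)
            skips.append(h)
            h = down(h).relu()
        h = self.bottleneck(h).relu()
        for up, dec, skip in zip(self.up, self.dec, reversed(skips)):
            h = up(upsample2x(h)).relu()
            h = dec(concat([h, skip], axis=1)).relu()
        return self.out(h)

    def saliency(self, x: np.ndarray) -> np.ndarray:
        """Numpy inference: sigmoid of the logits, values in (0, 1)."""
        with no_grad():
            logits = self.forward(Tensor(x))
        return logits.sigmoid().data
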