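"""Training losses: gated noise-prediction MSE, smooth-L1 + focal mask
loss with a ramped focusing exponent, and their sum.

All losses accept numpy arrays or autodiff Tensors and return a scalar
Tensor (use ``float(...)`` for the value).  Gradients flow when inputs
are Tensors on the tape.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn.tensor import Tensor

__all__ = [
    "LossConfig",
    "noise_loss",
    "smooth_l1",
    "focal_loss",
    "mask_loss",
    "total_loss",
    "gamma_focal_at",
]


@dataclass
class LossConfig:
    alpha: float = 0.75  # focal class weight on fracture pixels
    gamma_focal_start: float = 2.0
    gamma_focal_end: float = 3.5
    ramp_steps: int = 100  # steps over which gamma_focal ramps linearly
    gamma_mask: float = 1.0  # weight of focal vs smooth-L1
    detach_reconstruction: bool = True
    eps_clip: float = 1e-6

    def __post_init__(self):
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if self.gamma_focal_start < 0 or self.gamma_focal_end < 0:
            raise ValueError("gamma_focal must be >= 0")


def gamma_focal_at(cfg: LossConfig, step: int) -> float:
    """Linear ramp of the focal exponent from start to end over the run."""
    if cfg.ramp_steps <= 1:
        return cfg.gamma_focal_end
    f = min(max(step, 0) / (cfg.ramp_steps - 1), 1.0)
    return cfg.gamma_focal_start + f * (cfg.gamma_focal_end - cfg.gamma_focal_start)


def _pair(a, b, name_a="a", name_b="b") -> tuple[Tensor, Tensor]:
    ta, tb = Tensor.as_tensor(a), Tensor.as_tensor(b)
    if ta.shape != tb.shape:
        raise ValueError(f"{name_a} shape {ta.shape} != {name_b} shape {tb.shape}")
    return ta, tb


def noise_loss(eps_true, eps_pred, y) -> Tensor:
    """L_noise = (1/3)·(1−y)·Σ_{t in triple} mean‖ε_t − ε̂_t‖².

    ``eps_true``/``eps_pred`` are sequences of three noise fields (one per
    sampled time-step).  Pseudofracture samples (y=1) are gated out: the
    denoiser is trained on normal images only.  ``y`` may be a scalar or a
    per-sample vector matching the leading batch axis.
    """
    if len(eps_true) != 3 or len(eps_pred) != 3:
        raise ValueError("expected three noise fields per argument")
    y_arr = np.asarray(y, dtype=np.float32)
    gate = 1.0 - y_arr
    total = None
    for et, ep in zip(eps_true, eps_pred):
        et, ep = _pair(et, ep, "eps_true", "eps_pred")
        sq = (ep - et) * (ep - et)
        if y_arr.ndim == 0:
            term = sq.mean() * float(gate)
        else:
            axes = tuple(range(1, len(sq.shape)))
            term = (sq.mean(axis=axes) * Tensor(gate)).mean()
        total = term if total is None else total + term
    return total * (1.0 / 3.0)


def smooth_l1(M, M_hat) -> Tensor:
    """Pixel-averaged smooth L1: 0.5(y−p)² if |y−p| < 1 else |y−p| − 0.5."""
    m, p = _pair(M, M_hat, "M", "M_hat")
    m = Tensor(m.data.astype(np.float32)) if not m.requires_grad else m
    d = p - m
    quad = np.abs(d.data) < 1.0
    sign = np.sign(d.data)
    loss = d * d * (0.5 * quad) + d * ((1.0 - quad) * sign) - (1.0 - quad) * 0.5
    return loss.mean()


def focal_loss(M, M_hat, alpha: float = 0.75, gamma: float = 2.0, eps_clip: float = 1e-6) -> Tensor:
    """Class-weighted focal loss on per-pixel binary targets.

    Per pixel: α_t·(1−p_t)^γ·BCE(y, p) with p_t = y·p + (1−y)(1−p) and
    α_t = α for fracture pixels, 1−α otherwise; averaged over pixels.
    """
    m, p = _pair(M, M_hat, "M", "M_hat")
    y = m.data.astype(np.float32)
    p = p.clamp(eps_clip, 1.0 - eps_clip)
    pt = p * y + (1.0 - p) * (1.0 - y)
    at = alpha * y + (1.0 - alpha) * (1.0 - y)
    bce = -(pt.log())
    if gamma == 0.0:
        return (bce * at).mean()
    return (((1.0 - pt) ** gamma) * at * bce).mean()


def mask_loss(M, M_hat, cfg: LossConfig | None = None, step: int = 0) -> Tensor:
    """L_mask = smooth_L1 + γ_mask · focal, with the focal exponent ramped
    linearly from its start to end value across the configured run."""
    cfg = cfg or LossConfig()
    gamma = gamma_focal_at(cfg, step)
    l_sl1 = smooth_l1(M, M_hat)
    if cfg.gamma_mask == 0.0:
        return l_sl1
    l_focal = focal_loss(M, M_hat, alpha=cfg.alpha, gamma=gamma, eps_clip=cfg.eps_clip)
    return l_sl1 + cfg.gamma_mask * l_focal


def total_loss(noise_term, mask_term) -> Tensor:
    """L_total = L_noise + L_mask."""
    return Tensor.as_tensor(noise_term) + Tensor.as_tensor(mask_term)
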