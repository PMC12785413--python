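"""Stage II — DDPM forward/reverse algebra and multi-time-step
normal-image-guided one-step reconstruction (ING).

The forward process is the standard variance-preserving diffusion
    x_t = sqrt(alpha_bar_t) * x0 + sqrt(1 - alpha_bar_t) * eps,
and its one-step inverse
    x0_hat = (x_t - sqrt(1 - alpha_bar_t) * eps_hat) / sqrt(alpha_bar_t).

ING samples one time-step from each of three schedule segments
(short / medium / long), reconstructs x0_hat at the medium and long
steps, renoises those reconstructions back to the short step and uses
their deviation from x_{t_s} as a guidance term that corrects the
predicted noise before the final one-step reconstruction:

    delta   = w1 * (x_{t_s | x0_hat,m} - x_{t_s}) + w2 * (x_{t_s | x0_hat,l} - x_{t_s})
    eps_g   = eps_theta(x_{t_s}, t_s) - sqrt(1 - alpha_bar_{t_s}) * delta
    x0_g    = (x_{t_s} - sqrt(1 - alpha_bar_{t_s}) * eps_g) / sqrt(alpha_bar_{t_s})

By default the same noise realization used to form x_{t_s} is reused when
renoising the medium/long reconstructions, which makes the guidance term
deterministic given eps and admits a closed-form check with an oracle
denoiser.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np

__all__ = [
    "NoiseSchedule",
    "TimestepTriple",
    "GuidanceConfig",
    "build_schedule",
    "forward_diffuse",
    "predict_x0",
    "sample_timestep_triple",
    "ing_reconstruct",
    "reconstruct_batch",
    "oracle_denoiser",
]


@dataclass
class NoiseSchedule:
    """Per-time-step noise tables, 1-based with alpha_bar[0] = 1."""

    T: int
    beta: np.ndarray  # (T+1,), beta[0] = 0 by convention
    alpha: np.ndarray  # (T+1,), alpha[t] = 1 - beta[t]
    alpha_bar: np.ndarray  # (T+1,), cumulative product, alpha_bar[0] = 1
    segments: tuple  # three (lo, hi] index intervals, ordered & disjoint

    def __post_init__(self):
        if not (self.alpha_bar[0] == 1.0):
            raise ValueError("alpha_bar[0] must be 1")
        if np.any(np.diff(self.alpha_bar) >= 0):
            raise ValueError("alpha_bar must be strictly decreasing")


@dataclass
class TimestepTriple:
    t_s: int
    t_m: int
    t_l: int

    def __post_init__(self):
        if not (0 < self.t_s < self.t_m < self.t_l):
            raise ValueError("require 0 < t_s < t_m < t_l")

    def as_tuple(self) -> tuple[int, int, int]:
        return (self.t_s, self.t_m, self.t_l)


@dataclass
class GuidanceConfig:
    w1: float = 0.5
    w2: float = 0.5
    mode: str = "fixed"  # "fixed" | "random"
    triple: tuple | None = None  # fixed-mode triple; default = segment upper bounds
    reuse_noise: bool = True

    def __post_init__(self):
        if self.w1 < 0 or self.w2 < 0:
            raise ValueError("guidance weights must be >= 0")
        if self.mode not in ("fixed", "random"):
            raise ValueError("mode must be 'fixed' or 'random'")


def build_schedule(
    T: int,
    kind: str = "linear",
    beta_bounds: tuple = (1e-4, 0.02),
    segments: tuple | None = None,
) -> NoiseSchedule:
    """Linear beta schedule with short/medium/long segment partition.

    Default segments scale the reference partition (0,300], (300,500],
    (500,700] of a 1000-step schedule proportionally, i.e. fractions
    0.3 / 0.5 / 0.7 of T.
    """
    if T < 3:
        raise ValueError("T must be >= 3")
    if kind != "linear":
        raise ValueError(f"unknown schedule kind {kind!r}")
    lo, hi = beta_bounds
    if not (0.0 < lo <= hi < 1.0):
        raise ValueError("beta bounds must satisfy 0 < lo <= hi < 1")
    beta = np.zeros(T + 1, dtype=np.float64)
    beta[1:] = np.linspace(lo, hi, T)
    alpha = 1.0 - beta
    alpha_bar = np.cumprod(alpha)
    alpha_bar[0] = 1.0

    if segments is None:
        b1, b2, b3 = round(0.3 * T), round(0.5 * T), round(0.7 * T)
        segments = ((0, b1), (b1, b2), (b2, b3))
    segments = tuple((int(a), int(b)) for a, b in segments)
    prev_hi = 0
    for a, b in segments:
        if a != prev_hi or b <= a or b > T:
            raise ValueError(f"invalid segment partition {segments}")
        prev_hi = b
    return NoiseSchedule(T=T, beta=beta, alpha=alpha, alpha_bar=alpha_bar, segments=segments)


def _bar(sched: NoiseSchedule, t, ndim: int) -> tuple[np.ndarray, np.ndarray]:
    """sqrt(alpha_bar_t), sqrt(1 - alpha_bar_t) broadcast against an
    array with `ndim` dimensions (per-sample t along the leading axis)."""
    t = np.asarray(t)
    ab = sched.alpha_bar[t]
    if t.ndim > 0:
        ab = ab.reshape((-1,) + (1,) * (ndim - 1))
    return np.sqrt(ab), np.sqrt(1.0 - ab)


def forward_diffuse(x0: np.ndarray, t, eps: np.ndarray, sched: NoiseSchedule) -> np.ndarray:
    """x_t = sqrt(alpha_bar_t)*x0 + sqrt(1-alpha_bar_t)*eps."""
    if np.any(np.asarray(t) < 0) or np.any(np.asarray(t) > sched.T):
        raise ValueError(f"t out of range [0, {sched.T}]")
    if eps.shape != x0.shape:
        raise ValueError("eps must match x0 shape")
    sa, sb = _bar(sched, t, x0.ndim)
    return (sa * x0 + sb * eps).astype(np.float32)


def predict_x0(x_t: np.ndarray, t, eps_hat: np.ndarray, sched: NoiseSchedule) -> np.ndarray:
    """One-step inversion: x0_hat = (x_t - sqrt(1-ab_t)*eps_hat)/sqrt(ab_t)."""
    if np.any(np.asarray(t) < 1):
        raise ValueError("t must be >= 1 (alpha_bar[0] = 1 makes t=0 trivial)")
    if np.any(np.asarray(t) > sched.T):
        raise ValueError(f"t out of range [1, {sched.T}]")
    sa, sb = _bar(sched, t, x_t.ndim)
    return ((x_t - sb * eps_hat) / sa).astype(np.float32)


def default_triple(sched: NoiseSchedule) -> TimestepTriple:
    """Segment upper bounds — the reference configuration (300/500/700 at
    T=1000)."""
    return TimestepTriple(*(b for _, b in sched.segments))


def sample_timestep_triple(
    sched: NoiseSchedule, cfg: GuidanceConfig, seed: int = 0
) -> TimestepTriple:
    """Fixed mode returns the configured triple; random mode samples one
    step uniformly from each segment."""
    if cfg.mode == "fixed":
        if cfg.triple is not None:
            return TimestepTriple(*cfg.triple)
        return default_triple(sched)
    rng = np.random.default_rng(seed)
    steps = [int(rng.integers(a + 1, b + 1)) for a, b in sched.segments]
    return TimestepTriple(*steps)


def ing_reconstruct(
    x_in: np.ndarray,
    den,
    sched: NoiseSchedule,
    triple: TimestepTriple | None = None,
    cfg: GuidanceConfig | None = None,
    seed: int = 0,
    eps: np.ndarray | None = None,
) -> tuple[np.ndarray, dict]:
    """Multi-time-step guided one-step reconstruction of a single image.

    `den` is a callable (x_t batch (B,1,H,W), t array (B,)) -> eps_hat.
    Returns the clipped reconstruction and the intermediate quantities
    (noisy inputs, per-step reconstructions, guidance term, guided noise,
    unclipped result) for inspection and testing.
    """
    cfg = cfg or GuidanceConfig()
    triple = triple or sample_timestep_triple(sched, cfg, seed)
    if triple.t_l > sched.T:
        raise ValueError("triple exceeds schedule length")
    rng = np.random.default_rng(seed)
    if eps is None:
        eps = rng.standard_normal(x_in.shape).astype(np.float32)

    t_s, t_m, t_l = triple.as_tuple()
    x_ts = forward_diffuse(x_in, t_s, eps, sched)
    x_tm = forward_diffuse(x_in, t_m, eps, sched)
    x_tl = forward_diffuse(x_in, t_l, eps, sched)

    def _den(x, t):
        out = den(x[None, None], np.array([t]))
        return np.asarray(out)[0, 0]

    xhat0_m = predict_x0(x_tm, t_m, _den(x_tm, t_m), sched)
    xhat0_l = predict_x0(x_tl, t_l, _den(x_tl, t_l), sched)

    if cfg.reuse_noise:
        eps_m = eps_l = eps
    else:
        eps_m = rng.standard_normal(x_in.shape).astype(np.float32)
        eps_l = rng.standard_normal(x_in.shape).astype(np.float32)
    x_ts_m = forward_diffuse(xhat0_m, t_s, eps_m, sched)
    x_ts_l = forward_diffuse(xhat0_l, t_s, eps_l, sched)

    delta = cfg.w1 * (x_ts_m - x_ts) + cfg.w2 * (x_ts_l - x_ts)
    sb_s = np.sqrt(1.0 - sched.alpha_bar[t_s])
    eps_hat_s = _den(x_ts, t_s)
    eps_g = eps_hat_s - sb_s * delta
    x0_raw = predict_x0(x_ts, t_s, eps_g, sched)
    x0_guide = np.clip(x0_raw, 0.0, 1.0).astype(np.float32)

    intermediates = {
        "triple": triple,
        "eps": eps,
        "x_ts": x_ts,
        "x_tm": x_tm,
        "x_tl": x_tl,
        "xhat0_m": xhat0_m,
        "xhat0_l": xhat0_l,
        "delta": delta,
        "eps_hat_s": eps_hat_s,
        "eps_g": eps_g,
        "x0_raw": x0_raw,
    }
    return x0_guide, intermediates


def _image_seed(seed: int, img: np.ndarray) -> int:
    """Per-image seed tied to image content (order-independent)."""
    crc = zlib.crc32(np.ascontiguousarray(img, dtype=np.float32).tobytes())
    return int(np.random.SeedSequence([int(seed), crc]).generate_state(1)[0] % (2**31))


def reconstruct_batch(
    images: list[np.ndarray] | np.ndarray,
    den,
    sched: NoiseSchedule,
    cfg: GuidanceConfig | None = None,
    seed: int = 0,
) -> np.ndarray:
    """ING-reconstruct a batch; each image gets an independent noise draw
    derived from its own content, so results are order-equivariant and
    deterministic per seed.  The time-step triple is shared per call."""
    cfg = cfg or GuidanceConfig()
    triple = sample_timestep_triple(sched, cfg, seed)
    out = []
    for img in images:
        img = np.asarray(img, dtype=np.float32)
        x0_g, _ = ing_reconstruct(
            img, den, sched, triple=triple, cfg=cfg, seed=_image_seed(seed, img)
        )
        out.append(x0_g)
    return np.stack(out)


def oracle_denoiser(target: np.ndarray, sched: NoiseSchedule):
    """Analytic denoiser that believes every noisy input came from
    ``target``: eps_hat = (x_t - sqrt(ab_t)*target) / sqrt(1-ab_t).

    Used as the independent oracle for the guided-reconstruction algebra.
    """

    def den(x_t: np.ndarray, t: np.ndarray) -> np.ndarray:
        sa, sb = _bar(sched, t, x_t.ndim)
        return (x_t - sa * target[None, None]) / sb

    return den
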