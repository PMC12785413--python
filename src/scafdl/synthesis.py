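"""Stage I — self-supervised pseudofracture synthesis.

A healthy image N is turned into a training pair (S, M): a random
fracture-shaped polyline P is constrained to the bone foreground F
(M = F ⊙ P), filled with texture from a bank at opacity β
(A = β·T + (1−β)·N) and blended back (S = M ⊙ A + (1−M) ⊙ N).
Stochastic photometric/geometric augmentation provides the variability
the localizer must become invariant to.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage import exposure
from skimage.draw import line as _draw_line
from skimage.filters import threshold_otsu
from skimage.morphology import disk

from .errors import DegenerateInputError
from .phantom import TextureBank

__all__ = [
    "FractureShape",
    "PseudoSample",
    "AugOp",
    "AugmentationPool",
    "SynthesisConfig",
    "segment_foreground",
    "sample_fracture_shape",
    "transform_shape_mask",
    "make_anomaly_mask",
    "fill_texture",
    "blend_pseudofracture",
    "augment_pair",
    "synthesize_batch",
]


@dataclass
class FractureShape:
    mask: np.ndarray  # bool (H, W), dilated rasterized polyline
    vertices: list  # [(row, col), ...] endpoints + 1..5 interior points
    thickness: int

    def __post_init__(self):
        if not self.mask.any():
            raise ValueError("fracture shape mask is empty")


@dataclass
class PseudoSample:
    S: np.ndarray  # float32 (H, W)
    M: np.ndarray  # bool (H, W)
    y: int  # 1 iff M non-empty
    source_id: int = -1


def segment_foreground(
    N: np.ndarray, method: str = "threshold", oracle_mask: np.ndarray | None = None
) -> np.ndarray:
    """Binary foreground mask of the bone region.

    ``oracle`` returns the generator's stored mask (exact); ``threshold``
    is Otsu thresholding followed by largest-connected-component selection
    and hole filling, the stand-in for a segmentation network.
    """
    if method == "oracle":
        if oracle_mask is None:
            raise ValueError("oracle method requires oracle_mask")
        return oracle_mask.astype(bool)
    if method != "threshold":
        raise ValueError(f"unknown method {method!r}")
    if np.ptp(N) == 0:
        raise DegenerateInputError("constant image has no foreground")
    mask = N > threshold_otsu(N)
    labels, n = ndi.label(mask)
    if n == 0:
        raise DegenerateInputError("threshold segmentation found no foreground")
    largest = 1 + np.argmax(ndi.sum_labels(mask, labels, index=range(1, n + 1)))
    mask = ndi.binary_fill_holes(labels == largest)
    if not mask.any():
        raise DegenerateInputError("empty foreground after post-processing")
    return mask


def sample_fracture_shape(seed: int, size: int, thickness: int = 1) -> FractureShape:
    """Random fracture-shaped polyline spanning the image.

    Two endpoints are placed on opposite halves of the image border, with
    k ~ Uniform{1..5} jittered interior points between them; the polyline
    is rasterized with Bresenham segments and dilated to ``thickness``.
    """
    if size < 32:
        raise ValueError(f"size must be >= 32, got {size}")
    rng = np.random.default_rng(seed)
    if rng.random() < 0.5:  # left/right border halves
        p0 = (int(rng.integers(0, size)), 0)
        p1 = (int(rng.integers(0, size)), size - 1)
    else:  # top/bottom border halves
        p0 = (0, int(rng.integers(0, size)))
        p1 = (size - 1, int(rng.integers(0, size)))

    k = int(rng.integers(1, 6))
    a = np.array(p0, dtype=float)
    b = np.array(p1, dtype=float)
    span = np.linalg.norm(b - a)
    d = (b - a) / span
    perp = np.array([-d[1], d[0]])
    pts = [p0]
    for i in range(1, k + 1):
        f = i / (k + 1)
        off = rng.uniform(-0.15, 0.15) * span
        p = np.clip(np.round(a + f * (b - a) + off * perp), 0, size - 1).astype(int)
        pts.append((int(p[0]), int(p[1])))
    pts.append(p1)

    mask = np.zeros((size, size), dtype=bool)
    for (r0, c0), (r1, c1) in zip(pts[:-1], pts[1:]):
        rr, cc = _draw_line(r0, c0, r1, c1)
        mask[rr, cc] = True
    if thickness > 0:
        mask = ndi.binary_dilation(mask, structure=disk(thickness))
    return FractureShape(mask=mask, vertices=pts, thickness=thickness)


def transform_shape_mask(mask: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Aggressive geometric jitter of the fracture shape before foreground
    masking: rotation ±90°, shear 0–40°, translation ±50 %, scale 50–100 %."""
    h, w = mask.shape
    theta = np.deg2rad(rng.uniform(-90, 90))
    shear = np.deg2rad(rng.uniform(0, 40))
    scale = rng.uniform(0.5, 1.0)
    t_r = rng.uniform(-0.5, 0.5) * h
    t_c = rng.uniform(-0.5, 0.5) * w
    c, s = np.cos(theta), np.sin(theta)
    rot = np.array([[c, -s], [s, c]])
    shr = np.array([[1.0, np.tan(shear)], [0.0, 1.0]])
    lin = rot @ shr * scale
    center = np.array([(h - 1) / 2.0, (w - 1) / 2.0])
    # affine_transform maps output coords through `matrix @ o + offset` to input
    inv = np.linalg.inv(lin)
    offset = center - inv @ (center + np.array([t_r, t_c]))
    return ndi.affine_transform(
        mask.astype(np.float32), inv, offset=offset, order=0, mode="constant", cval=0.0
    ) > 0.5


def make_anomaly_mask(F: np.ndarray, shape: FractureShape | np.ndarray) -> np.ndarray:
    """M = F ⊙ P: the fracture shape restricted to the bone foreground."""
    P = shape.mask if isinstance(shape, FractureShape) else shape
    if F.shape != P.shape:
        raise ValueError(f"shape mismatch: {F.shape} vs {P.shape}")
    return F.astype(bool) & P.astype(bool)


def fill_texture(
    M: np.ndarray,
    bank: TextureBank,
    N: np.ndarray,
    beta: float,
    seed: int,
) -> np.ndarray:
    """Opacity blend A = β·T + (1−β)·N with a bank patch T chosen per seed.

    Defined on every pixel; the anomaly mask is applied later in the blend.
    """
    if not bank.patches:
        raise ValueError("texture bank is empty")
    if not 0.0 <= beta <= 1.0:
        raise ValueError("beta must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    T = bank.patches[int(rng.integers(0, len(bank.patches)))]
    T = _fit_patch(T, N.shape)
    if M.shape != N.shape:
        raise ValueError(f"shape mismatch: {M.shape} vs {N.shape}")
    return (beta * T + (1.0 - beta) * N).astype(np.float32)


def _fit_patch(T: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Tile/crop a bank patch to the target image size."""
    if T.shape == shape:
        return T
    reps = (int(np.ceil(shape[0] / T.shape[0])), int(np.ceil(shape[1] / T.shape[1])))
    return np.tile(T, reps)[: shape[0], : shape[1]]


def blend_pseudofracture(
    N: np.ndarray, A: np.ndarray, M: np.ndarray, source_id: int = -1
) -> PseudoSample:
    """S = M ⊙ A + (1−M) ⊙ N, clipped to [0, 1]; y = [M non-empty]."""
    if not (N.shape == A.shape == M.shape):
        raise ValueError("N, A, M must share a shape")
    Mf = M.astype(np.float32)
    S = np.clip(Mf * A + (1.0 - Mf) * N, 0.0, 1.0).astype(np.float32)
    return PseudoSample(S=S, M=M.astype(bool), y=int(M.any()), source_id=source_id)


# --------------------------------------------------------------------------
# augmentation pool


@dataclass
class AugOp:
    name: str
    kind: str  # "photometric" | "geometric"

    def sample_params(self, rng: np.random.Generator) -> dict:
        if self.name == "gamma":
            return {"gamma": rng.uniform(0.5, 2.0)}
        if self.name == "brightness":
            return {"gain": rng.uniform(0.8, 1.2), "offset": rng.uniform(-30, 30) / 255.0}
        if self.name == "solarize":
            return {"threshold": rng.uniform(32, 128) / 255.0}
        if self.name == "rotate":
            return {"angle": rng.uniform(-45.0, 45.0)}
        return {}

    def apply(self, img: np.ndarray, mask: np.ndarray, params: dict):
        if self.name == "gamma":
            return np.power(np.clip(img, 0, 1), params["gamma"]), mask
        if self.name == "brightness":
            return img * params["gain"] + params["offset"], mask
        if self.name == "solarize":
            out = np.where(img > params["threshold"], 1.0 - img, img)
            return out, mask
        if self.name == "autocontrast":
            lo, hi = img.min(), img.max()
            return (img - lo) / (hi - lo) if hi > lo else img, mask
        if self.name == "equalize":
            return exposure.equalize_hist(np.clip(img, 0, 1)), mask
        if self.name == "rotate":
            img2 = ndi.rotate(img, params["angle"], reshape=False, order=1, mode="nearest")
            mask2 = (
                ndi.rotate(
                    mask.astype(np.float32), params["angle"], reshape=False, order=0
                )
                > 0.5
            )
            return img2, mask2
        raise ValueError(f"unknown op {self.name!r}")


def _default_ops() -> list[AugOp]:
    return [
        AugOp("gamma", "photometric"),
        AugOp("brightness", "photometric"),
        AugOp("solarize", "photometric"),
        AugOp("autocontrast", "photometric"),
        AugOp("equalize", "photometric"),
        AugOp("rotate", "geometric"),
    ]


@dataclass
class AugmentationPool:
    """Merged photometric + geometric op pool; exactly 3 ops are drawn
    without replacement per application."""

    ops: list = field(default_factory=_default_ops)
    draws: int = 3

    @classmethod
    def photometric_only(cls) -> "AugmentationPool":
        return cls(ops=[op for op in _default_ops() if op.kind == "photometric"])

    @classmethod
    def single(cls, name: str) -> "AugmentationPool":
        ops = [op for op in _default_ops() if op.name == name]
        return cls(ops=ops, draws=1)


def augment_pair(
    S: np.ndarray, M: np.ndarray, pool: AugmentationPool, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Apply ``pool.draws`` randomly chosen ops; geometric ops move image
    and mask identically (nearest-neighbour for the mask), photometric ops
    touch the image only.  Output image is clipped to [0, 1]."""
    rng = np.random.default_rng(seed)
    n = min(pool.draws, len(pool.ops))
    idx = rng.choice(len(pool.ops), size=n, replace=False)
    img, mask = S, M.astype(bool)
    for i in idx:
        op = pool.ops[int(i)]
        img, mask = op.apply(img, mask, op.sample_params(rng))
    return np.clip(img, 0.0, 1.0).astype(np.float32), mask.astype(bool)


# --------------------------------------------------------------------------
# batch synthesis


@dataclass
class SynthesisConfig:
    ratio: float = 0.5  # fraction of pseudofracture (y=1) samples per batch
    beta_range: tuple = (0.5, 1.0)
    thickness: int = 1
    shape_transforms: bool = True
    max_retries: int = 8


def synthesize_batch(
    normals: list,
    bank: TextureBank,
    config: SynthesisConfig | None = None,
    seed: int = 0,
) -> list[PseudoSample]:
    """Turn a list of (N, F) healthy image/foreground pairs into a training
    batch with the configured normal/pseudofracture mix (default 50/50).

    y=0 samples pass through untouched; y=1 samples get a foreground-
    constrained pseudofracture.  If an aggressively transformed shape
    misses the foreground entirely, a fresh shape is drawn.
    """
    if not normals:
        raise ValueError("normals must be non-empty")
    cfg = config or SynthesisConfig()
    rng = np.random.default_rng(seed)
    n = len(normals)
    n_pseudo = int(round(n * cfg.ratio))
    pseudo_idx = set(rng.choice(n, size=n_pseudo, replace=False).tolist())

    out: list[PseudoSample] = []
    for i, (N, F) in enumerate(normals):
        if i not in pseudo_idx:
            out.append(PseudoSample(S=N.astype(np.float32), M=np.zeros_like(F, dtype=bool), y=0, source_id=i))
            continue
        size = N.shape[0]
        M = None
        # aggressively transformed shapes can miss the foreground; retry,
        # then fall back to untransformed border-to-border shapes
        for attempt in range(2 * cfg.max_retries):
            shape = sample_fracture_shape(
                int(rng.integers(0, 2**31)), size=size, thickness=cfg.thickness
            )
            P = shape.mask
            if cfg.shape_transforms and attempt < cfg.max_retries:
                P = transform_shape_mask(P, rng)
            cand = make_anomaly_mask(F, P)
            if cand.any():
                M = cand
                break
        if M is None:
            raise DegenerateInputError(
                "could not place a fracture shape inside the foreground"
            )
        beta = rng.uniform(*cfg.beta_range)
        A = fill_texture(M, bank, N, beta=beta, seed=int(rng.integers(0, 2**31)))
        out.append(blend_pseudofracture(N, A, M, source_id=i))
    return out
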