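"""Synthetic phantom-radiograph generator.

Every stage of the pipeline is exercised on images produced here: a
bright, smoothly shaded, roughly elliptical "bone" on a cluttered darker
background, with optional thin dark fracture lines and exact pixel-level
ground-truth masks.  Phantoms make no claim of anatomical realism; they
reproduce the *statistical* features the reconstruction and localization
stages depend on — a connected high-intensity foreground of variable
size and orientation, smooth intensity ("bone density") variation, faint
elongated distractor structures, and fractures that appear as thin dark
polylines strictly inside the foreground.

All outputs are pure functions of their seeds and arguments.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from scipy import ndimage as ndi
from scipy.special import gamma as _gamma_fn
from skimage.draw import line as _draw_line
from skimage.morphology import disk


def _bdilate(mask: np.ndarray, radius: int) -> np.ndarray:
    return ndi.binary_dilation(mask, structure=disk(radius))


def _berode(mask: np.ndarray, radius: int) -> np.ndarray:
    return ndi.binary_erosion(mask, structure=disk(radius))

from .errors import DegenerateInputError

__all__ = [
    "Phantom",
    "TextureBank",
    "DatasetManifest",
    "ManifestEntry",
    "SEVERITIES",
    "generate_phantom",
    "inscribe_true_fracture",
    "generate_texture_bank",
    "build_dataset",
    "load_manifest",
    "read_image",
    "read_mask",
]

SEVERITIES = ("subtle", "line", "displaced")

# mean multiplicative intensity drop inside the fracture mask, per severity
_SEVERITY_DROP = {"subtle": 0.18, "line": 0.45, "displaced": 0.60}
_SEVERITY_RADIUS = {"subtle": 1, "line": 1, "displaced": 2}


@dataclass
class Phantom:
    """A synthetic radiograph crop with its exact foreground mask."""

    image: np.ndarray  # float32 (H, W) in [0, 1]
    foreground: np.ndarray  # bool (H, W)
    meta: dict = field(default_factory=dict)


@dataclass
class TextureBank:
    """Patches used to fill pseudofracture interiors.

    ``bone-overlap-like`` patches are band-limited noise of moderate
    variance (standing in for overlapping-bone texture); ``background-like``
    patches are near-uniform and dark.
    """

    patches: list  # list of float32 (H, W) arrays in [0, 1]
    tags: list  # parallel list of provenance tags

    def __post_init__(self):
        if not self.patches:
            raise ValueError("texture bank must be non-empty")


@dataclass
class ManifestEntry:
    path: str
    label: int  # 1 = fractured
    mask_path: str | None = None


@dataclass
class DatasetManifest:
    root: str
    train: list
    test: list
    seed: int

    def __post_init__(self):
        for e in self.train:
            if e.label != 0:
                raise ValueError("train split must contain only normal (y=0) images")
        for e in self.test:
            if e.label == 1 and not e.mask_path:
                raise ValueError("every fractured test entry needs a mask path")

    def save(self, path: Path | str) -> None:
        # root stored relative to the manifest file: same-seed datasets
        # produce byte-identical manifests wherever they are written
        path = Path(path)
        root = Path(self.root).resolve()
        try:
            rel = str(root.relative_to(path.resolve().parent))
        except ValueError:
            rel = str(root)
        payload = {
            "root": rel,
            "seed": self.seed,
            "train": [e.__dict__ for e in self.train],
            "test": [e.__dict__ for e in self.test],
        }
        path.write_text(json.dumps(payload, indent=1))


def load_manifest(path: Path | str) -> DatasetManifest:
    path = Path(path)
    payload = json.loads(path.read_text())
    root = Path(payload["root"])
    if not root.is_absolute():
        root = path.parent / root
    return DatasetManifest(
        root=str(root),
        train=[ManifestEntry(**e) for e in payload["train"]],
        test=[ManifestEntry(**e) for e in payload["test"]],
        seed=payload["seed"],
    )


def _superellipse_mask(
    size: int, center, axes, angle: float, exponent: float
) -> np.ndarray:
    rows, cols = np.mgrid[0:size, 0:size].astype(np.float32)
    dr = rows - center[0]
    dc = cols - center[1]
    ca, sa = np.cos(angle), np.sin(angle)
    u = ca * dc + sa * dr
    v = -sa * dc + ca * dr
    return (
        np.abs(u / axes[0]) ** exponent + np.abs(v / axes[1]) ** exponent
    ) <= 1.0


def _smooth_noise(rng: np.random.Generator, size: int, sigma: float) -> np.ndarray:
    g = ndi.gaussian_filter(rng.standard_normal((size, size)), sigma)
    g -= g.mean()
    s = g.std()
    return g / s if s > 0 else g


def generate_phantom(seed: int, size: int = 128, params: dict | None = None) -> Phantom:
    """Generate one phantom radiograph crop.

    The foreground is a rotated super-ellipse whose area is sampled so the
    foreground covers 15-60 % of the image; its intensity is modulated by a
    Gaussian-smoothed low-frequency density field.  The background carries
    smooth clutter, 1-3 faint elongated distractor blobs (emulating
    interference from neighbouring bones) and mild pixel noise.
    """
    if size < 32:
        raise ValueError(f"size must be >= 32, got {size}")
    params = dict(params or {})
    rng = np.random.default_rng(seed)

    # super-ellipse area = 4ab * Gamma(1+1/p)^2 / Gamma(1+2/p)
    exponent = params.get("exponent", rng.uniform(1.8, 3.0))
    aspect = params.get("aspect", rng.uniform(0.55, 0.95))
    angle = params.get("angle", rng.uniform(0.0, np.pi))
    frac = params.get("target_fraction", rng.uniform(0.22, 0.50))
    shape_factor = 4.0 * _gamma_fn(1 + 1 / exponent) ** 2 / _gamma_fn(1 + 2 / exponent)

    foreground = None
    center = axes = None
    for attempt in range(8):
        jitter = 0.08 * size / (attempt + 1)
        c = (
            size / 2 + rng.uniform(-jitter, jitter),
            size / 2 + rng.uniform(-jitter, jitter),
        )
        a = np.sqrt(frac * size * size / (shape_factor * aspect))
        ax = (a, aspect * a)
        mask = _superellipse_mask(size, c, ax, angle, exponent)
        got = mask.mean()
        if 0.15 <= got <= 0.60:
            foreground, center, axes = mask, c, ax
            break
        frac = float(np.clip(frac * (0.35 / max(got, 1e-6)) ** 0.5, 0.18, 0.50))
    if foreground is None:  # pragma: no cover - defensive
        raise RuntimeError("could not place a valid foreground")

    # bone shading: base intensity x low-frequency density field
    base = params.get("bone_intensity", rng.uniform(0.60, 0.75))
    density = 1.0 + 0.12 * _smooth_noise(rng, size, sigma=size / 8)
    density = np.clip(density, 0.75, 1.25)

    # background: dark base + smooth clutter + elongated distractors
    bg = rng.uniform(0.08, 0.16) + 0.05 * _smooth_noise(rng, size, sigma=size / 10)
    n_distract = rng.integers(1, 4)
    for _ in range(n_distract):
        dc = (rng.uniform(0, size), rng.uniform(0, size))
        da = (rng.uniform(0.15, 0.45) * size, rng.uniform(0.03, 0.10) * size)
        dmask = _superellipse_mask(size, dc, da, rng.uniform(0, np.pi), 2.0)
        blob = ndi.gaussian_filter(dmask.astype(np.float32), size / 40)
        bg = bg + rng.uniform(0.10, 0.22) * blob

    alpha = ndi.gaussian_filter(foreground.astype(np.float32), 1.0)
    image = bg * (1.0 - alpha) + base * density * alpha
    image = image + rng.normal(0.0, 0.015, (size, size))
    image = np.clip(image, 0.0, 1.0).astype(np.float32)

    meta = {
        "seed": int(seed),
        "size": int(size),
        "center": tuple(float(x) for x in center),
        "axes": tuple(float(x) for x in axes),
        "angle": float(angle),
        "exponent": float(exponent),
        "bone_intensity": float(base),
        "foreground_fraction": float(foreground.mean()),
    }
    return Phantom(image=image, foreground=foreground, meta=meta)


def _fracture_polyline(
    rng: np.random.Generator, interior: np.ndarray, n_interior: int
) -> list[tuple[int, int]]:
    """Endpoints on opposite extremes of the interior along a random
    direction, with `n_interior` jittered way-points between them."""
    coords = np.argwhere(interior)
    phi = rng.uniform(0, np.pi)
    d = np.array([np.sin(phi), np.cos(phi)])
    proj = coords @ d
    lo = coords[int(np.argmin(proj))]
    hi = coords[int(np.argmax(proj))]
    span = np.linalg.norm(hi - lo)
    perp = np.array([-d[1], d[0]])
    pts = [tuple(int(v) for v in lo)]
    h, w = interior.shape
    for i in range(1, n_interior + 1):
        f = i / (n_interior + 1)
        base = lo + f * (hi - lo)
        off = rng.uniform(-0.12, 0.12) * span
        p = np.clip(np.round(base + off * perp), 0, [h - 1, w - 1]).astype(int)
        pts.append((int(p[0]), int(p[1])))
    pts.append(tuple(int(v) for v in hi))
    return pts


def _rasterize_polyline(
    points: list[tuple[int, int]], shape: tuple[int, int], radius: int
) -> np.ndarray:
    mask = np.zeros(shape, dtype=bool)
    for (r0, c0), (r1, c1) in zip(points[:-1], points[1:]):
        rr, cc = _draw_line(r0, c0, r1, c1)
        mask[rr, cc] = True
    if radius > 0:
        mask = _bdilate(mask, radius)
    return mask


def inscribe_true_fracture(
    phantom: Phantom, seed: int, severity: str = "line"
) -> tuple[np.ndarray, np.ndarray]:
    """Darken a thin polyline strictly inside the phantom foreground.

    Severities proxy the clinical spectrum: ``subtle`` (occult-like faint
    fissure), ``line`` (nondisplaced dark line), ``displaced`` (wider,
    stronger gap).  Returns ``(image, mask)`` where the mask marks exactly
    the altered pixels; the image is untouched outside the mask.
    """
    if severity not in SEVERITIES:
        raise ValueError(f"severity must be one of {SEVERITIES}")
    if not phantom.foreground.any():
        raise DegenerateInputError("phantom foreground is empty")
    rng = np.random.default_rng(seed)
    radius = _SEVERITY_RADIUS[severity]
    interior = _berode(phantom.foreground, radius + 2)
    if interior.sum() < 30:
        raise DegenerateInputError("foreground too small to host a fracture line")

    n_interior = int(rng.integers(1, 6))
    pts = _fracture_polyline(rng, interior, n_interior)
    mask = _rasterize_polyline(pts, phantom.foreground.shape, radius)
    mask &= _berode(phantom.foreground, 1)

    drop = _SEVERITY_DROP[severity]
    image = phantom.image.copy()
    image[mask] = np.clip(image[mask] * (1.0 - drop), 0.0, 1.0)
    altered = mask & (image != phantom.image)
    return image, altered


def generate_texture_bank(seed: int, n: int, size: int) -> TextureBank:
    """Alternating bone-overlap-like (band-limited noise) and
    background-like (near-uniform dark) patches, deterministic per seed."""
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    rng = np.random.default_rng(seed)
    patches, tags = [], []
    for i in range(n):
        if i % 2 == 0:
            p = 0.55 + 0.14 * _smooth_noise(rng, size, sigma=2.0)
            tags.append("bone-overlap-like")
        else:
            p = rng.uniform(0.05, 0.18) + rng.normal(0.0, 0.01, (size, size))
            tags.append("background-like")
        patches.append(np.clip(p, 0.0, 1.0).astype(np.float32))
    return TextureBank(patches=patches, tags=tags)


def _to_png(arr: np.ndarray) -> np.ndarray:
    return np.round(np.clip(arr, 0.0, 1.0) * 255.0).astype(np.uint8)


def read_image(path: Path | str) -> np.ndarray:
    """Read an 8-bit grayscale PNG back into float32 [0, 1]."""
    return iio.imread(path).astype(np.float32) / 255.0


def read_mask(path: Path | str) -> np.ndarray:
    return iio.imread(path) > 127


def build_dataset(
    out_dir: Path | str,
    n_train: int,
    n_test_normal: int,
    n_test_fractured: int,
    seed: int,
    size: int = 128,
) -> DatasetManifest:
    """Write a train/test phantom dataset in the standard layout.

    ``root/train/normal``, ``root/test/normal``, ``root/test/fractured``
    PNGs plus ``root/ground_truth/fractured/*_mask.png`` (0 = normal,
    255 = anomalous) and a JSON manifest.  Train images are fracture-free;
    fractured test images cycle through the severity taxonomy.
    """
    root = Path(out_dir)
    for sub in ("train/normal", "test/normal", "test/fractured", "ground_truth/fractured"):
        (root / sub).mkdir(parents=True, exist_ok=True)

    ss = np.random.SeedSequence([int(seed), 0x5CAF])
    base = int(ss.generate_state(1)[0] % (2**31))

    train, test = [], []
    for i in range(n_train):
        ph = generate_phantom(base + i, size=size)
        rel = f"train/normal/{i:04d}.png"
        iio.imwrite(root / rel, _to_png(ph.image))
        train.append(ManifestEntry(path=rel, label=0))
    for i in range(n_test_normal):
        ph = generate_phantom(base + 10_000 + i, size=size)
        rel = f"test/normal/{i:04d}.png"
        iio.imwrite(root / rel, _to_png(ph.image))
        test.append(ManifestEntry(path=rel, label=0))
    for i in range(n_test_fractured):
        ph = generate_phantom(base + 20_000 + i, size=size)
        severity = SEVERITIES[i % len(SEVERITIES)]
        img, mask = inscribe_true_fracture(ph, seed=base + 30_000 + i, severity=severity)
        rel = f"test/fractured/{i:04d}.png"
        mask_rel = f"ground_truth/fractured/{i:04d}_mask.png"
        iio.imwrite(root / rel, _to_png(img))
        iio.imwrite(root / mask_rel, (mask.astype(np.uint8) * 255))
        test.append(ManifestEntry(path=rel, label=1, mask_path=mask_rel))

    manifest = DatasetManifest(root=str(root), train=train, test=test, seed=int(seed))
    manifest.save(root / "manifest.json")
    return manifest
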