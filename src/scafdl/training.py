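"""Joint training of the reconstruction denoiser and the localizer.

Each step: draw a batch of healthy training images, synthesize the
configured normal/pseudofracture mix, sample a time-step triple (one
step per schedule segment), diffuse the batch with a shared per-image
noise draw, predict noise at the three steps, form the guided one-step
reconstruction, run the localizer on (input, reconstruction), and apply
L_total = L_noise + L_mask.  The denoiser is trained by L_noise on
normal samples only; by default the reconstruction fed to the localizer
is detached, so L_mask trains the localizer alone.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .config import RunConfig, make_config
from .diffusion import (
    GuidanceConfig,
    NoiseSchedule,
    build_schedule,
    forward_diffuse,
    reconstruct_batch,
    sample_timestep_triple,
)
from .losses import LossConfig, mask_loss, noise_loss, total_loss
from .nn import (
    Adam,
    DenoiserConfig,
    DenoiserUNet,
    LocalizerConfig,
    SEUNetLocalizer,
    Tensor,
)
from .nn.tensor import concat as t_concat
from .nn.tensor import no_grad, split as t_split
from .phantom import DatasetManifest, read_image
from .synthesis import (
    AugmentationPool,
    SynthesisConfig,
    augment_pair,
    segment_foreground,
    synthesize_batch,
)
from .phantom import generate_texture_bank

__all__ = ["ModelBundle", "TrainResult", "train", "load_bundle"]


@dataclass
class TrainResult:
    bundle: "ModelBundle"
    log: list
    checkpoint_path: str | None


class ModelBundle:
    """Trained denoiser + localizer + schedule, with save/load."""

    def __init__(
        self,
        denoiser: DenoiserUNet,
        localizer: SEUNetLocalizer,
        sched: NoiseSchedule,
        guidance: GuidanceConfig,
        config: dict,
        step: int = 0,
    ):
        self.denoiser = denoiser
        self.localizer = localizer
        self.sched = sched
        self.guidance = guidance
        self.config = config
        self.step = step

    # -- inference ----------------------------------------------------------
    def reconstruct(self, images: np.ndarray, seed: int = 0) -> np.ndarray:
        """ING-reconstruct (n, H, W) images with per-image noise."""
        return reconstruct_batch(
            images, self.denoiser.predict, self.sched, cfg=self.guidance, seed=seed
        )

    def saliency_maps(self, images: np.ndarray, seed: int = 0):
        """Returns (saliency (n,H,W), reconstructions (n,H,W))."""
        images = np.asarray(images, dtype=np.float32)
        recon = self.reconstruct(images, seed=seed)
        pair = np.stack([images, recon], axis=1)  # (n, 2, H, W)
        sal = self.localizer.saliency(pair)[:, 0]
        return sal, recon

    # -- persistence --------------------------------------------------------
    def save(self, path: Path | str) -> None:
        arrays = {f"den.{k}": v for k, v in self.denoiser.state_dict().items()}
        arrays.update({f"loc.{k}": v for k, v in self.localizer.state_dict().items()})
        meta = {
            "config": self.config,
            "step": self.step,
            "schedule": {
                "T": self.sched.T,
                "segments": [list(s) for s in self.sched.segments],
            },
        }
        np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrays)

    @classmethod
    def load(cls, path: Path | str) -> "ModelBundle":
        with np.load(path) as data:
            meta = json.loads(bytes(data["__meta__"]).decode())
            arrays = {k: data[k] for k in data.files if k != "__meta__"}
        cfg = meta["config"]
        rng = np.random.default_rng(0)  # weights overwritten below
        den = DenoiserUNet(DenoiserConfig(**cfg["denoiser"], in_channels=1), rng)
        loc = SEUNetLocalizer(LocalizerConfig(**cfg["localizer"], in_channels=2), rng)
        den.load_state_dict(
            {k[4:]: v for k, v in arrays.items() if k.startswith("den.")}
        )
        loc.load_state_dict(
            {k[4:]: v for k, v in arrays.items() if k.startswith("loc.")}
        )
        sched = build_schedule(
            cfg["diffusion"]["T"],
            beta_bounds=(cfg["diffusion"]["beta_min"], cfg["diffusion"]["beta_max"]),
            segments=cfg["diffusion"]["segments"],
        )
        guidance = _guidance_from(cfg, mode="fixed")
        return cls(den, loc, sched, guidance, cfg, step=int(meta["step"]))


def load_bundle(path: Path | str) -> ModelBundle:
    return ModelBundle.load(path)


def _guidance_from(cfg: dict, mode: str | None = None) -> GuidanceConfig:
    g = cfg["guidance"]
    return GuidanceConfig(
        w1=g["w1"],
        w2=g["w2"],
        mode=mode or g["mode"],
        triple=tuple(g["triple"]),
        reuse_noise=g["reuse_noise"],
    )


def _load_training_set(manifest: DatasetManifest):
    if not manifest.train:
        raise ValueError("train split is empty")
    root = Path(manifest.root)
    normals = []
    for entry in manifest.train:
        if entry.label != 0:
            raise ValueError("train split must contain only normal images")
        img = read_image(root / entry.path)
        fg = segment_foreground(img, method="threshold")
        normals.append((img, fg))
    return normals


def _guided_reconstruction(x, eps, eps_hats, triple, sched, guidance):
    """Tensor-valued ING algebra shared by training and the detach test.

    `eps_hats` are the denoiser outputs at (t_s, t_m, t_l) as Tensors
    (constant Tensors when detached).  Returns the clipped reconstruction.
    """
    t_s, t_m, t_l = triple.as_tuple()
    ab = sched.alpha_bar
    sa = {t: np.float32(np.sqrt(ab[t])) for t in (t_s, t_m, t_l)}
    sb = {t: np.float32(np.sqrt(1.0 - ab[t])) for t in (t_s, t_m, t_l)}
    x_ts = forward_diffuse(x, t_s, eps, sched)
    x_tm = forward_diffuse(x, t_m, eps, sched)
    x_tl = forward_diffuse(x, t_l, eps, sched)
    eh_s, eh_m, eh_l = eps_hats

    xhat0_m = (Tensor(x_tm) - eh_m * sb[t_m]) * np.float32(1.0 / sa[t_m])
    xhat0_l = (Tensor(x_tl) - eh_l * sb[t_l]) * np.float32(1.0 / sa[t_l])
    # renoise to t_s reusing the forward noise draw
    x_ts_m = xhat0_m * sa[t_s] + Tensor(eps) * sb[t_s]
    x_ts_l = xhat0_l * sa[t_s] + Tensor(eps) * sb[t_s]
    delta = (x_ts_m - Tensor(x_ts)) * np.float32(guidance.w1) + (
        x_ts_l - Tensor(x_ts)
    ) * np.float32(guidance.w2)
    eps_g = eh_s - delta * sb[t_s]
    x0_raw = (Tensor(x_ts) - eps_g * sb[t_s]) * np.float32(1.0 / sa[t_s])
    return x0_raw.clamp(0.0, 1.0)


def train_step(
    normals: list,
    bank,
    denoiser: DenoiserUNet,
    localizer: SEUNetLocalizer,
    optimizer: Adam,
    sched: NoiseSchedule,
    cfg: RunConfig,
    loss_cfg: LossConfig,
    step: int,
    rng: np.random.Generator,
    pool: AugmentationPool | None = None,
) -> dict:
    """One optimization step; returns the logged record."""
    tr = cfg["train"]
    syn = cfg["synthesis"]
    batch_n = min(tr["batch"], len(normals))
    idx = rng.choice(len(normals), size=batch_n, replace=len(normals) < batch_n)
    chosen = [normals[i] for i in idx]
    samples = synthesize_batch(
        chosen,
        bank,
        SynthesisConfig(
            ratio=syn["ratio"],
            beta_range=tuple(syn["beta_range"]),
            thickness=syn["thickness"],
        ),
        seed=int(rng.integers(0, 2**31)),
    )
    if tr.get("augment") and pool is not None:
        samples = [
            _augmented(s, pool, int(rng.integers(0, 2**31))) for s in samples
        ]
    # normals first so the taped denoiser pass covers a contiguous block
    samples.sort(key=lambda s: s.y)
    x = np.stack([s.S for s in samples])[:, None].astype(np.float32)
    m = np.stack([s.M for s in samples])[:, None].astype(np.float32)
    y = np.array([s.y for s in samples], dtype=np.float32)
    n_norm = int((y == 0).sum())
    b = x.shape[0]

    guidance = _guidance_from(cfg.raw)
    triple = sample_timestep_triple(sched, guidance, seed=int(rng.integers(0, 2**31)))
    eps = rng.standard_normal(x.shape).astype(np.float32)
    detach = loss_cfg.detach_reconstruction

    ts = triple.as_tuple()
    x_noisy = np.concatenate([forward_diffuse(x, t, eps, sched) for t in ts])
    t_vec = np.repeat(ts, b)

    if detach:
        taped_rows = np.concatenate([np.arange(n_norm) + k * b for k in range(3)])
        eh_taped = denoiser(Tensor(x_noisy[taped_rows]), t_vec[taped_rows])
        with no_grad():
            other = np.setdiff1d(np.arange(3 * b), taped_rows)
            eh_rest = denoiser.forward(Tensor(x_noisy[other]), t_vec[other]).data
        eh_norm = t_split(eh_taped, 3)  # per-timestep taped blocks (normals)
        eh_full = np.empty((3 * b, 1) + x.shape[2:], dtype=np.float32)
        for k in range(3):
            eh_full[k * b : k * b + n_norm] = eh_norm[k].data
        eh_rest_blocks = eh_rest.reshape(3, b - n_norm, *eh_rest.shape[1:])
        for k in range(3):
            eh_full[k * b + n_norm : (k + 1) * b] = eh_rest_blocks[k]
        eps_hats_noise = [
            t_concat([eh_norm[k], Tensor(eh_full[k * b + n_norm : (k + 1) * b])], axis=0)
            for k in range(3)
        ]
        eps_hats_recon = [Tensor(eh_full[k * b : (k + 1) * b]) for k in range(3)]
    else:
        eh_all = denoiser(Tensor(x_noisy), t_vec)
        eps_hats_noise = t_split(eh_all, 3)
        eps_hats_recon = eps_hats_noise

    l_noise = noise_loss([eps] * 3, eps_hats_noise, y)
    x0_guide = _guided_reconstruction(x, eps, eps_hats_recon, triple, sched, guidance)
    loc_in = t_concat([Tensor(x), x0_guide], axis=1)
    saliency = localizer(loc_in).sigmoid()
    l_mask = mask_loss(m, saliency, loss_cfg, step=step)
    l_total = total_loss(l_noise, l_mask)

    optimizer.zero_grad()
    l_total.backward()
    optimizer.step()
    return {
        "step": step,
        "loss_total": float(l_total),
        "loss_noise": float(l_noise),
        "loss_mask": float(l_mask),
        "triple": list(ts),
        "n_pseudo": int(b - n_norm),
    }


def _augmented(sample, pool: AugmentationPool, seed: int):
    from .synthesis import PseudoSample

    S2, M2 = augment_pair(sample.S, sample.M, pool, seed)
    y2 = int(M2.any())
    return PseudoSample(S=S2, M=M2, y=y2, source_id=sample.source_id)


def train(
    manifest: DatasetManifest,
    cfg: RunConfig | None = None,
    seed: int | None = None,
    out_dir: Path | str | None = None,
    steps: int | None = None,
    resume_from: Path | str | None = None,
) -> TrainResult:
    """Run the joint training loop; reproducible given the seed.

    Writes ``checkpoint.npz``, ``config.json`` and a JSON-lines training
    log under ``out_dir`` when given.
    """
    cfg = cfg or make_config("desk")
    seed = cfg.seed if seed is None else int(seed)
    n_steps = int(steps if steps is not None else cfg["train"]["steps"])

    normals = _load_training_set(manifest)
    size = normals[0][0].shape[0]
    bank = generate_texture_bank(
        int(np.random.SeedSequence([seed, 0xBA2]).generate_state(1)[0] % (2**31)),
        n=cfg["synthesis"]["bank_size"],
        size=size,
    )
    sched = build_schedule(
        cfg["diffusion"]["T"],
        beta_bounds=(cfg["diffusion"]["beta_min"], cfg["diffusion"]["beta_max"]),
        segments=cfg["diffusion"]["segments"],
    )
    init_rng = np.random.default_rng(np.random.SeedSequence([seed, 1]))
    den = DenoiserUNet(DenoiserConfig(**cfg["denoiser"], in_channels=1), init_rng)
    loc = SEUNetLocalizer(LocalizerConfig(**cfg["localizer"], in_channels=2), init_rng)
    opt = Adam(den.parameters() + loc.parameters(), lr=cfg["train"]["lr"])
    start_step = 0
    if resume_from is not None:
        prev = ModelBundle.load(resume_from)
        den.load_state_dict(prev.denoiser.state_dict())
        loc.load_state_dict(prev.localizer.state_dict())
        start_step = prev.step

    loss_cfg = LossConfig(
        alpha=cfg["loss"]["alpha"],
        gamma_focal_start=cfg["loss"]["gamma_focal_start"],
        gamma_focal_end=cfg["loss"]["gamma_focal_end"],
        ramp_steps=max(start_step + n_steps, 2),
        gamma_mask=cfg["loss"]["gamma_mask"],
        detach_reconstruction=cfg["loss"]["detach_reconstruction"],
    )
    pool = AugmentationPool() if cfg["train"].get("augment") else None

    log: list[dict] = []
    out_path = None
    log_fh = None
    if out_dir is not None:
        out_path = Path(out_dir)
        out_path.mkdir(parents=True, exist_ok=True)
        cfg.save(out_path / "config.json")
        log_fh = open(out_path / "train_log.jsonl", "a")

    rng = np.random.default_rng(np.random.SeedSequence([seed, 2, start_step]))
    t0 = time.time()
    for k in range(n_steps):
        step = start_step + k
        rec = train_step(
            normals, bank, den, loc, opt, sched, cfg, loss_cfg, step, rng, pool
        )
        rec["elapsed_s"] = round(time.time() - t0, 2)
        log.append(rec)
        if log_fh and (step % cfg["train"]["log_every"] == 0 or k == n_steps - 1):
            log_fh.write(json.dumps(rec) + "\n")
            log_fh.flush()
    if log_fh:
        log_fh.close()

    bundle = ModelBundle(
        den, loc, sched, _guidance_from(cfg.raw, mode="fixed"), cfg.to_dict(),
        step=start_step + n_steps,
    )
    ckpt = None
    if out_path is not None:
        ckpt = str(out_path / "checkpoint.npz")
        bundle.save(ckpt)
    return TrainResult(bundle=bundle, log=log, checkpoint_path=ckpt)
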