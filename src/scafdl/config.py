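"""Run configuration: profiles, YAML loading, overrides.

Two built-in profiles share one code path:

* ``desk`` — 32x32 phantoms, a 200-step schedule with segments
  (0,60]/(60,100]/(100,140], narrow networks.  Everything runs on a
  single CPU in minutes; this is the profile the tests and the
  acceptance run use.
* ``paper`` — 128x128 images, 1000-step schedule with the reference
  300/500/700 time-step triple, transformer depth 12, lr 1e-5,
  1500 epochs, batch 16.  Kept as configuration; not exercised by the
  test suite.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = ["RunConfig", "PROFILES", "load_config", "make_config"]


_DESK = {
    "profile": "desk",
    "seed": 0,
    "data": {
        "dir": "data",
        "n_train": 60,
        "n_test_normal": 20,
        "n_test_fractured": 20,
        "size": 32,
    },
    "synthesis": {
        "beta_range": [0.5, 1.0],
        "thickness": 1,
        "ratio": 0.5,
        "bank_size": 8,
    },
    "diffusion": {"T": 200, "beta_min": 1e-4, "beta_max": 0.02,
                  "segments": [[0, 60], [60, 100], [100, 140]]},
    "guidance": {"w1": 0.5, "w2": 0.5, "triple": [60, 100, 140],
                 "mode": "random", "reuse_noise": True},
    "denoiser": {"base_width": 8, "transformer_depth": 2, "heads": 4},
    "localizer": {"base_width": 16, "stages": 3, "se_reduction": 16},
    "loss": {"alpha": 0.75, "gamma_focal_start": 2.0, "gamma_focal_end": 3.5,
             "gamma_mask": 1.0, "detach_reconstruction": True},
    "train": {"batch": 8, "lr": 1e-3, "steps": 1000, "augment": True,
              "log_every": 25},
}

_PAPER = copy.deepcopy(_DESK)
_PAPER.update({"profile": "paper"})
_PAPER["data"].update({"n_train": 120, "n_test_normal": 40,
                       "n_test_fractured": 80, "size": 128})
_PAPER["diffusion"].update({"T": 1000,
                            "segments": [[0, 300], [300, 500], [500, 700]]})
_PAPER["guidance"].update({"triple": [300, 500, 700]})
_PAPER["denoiser"].update({"base_width": 64, "transformer_depth": 12, "heads": 8})
_PAPER["localizer"].update({"base_width": 32, "stages": 4})
# batch 16 of ~8 normal + ~8 pseudofracture samples; Adam at 1e-5 for 1500 epochs
_PAPER["train"].update({"batch": 16, "lr": 1e-5, "steps": 11250, "epochs": 1500})

PROFILES = {"desk": _DESK, "paper": _PAPER}


@dataclass
class RunConfig:
    raw: dict = field(default_factory=lambda: copy.deepcopy(_DESK))

    def __getitem__(self, key):
        return self.raw[key]

    @property
    def profile(self) -> str:
        return self.raw["profile"]

    @property
    def seed(self) -> int:
        return int(self.raw["seed"])

    def to_dict(self) -> dict:
        return copy.deepcopy(self.raw)

    def save(self, path: Path | str) -> None:
        Path(path).write_text(json.dumps(self.raw, indent=1))


def _merge(base: dict, override: dict, path: str = "") -> dict:
    out = copy.deepcopy(base)
    for key, value in override.items():
        here = f"{path}.{key}" if path else key
        if key not in base:
            raise KeyError(f"unknown config key: {here}")
        if isinstance(base[key], dict):
            if not isinstance(value, dict):
                raise ValueError(f"{here} must be a mapping")
            out[key] = _merge(base[key], value, here)
        else:
            out[key] = value
    return out


def make_config(profile: str = "desk", overrides: dict | None = None) -> RunConfig:
    if profile not in PROFILES:
        raise ValueError(f"unknown profile {profile!r}; choose from {sorted(PROFILES)}")
    raw = copy.deepcopy(PROFILES[profile])
    if overrides:
        raw = _merge(raw, overrides)
    return RunConfig(raw=raw)


def load_config(path: Path | str | None = None, profile: str | None = None,
                overrides: dict | None = None) -> RunConfig:
    """Merge (profile defaults) <- (YAML file) <- (explicit overrides);
    unknown keys are rejected."""
    file_cfg: dict = {}
    if path is not None:
        file_cfg = yaml.safe_load(Path(path).read_text()) or {}
    prof = profile or file_cfg.get("profile") or "desk"
    cfg = make_config(prof)
    raw = _merge(cfg.raw, file_cfg)
    if overrides:
        raw = _merge(raw, overrides)
    return RunConfig(raw=raw)
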