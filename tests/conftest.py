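import numpy as np
import pytest

from scafdl.config import make_config
from scafdl.phantom import build_dataset, generate_phantom, generate_texture_bank

# Desk-scale study conditions: 32x32 phantoms, 60 healthy training images,
# 20 normal + 20 fractured held-out test images.
DESK_SEED = 11
TRAIN_STEPS = 1000
TRAIN_SEEDS = (1, 2, 3)


@pytest.fixture(scope="session")
def desk_dataset(tmp_path_factory):
    root = tmp_path_factory.mktemp("desk_data")
    return build_dataset(root, 60, 20, 20, seed=DESK_SEED, size=32)


@pytest.fixture(scope="session")
def trained_results(desk_dataset, tmp_path_factory):
    """Desk-profile training runs for three seeds (shared across tests:
    the scaled-down learning check, the ablation harness and the smoke
    assertions all reuse these)."""
    from scafdl.training import train

    out_root = tmp_path_factory.mktemp("runs")
    cfg = make_config("desk")
    results = []
    for seed in TRAIN_SEEDS:
        results.append(
            train(desk_dataset, cfg, seed=seed, out_dir=out_root / f"s{seed}",
                  steps=TRAIN_STEPS)
        )
    return results


@pytest.fixture(scope="session")
def phantoms32():
    return [generate_phantom(s, size=32) for s in range(20)]


@pytest.fixture(scope="session")
def phantom64():
    return generate_phantom(5, size=64)


@pytest.fixture(scope="session")
def bank32():
    return generate_texture_bank(3, n=8, size=32)


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
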