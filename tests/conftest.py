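import numpy as np
import pytest

from graylift import (
    GrayImage,
    ModelBundle,
    NetworkConfig,
    SyntheticSpec,
    TrainingConfig,
    generate,
    train,
)

#: small architecture used throughout the suite; the full-scale default
#: (base 64, four scales) is exercised only for shape contracts.
TINY_NET = NetworkConfig(base_channels=8, n_scales=2)

SMOKE_TRAINING = dict(
    batch_size=8,
    epochs=20,
    lr_initial=5e-3,
    lr_halving_period=10,
    patch_size=16,
    patches_per_epoch=40,
    seed=7,
    network=TINY_NET,
)


def smooth_images(n_per_kind: int = 12, size: int = 48) -> list[np.ndarray]:
    """Low-entropy training pool: constants, ramps, soft blobs."""
    pool = []
    for i in range(n_per_kind):
        pool.append(generate(SyntheticSpec("constant", size, size, seed=i)).values)
        pool.append(generate(SyntheticSpec("gradient", size, size, seed=100 + i)).values)
        pool.append(
            generate(SyntheticSpec("gaussian-blobs", size, size, seed=200 + i)).values
        )
    return pool


@pytest.fixture(scope="session")
def untrained_bundle() -> ModelBundle:
    return ModelBundle.create(TINY_NET, seed=3)


@pytest.fixture(scope="session")
def smooth_pool() -> list[np.ndarray]:
    return smooth_images()


@pytest.fixture(scope="session")
def smoke_bundle(smooth_pool) -> ModelBundle:
    """Bundle trained for ~100 Adam steps per network on smooth images."""
    return train(smooth_pool, TrainingConfig(**SMOKE_TRAINING))


def random_image(rng: np.random.Generator, lo: int = 1, hi: int = 65) -> GrayImage:
    h = int(rng.integers(lo, hi))
    w = int(rng.integers(lo, hi))
    return GrayImage(rng.integers(0, 256, (h, w)).astype(np.uint8))
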