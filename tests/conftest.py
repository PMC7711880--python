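import numpy as np
import pytest

from sbocad import cnn, preprocessing as pre, synth


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_dataset():
    """16 synthetic images at default difficulty, shared across modules."""
    return synth.generate_dataset(16, seed=7)


@pytest.fixture(scope="session")
def small_grays(small_dataset):
    return [pre.median_filter(pre.to_grayscale(im), 3)
            for im in small_dataset.images]


@pytest.fixture(scope="session")
def trained_segmenter(small_dataset, small_grays):
    """Patch classifier trained on 12 of the 16 shared images."""
    rng = np.random.default_rng(7)
    x, d = cnn.sample_patches(small_grays[:12], small_dataset.masks[:12],
                              16, 40, rng)
    net = cnn.patch_architecture(patch_size=16, channels=1, seed=7)
    cfg = cnn.TrainConfig(learning_rate=0.1, iterations=300, theta=1e-4,
                          dropout_active=False, seed=7)
    cnn.gd_train(net, x, d, cfg)
    return net


@pytest.fixture(scope="session")
def disk_mask():
    """Rasterized disk of radius 40, centered for exact symmetry."""
    side = 101
    r, c = np.mgrid[0:side, 0:side]
    return (r - 50) ** 2 + (c - 50) ** 2 <= 40.5 ** 2
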