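import numpy as np
import pytest

import hdestack as h


@pytest.fixture(scope="session")
def tiny_cfg():
    """Small, fast study design: 3 classes, coarse 25 nm grid."""
    return h.SynthConfig(
        n_classes=3,
        n_per_class=20,
        wavelength_step=25.0,
        seed=7,
        class_shift_sd=0.01,
        noise_sd=0.008,
        morph_effect_size=1.0,
    )


@pytest.fixture(scope="session")
def tiny_dataset(tiny_cfg):
    return h.make_dataset(tiny_cfg)


@pytest.fixture(scope="session")
def tiny_fused(tiny_dataset):
    """Normalized fused train/test tables for the tiny design."""
    morph, spectra, labels = tiny_dataset
    spec = h.sg_smooth(spectra, 11, 2).to_feature_table(labels)
    fused = h.fuse(morph, spec)
    train, test = h.split(fused, 0.7, seed=0)
    train_n, ranges = h.minmax_normalize(train)
    test_n, _ = h.minmax_normalize(test, ranges=ranges)
    return train_n, test_n


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def informative_band_matrix():
    """150 x 200 matrix, 3 classes, informative bands at 40/100/160."""
    def make(seed):
        gen = np.random.default_rng(seed)
        y = np.repeat(np.arange(3), 50)
        x = gen.normal(0.0, 1.0, (150, 200))
        for k, band in enumerate((40, 100, 160)):
            x[:, band] += 2.0 * (y == k)
        return x, y, (40, 100, 160)

    return make
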