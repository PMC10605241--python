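import numpy as np
import pytest

from histotex import (
    CohortConfig,
    TextureFeatureExtractor,
    default_separable_presets,
    generate_cohort,
    hard_presets,
)


def _cohort_features(presets, seed, n_per_class, size):
    cfg = CohortConfig(
        n_per_class=n_per_class,
        image_size=(size, size),
        params_normal=presets[0],
        params_gbm=presets[1],
        seed=seed,
    )
    images, _ = generate_cohort(cfg)
    return TextureFeatureExtractor().transform(images)


@pytest.fixture(scope="session")
def separable_features():
    """Feature table of the default separable cohort: 200/class at 256x256."""
    return _cohort_features(default_separable_presets(), seed=7, n_per_class=200, size=256)


@pytest.fixture(scope="session")
def hard_features():
    """Feature table of the overlapping 'hard' cohort: 200/class at 256x256."""
    return _cohort_features(hard_presets(), seed=11, n_per_class=200, size=256)


@pytest.fixture(scope="session")
def small_separable_features():
    """A quick 12/class cohort at 128x128 for unit-level checks."""
    return _cohort_features(default_separable_presets(), seed=3, n_per_class=12, size=128)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
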