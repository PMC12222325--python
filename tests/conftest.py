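import numpy as np
import pytest

from pestfsod import SceneSpec, generate_dataset, split_train_test
from pestfsod.episodes import make_split


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_spec():
    """A 6-class separable scene spec used across pipeline tests."""
    return SceneSpec(
        image_size=(96, 96), n_classes=6, size_range_px=(12, 36),
        objects_per_image=(1, 3), overlap_max_iou=0.2,
    )


@pytest.fixture
def tiny_dataset(small_spec):
    """In-memory 6-class dataset with an 80/20 split and a 4/2 class split."""
    rng = np.random.default_rng(7)
    manifest = generate_dataset(small_spec, {c: 8 for c in range(6)}, None, rng)
    train, test = split_train_test(manifest, 0.8, rng)
    split = make_split(list(range(6)), 4, 0)
    return train, test, split
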