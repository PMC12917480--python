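import numpy as np
import pytest

from rankmil.bags import Bag
from rankmil.synthetic import SyntheticSpec, generate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_bag(rng, k=None, d=4, label=None, with_coords=False):
    """A random valid bag for round-trip / fuzz tests."""
    k = int(rng.integers(1, 40)) if k is None else k
    label = int(rng.integers(0, 2)) if label is None else label
    y = np.zeros(k, dtype=np.int8)
    if label == 1 and k > 1:
        y[rng.choice(k, size=int(rng.integers(1, k)), replace=False)] = 1
    elif label == 1:
        y[0] = 1
    coords = None
    if with_coords:
        side = int(np.ceil(np.sqrt(k)))
        coords = np.stack(np.divmod(np.arange(k), side), axis=1)
    return Bag(
        slide_id=f"slide_{rng.integers(1e9)}",
        features=rng.normal(size=(k, d)).astype(np.float32),
        slide_label=label,
        patch_labels=y,
        patch_coords=coords,
        annotated=True,
    )


@pytest.fixture(scope="session")
def tiny_dataset():
    """A small, quickly learnable synthetic dataset for trainer unit tests."""
    spec = SyntheticSpec(
        n_train_per_class=6, n_val_per_class=3, n_test_per_class=5,
        bag_size_range=(30, 60), feature_dim=8, separation=3.0, seed=7,
    )
    return generate_dataset(spec)
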