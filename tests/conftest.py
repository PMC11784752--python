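import numpy as np
import pytest

from rkcnn.dataset import Dataset


@pytest.fixture
def two_class_points():
    """Classes A={(0,0),(0,1)}, B={(3,0),(4,0)}: the worked kCNN example."""
    return Dataset(
        np.array([[0.0, 0.0], [0.0, 1.0], [3.0, 0.0], [4.0, 0.0]]),
        np.array(["A", "A", "B", "B"]),
    )


@pytest.fixture
def square_corners():
    """Classes {(0,0),(0,2)} and {(4,0),(4,2)}: the worked separation example."""
    return Dataset(
        np.array([[0.0, 0.0], [0.0, 2.0], [4.0, 0.0], [4.0, 2.0]]),
        np.array(["A", "A", "B", "B"]),
    )


def random_dataset(rng, n_classes=None, n=None, q=None):
    """A random labeled dataset with every class holding >= 2 members."""
    if n_classes is None:
        n_classes = rng.integers(2, 5)
    if q is None:
        q = int(rng.integers(2, 41))
    if n is None:
        n = int(rng.integers(max(6, 2 * n_classes), 61))
    # at least 2 per class, remainder at random
    codes = np.concatenate(
        [np.repeat(np.arange(n_classes), 2),
         rng.integers(0, n_classes, n - 2 * n_classes)]
    )
    X = rng.normal(size=(n, q)) + codes[:, None] * rng.normal(size=q)
    labels = np.array([f"c{c}" for c in codes])
    return Dataset(X, labels)


@pytest.fixture
def separable_clouds():
    """Two far-apart Gaussian blobs: any sane classifier is perfect."""
    rng = np.random.default_rng(7)
    n = 10
    a = rng.normal(loc=-10.0, size=(n, 3))
    b = rng.normal(loc=10.0, size=(n, 3))
    return Dataset(
        np.vstack([a, b]), np.array(["neg"] * n + ["pos"] * n)
    )
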