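import numpy as np
import pytest

from bsda.synthetic import make_blob_images, make_sparse_features


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_blobs():
    """Small, fast image dataset shared across harness/CLI tests."""
    return make_blob_images(n=200, classes=3, size=16, noise=0.05, seed=7)


@pytest.fixture(scope="session")
def sparse_dataset():
    return make_sparse_features(n=2000, k=64, classes=3, zero_frac=0.5,
                                sep=4.0, seed=11)
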