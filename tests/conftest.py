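import numpy as np
import pytest

from msunet.synthetic import SyntheticStyle, make_splits, synthesize_dataset


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def blob_dataset():
    """A small shared blobs dataset with its split plan (n=30, 64 px)."""
    ds = synthesize_dataset(SyntheticStyle("blobs", image_size=64), 30, seed=3)
    return ds, make_splits(30, seed=3)


def numeric_gradient(fn, x: np.ndarray, eps: float = 1e-5) -> np.ndarray:
    """Central finite differences of a scalar-valued fn with respect to x."""
    g = np.zeros_like(x)
    it = np.nditer(x, flags=["multi_index"])
    for _ in it:
        i = it.multi_index
        orig = x[i]
        x[i] = orig + eps
        f1 = fn()
        x[i] = orig - eps
        f2 = fn()
        x[i] = orig
        g[i] = (f1 - f2) / (2 * eps)
    return g
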