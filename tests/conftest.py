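import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20240109)


@pytest.fixture
def mask_pair(rng):
    """One random 8x8 (pred, gt) pair with pred in the open unit interval."""
    pred = rng.uniform(0.02, 0.98, (8, 8))
    gt = (rng.random((8, 8)) < 0.3).astype(float)
    return pred, gt


@pytest.fixture
def small_dataset():
    """A tiny deterministic phantom dataset shared by harness tests."""
    from aspseg.synthetic import PhantomSpec, generate_dataset
    return generate_dataset(PhantomSpec(image_size=(32, 32), seed=99), 24)
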