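import numpy as np
import pytest

from camstitch.backbone import TinyCNN
from camstitch.synth import SyntheticSpec, generate_labeled_mosaic


@pytest.fixture(scope="session")
def small_spec() -> SyntheticSpec:
    """A quick-to-generate annotated-mosaic recipe with separable textures."""
    return SyntheticSpec(mosaic_shape=(192, 192), n_mosaics=4, blob_sigma=24.0).easy()


@pytest.fixture(scope="session")
def annotated_pair(small_spec):
    return generate_labeled_mosaic(small_spec, seed=7)


@pytest.fixture(scope="session")
def tiny_model() -> TinyCNN:
    """An untrained reference backbone for 16x16 inputs (K = 8 channels)."""
    return TinyCNN(in_size=16, channels=(4, 4, 8), seed=2)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(0)
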