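import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_image(rng):
    """Smooth 16x16 grayscale image in [0.1, 0.9]."""
    from spikedenoise.data_synth import make_synthetic_images

    return make_synthetic_images("blobs", 16, 1, seed=7)[0]
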