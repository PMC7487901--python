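import numpy as np
import pytest

from rhoquant.img_io import Raster


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def random_int_raster(rng):
    return Raster(
        rng.integers(0, 65535, size=(32, 32)).astype(np.float64),
        pixel_size_um=0.5,
        bit_depth=16,
    )
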