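import numpy as np
import pytest

from stegowave import Image8, PhantomSpec, generate_phantom


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def ellipse128():
    return generate_phantom(PhantomSpec(128, 128, "ellipse", noise_sd=5.0, seed=7))


def random_image(rng, rows, cols, rgb=False) -> Image8:
    shape = (rows, cols, 3) if rgb else (rows, cols)
    return Image8(rng.integers(0, 256, size=shape, dtype=np.uint8))
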