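import numpy as np
import pytest

from cfcanopy.synthetic_data import SceneSpec, make_canopy_image


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def scene():
    """One noiseless synthetic scene with ground truth, shared per session."""
    spec = SceneSpec(day=10, seed=3)
    img, canopy, pot = make_canopy_image(spec)
    return img, canopy, pot
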