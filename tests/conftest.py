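import numpy as np
import pytest

from fadseed.synthetic_data import ImageGenParams, generate_seed_image


@pytest.fixture(scope="session")
def default_image():
    """One rendered seed photograph with its truth masks (30% cover)."""
    params = ImageGenParams(target_cover=0.30, seed=42)
    img, truth = generate_seed_image(params)
    return params, img, truth


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)
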