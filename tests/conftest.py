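import numpy as np
import pytest

from synthrad.phantom import default_tissue_model, generate_phantom_pair
from synthrad.prep import quantize


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def phantom64():
    """One deterministic 64x64 noisy phantom pair."""
    return generate_phantom_pair(64, default_tissue_model(noise_sigma=0.02, seed=5))


def random_quantized(rng, size=16, n_bins=4, mask_frac=0.8):
    """Small random quantized image with a random (non-empty) mask."""
    img = rng.uniform(0, 1, (size, size))
    mask = rng.random((size, size)) < mask_frac
    if not mask.any():
        mask[size // 2, size // 2] = True
    return quantize(img, mask, n_bins=n_bins)
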