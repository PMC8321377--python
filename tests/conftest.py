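import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20240611)


@pytest.fixture
def random_masks(rng):
    """A batch of small random boolean masks with varied densities."""
    def _make(n=20, shape=(16, 16)):
        return [rng.random(shape) < density
                for density in np.linspace(0.1, 0.9, n)]
    return _make


@pytest.fixture
def two_mode_spm(rng):
    """Bimodal SPM: low background plus one high rectangle, mild noise."""
    spm = np.full((32, 32), 20.0)
    spm[8:24, 8:24] = 220.0
    spm += rng.normal(0, 4, (32, 32))
    return np.clip(np.round(spm), 0, 255).astype(np.uint8)
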