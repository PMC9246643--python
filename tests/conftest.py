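import numpy as np
import pytest

import ilrdd


@pytest.fixture(scope="session")
def phantom64():
    """A 64x64 clean phantom shared across tests (read-only)."""
    return ilrdd.generate_phantom(64, 64, 4, 1.0, seed=7)


@pytest.fixture(scope="session")
def noisy64(phantom64):
    return ilrdd.add_rician_noise(phantom64, ilrdd.NoiseSpec(3.0, seed=7))


@pytest.fixture(scope="session")
def prior64(phantom64):
    """K=8 patch prior trained on the clean 64x64 phantom."""
    pm = ilrdd.extract_patches(phantom64, 8, 4)
    return ilrdd.fit_gmm_em(pm, 8, seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
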