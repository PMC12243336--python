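import numpy as np
import pytest

import chemocal as cc


@pytest.fixture(scope="session")
def noise_free_bundle():
    """25-mixture design + 13 LHS / 13 MC validation points, zero noise."""
    return cc.make_study(seed=7, noise=cc.NoiseSpec(0.0, 0.0, 0.0, False, 0))


@pytest.fixture(scope="session")
def noisy_bundle():
    """Same layout at default bench-UV noise levels."""
    return cc.make_study(seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
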