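import numpy as np
import pytest

import blastcurve as bc


@pytest.fixture(scope="session")
def tiny_spec():
    """Three-stage variant of the architecture for 34-px test images."""
    return bc.build_network(34, 34, 3, 2, n_stages=3)


@pytest.fixture(scope="session")
def tiny_model(tiny_spec):
    return bc.init_model(tiny_spec, seed=11)


@pytest.fixture(scope="session")
def small_two_class():
    """Small 34-px two-class synthetic set for structural protocol tests."""
    cfg = bc.SyntheticConfig(image_size=34, n_per_class=21, seed=7)
    return bc.generate_dataset(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
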