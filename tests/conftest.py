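import numpy as np
import pytest

from echoseg.model import BackboneConfig, build_model


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_model():
    """A small, fixed-seed network shared by read-only tests."""
    return build_model(BackboneConfig.tiny(), seed=0)


def random_prob_map(rng, k=4, h=4, w=4):
    """Random per-pixel categorical distributions, shape (k, h, w)."""
    p = rng.dirichlet(np.ones(k), size=(h, w))
    return np.ascontiguousarray(p.transpose(2, 0, 1))
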