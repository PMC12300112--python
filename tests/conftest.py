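import numpy as np
import pytest

from metanet import CommunityConfig, MetaState, sample_community


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_config():
    """A 2-plant, 2-animal, 2-network community, fully connected."""
    return CommunityConfig(M=2, N=2, n=2, connectance=1.0, seed=7)


@pytest.fixture
def small_community(small_config):
    return sample_community(small_config)


@pytest.fixture
def small_state(small_community, rng):
    return MetaState.random_uniform(
        small_community.M, small_community.N, small_community.n, rng
    )


def make_community(M=3, N=2, n=2, seed=0, **kw):
    cfg = CommunityConfig(M=M, N=N, n=n, connectance=kw.pop("connectance", 1.0),
                          seed=seed, **kw)
    return sample_community(cfg)
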