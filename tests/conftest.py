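import numpy as np
import pytest

from erosdecode import ModelConfig, Network, SimConfig, make_montage_spec


@pytest.fixture
def tiny_mcfg():
    """Small architecture for gradient checks and fast fits."""
    return ModelConfig(C=5, T=24, F1=2, D=2, F2=3,
                       temporal_kernel=6, separable_kernel=5, pool=4,
                       dropout_p=0.0)


@pytest.fixture
def tiny_net(tiny_mcfg):
    return Network(tiny_mcfg, seed=1)


@pytest.fixture
def full_montage():
    """A fully viable montage (no dropout, 4 channels everywhere)."""
    cfg = SimConfig(voxel_dropout_range=(0.0, 0.0), channels_per_voxel_range=(4, 4))
    return cfg, make_montage_spec(cfg, "A")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
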