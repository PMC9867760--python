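import numpy as np
import pytest

from psnet.config import PSNetConfig, SynthConfig
from psnet.model import PSNet
from psnet.train import init_weights


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_cfg():
    return PSNetConfig.tiny()


@pytest.fixture(scope="session")
def tiny_model(tiny_cfg):
    """One shared initialized tiny model for read-only forward-pass tests."""
    model = PSNet(tiny_cfg)
    init_weights(model, seed=0)
    return model


@pytest.fixture(scope="session")
def synth_dir(tmp_path_factory):
    """16 synthetic 64x64 frames with masks (the fixture preset)."""
    from psnet.synthetic import generate
    out = tmp_path_factory.mktemp("synth")
    manifest = generate(SynthConfig(n_images=16, image_size=64, seed=123), out)
    return out, manifest
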