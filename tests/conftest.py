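import numpy as np
import pytest

from wavedet.detector import ModelConfig, WaveletDetector
from wavedet.wavelet import WTPConfig


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def tiny_config():
    """Desk-scale model: 2 encoder / 2 decoder layers, hidden 64, K=20."""
    return ModelConfig(
        num_classes=2, hidden_dim=64, heads=8, encoder_layers=2,
        decoder_layers=2, num_queries=20, ffn_hidden_dim=128,
        backbone_channels=(16, 32, 64, 128), deformable_points=2,
        wtp=WTPConfig(levels=1))


@pytest.fixture(scope="session")
def tiny_model(tiny_config):
    return WaveletDetector(tiny_config, seed=0)
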