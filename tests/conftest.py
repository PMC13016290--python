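import numpy as np
import pytest

from egunet.backbone import BackboneConfig
from egunet.model import ModelConfig, SegmentationNet


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def tiny_config():
    """Smallest architecture that exercises every block (32x32-capable)."""
    return ModelConfig(
        backbone=BackboneConfig(stage_channels=(4, 8, 8, 16)),
        num_classes=3,
        decoder_channels=(8, 8, 4, 4),
        gn_groups=4,
    )


@pytest.fixture
def tiny_model(tiny_config):
    return SegmentationNet(tiny_config, seed=7)
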