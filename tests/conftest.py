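import numpy as np
import pytest

from promptad.encoders import EncoderSpec, toy_image_encoder, toy_text_encoder
from promptad.phantom import PhantomConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_spec():
    """Two-level hierarchy at a desk-test dimension."""
    return EncoderSpec(feature_dim=32, levels=(12, 24), patch_sizes=(16, 8))


@pytest.fixture
def small_image_encoder(small_spec):
    return toy_image_encoder(3, small_spec)


@pytest.fixture
def text_encoder():
    return toy_text_encoder(3, 32)


@pytest.fixture
def phantom_cfg():
    return PhantomConfig()
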