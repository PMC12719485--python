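import numpy as np
import pytest

from ulcerstage.data_io import LabeledImage
from ulcerstage.model import BackboneSpec, StagingNetwork


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def micro_net():
    """A micro network (5 tokens, d=8) for fast forward/backward tests."""
    spec = BackboneSpec(depth=2, dim=8, heads=2, patch_size=8, img_size=16,
                        tap_blocks=(1, 2))
    return StagingNetwork(spec, seed=7, attention_heads=2,
                          head_dropout=0.0, stochastic_depth=0.0)


def make_image(rng, size=32, label="he", value=None):
    if value is not None:
        pixels = np.full((size, size, 3), value, dtype=float)
    else:
        pixels = rng.random((size, size, 3))
    return LabeledImage(np.round(pixels * 255) / 255, label)


@pytest.fixture()
def random_simplex_rows():
    def make(n, c=6, seed=0):
        g = np.random.default_rng(seed)
        raw = g.random((n, c)) + 1e-3
        return raw / raw.sum(axis=1, keepdims=True)
    return make
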