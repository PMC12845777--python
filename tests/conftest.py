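import numpy as np
import pytest

from gefay.attention import AttentionSpec
from gefay.model import ModelSpec
from gefay.synth import SceneSpec, generate


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_dataset(tmp_path_factory):
    """12 small images, 4 classes, 7:2:1 split."""
    root = tmp_path_factory.mktemp("synth")
    spec = SceneSpec(image_size=160, n_images=12, n_classes=4,
                     min_objects=1, max_objects=3,
                     min_scale=0.2, max_scale=0.45, seed=11)
    generate(spec, root)
    return root


@pytest.fixture(scope="session")
def tiny_model_spec():
    """A narrow detector for fast forward passes."""
    return ModelSpec(nc=4, width_multiple=0.125, depth_multiple=0.33,
                     input_size=160, attention=AttentionSpec("none"))
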