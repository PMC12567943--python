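import numpy as np
import pytest

from wiretrace.mslnet import MSLNet, PatchMLPEncoder, TrainConfig, train
from wiretrace.synthetic import SceneConfig, make_dataset


@pytest.fixture(scope="session")
def trained_model():
    """A modestly trained network for pipeline-level tests.

    Mid-scale setting (80 scenes of 160x160, 12 epochs) trains in well under
    a minute and yields usable segmentations; quality-critical checks use the
    larger run in the acceptance tests.
    """
    cfg = SceneConfig(height=160, width=160, seed=0)
    ds = make_dataset(cfg, 80, seed=50)
    model = MSLNet(PatchMLPEncoder(seed=0))
    train(model, [(s.image, s.mask) for s in ds], TrainConfig(epochs=12, seed=0))
    return model


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
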