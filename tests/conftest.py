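import numpy as np
import pytest

from logmelaci import AudioSignal, FrameParams
from logmelaci.synth import DielDatasetSpec, gen_diel_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def default_params():
    return FrameParams()


@pytest.fixture
def random_signal(rng):
    return AudioSignal(rng.uniform(-0.5, 0.5, 22050), 22050, source_id="random")


@pytest.fixture(scope="session")
def diel_dataset():
    """Default synthetic dawn/noon/night corpus (3 species x 3 periods x 5)."""
    return gen_diel_dataset(DielDatasetSpec(seed=7))
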