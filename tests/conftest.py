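import numpy as np
import pytest
from hypothesis import settings

from tonetrace import SpeakerRange, make_target_stimuli

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def targets():
    return make_target_stimuli()


@pytest.fixture(scope="session")
def target_range():
    return SpeakerRange("target", 120.0, 300.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
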