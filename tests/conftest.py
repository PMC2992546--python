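import numpy as np
import pytest
from hypothesis import settings

from stepcnv.model import GCNSignal, Hyperparameters, ModelState, Segment

settings.register_profile("repro", deadline=None, derandomize=True)
settings.load_profile("repro")


@pytest.fixture
def rng():
    return np.random.default_rng(20251)


@pytest.fixture
def toy_signal():
    """Small 8-probe signal with one clear step."""
    values = np.array([0.1, -0.2, 1.4, 1.6, 1.5, 0.2, -0.1, 0.05])
    return GCNSignal(np.arange(1, 9), values)


@pytest.fixture
def toy_state():
    return ModelState([Segment(3, 3, 1.5)], 0.09)


@pytest.fixture
def default_hp():
    return Hyperparameters()
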