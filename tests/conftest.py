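import numpy as np
import pytest

from gazelearn.saliency import compute_saliency_sequence
from gazelearn.stimulus import DisplayConfig, render_occluded_rod


@pytest.fixture(scope="session")
def display() -> DisplayConfig:
    return DisplayConfig()


@pytest.fixture(scope="session")
def frames(display):
    return render_occluded_rod(display)


@pytest.fixture(scope="session")
def smaps(frames):
    """Saliency maps for the full default display cycle (computed once)."""
    return compute_saliency_sequence(frames)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
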