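import numpy as np
import pytest

from retilume.synthfundus import generate, spec_for_preset


@pytest.fixture
def rng():
    return np.random.default_rng(20251001)


@pytest.fixture
def random_rgb(rng):
    return rng.integers(0, 256, size=(64, 64, 3), dtype=np.uint8)


@pytest.fixture(scope="session")
def red_phantom():
    return generate(spec_for_preset("red", seed=11))


@pytest.fixture(scope="session")
def pale_phantom():
    return generate(spec_for_preset("pale", seed=11))
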