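import numpy as np
import pytest

from uvsynth import synthetic_skin as S


@pytest.fixture(scope="session")
def clean_pair():
    """Noise-free, aligned phantom with spots."""
    return S.make_phantom(S.PhantomParams(seed=11, noise_sigma=0.0,
                                          misalign_max=0))


@pytest.fixture(scope="session")
def misaligned_pair():
    """Noise-free phantom with planted piecewise-constant shifts."""
    return S.make_phantom(S.PhantomParams(seed=12, noise_sigma=0.0,
                                          misalign_max=4, misalign_tile=96))


@pytest.fixture(scope="session")
def default_pair():
    """Phantom at default (noisy, misaligned) conditions."""
    return S.make_phantom(S.PhantomParams(seed=13, misalign_max=4))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
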