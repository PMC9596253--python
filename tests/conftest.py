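import numpy as np
import pytest

from ctcascade.io import WindowSpec, extract_slices
from ctcascade.phantom import PhantomSpec, generate_phantom


@pytest.fixture
def rng():
    return np.random.default_rng(2026)


@pytest.fixture(scope="session")
def phantom_with_info():
    """One default phantom plus the generator's ground-truth geometry."""
    return generate_phantom(PhantomSpec(), seed=7, return_info=True)


@pytest.fixture(scope="session")
def phantom_slices(phantom_with_info):
    volume, labels, _info = phantom_with_info
    return extract_slices(volume, labels, WindowSpec())


@pytest.fixture(scope="session")
def tumor_slices(phantom_slices):
    return [s for s in phantom_slices if s.has_tumor]


@pytest.fixture(scope="session")
def background_slices(phantom_slices):
    return [s for s in phantom_slices if not s.has_tumor]
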