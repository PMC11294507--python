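import numpy as np
import pytest

from diaphragmct import (
    CapPhantomSpec,
    ExtractionParams,
    extract_diaphragm,
    make_cap_phantom,
    split_lungs,
)


@pytest.fixture
def params():
    return ExtractionParams()


@pytest.fixture(scope="session")
def small_phantom():
    """a=30 mm, h=15 mm single-lung phantom: fast, analytic index 1.25."""
    spec = CapPhantomSpec(a=30.0, h=15.0)
    return spec, make_cap_phantom(spec)


@pytest.fixture(scope="session")
def small_surface(small_phantom):
    spec, vol = small_phantom
    left, _ = split_lungs(vol)
    return spec, extract_diaphragm(left)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
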