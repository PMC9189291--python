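import numpy as np
import pytest
from hypothesis import settings

from forceprofile import (
    ArrestPeptide,
    ConstructSpec,
    RenderParams,
    build_construct,
)

settings.register_profile("default", derandomize=True, max_examples=50)
settings.load_profile("default")


@pytest.fixture(scope="session")
def ap():
    return ArrestPeptide()


@pytest.fixture(scope="session")
def full_construct():
    """The full protein held 40 residues from the PTC (L = 279)."""
    return build_construct(ConstructSpec("L279", domain_length=239, linker_length=23))


@pytest.fixture
def noiseless_render():
    from dataclasses import replace

    return replace(RenderParams(), noise_sigma=0.0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
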