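import pytest
from hypothesis import settings

from lorefine.synthetic import (make_antiparallel_pair, make_ideal_helix,
                                make_ideal_strand)

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def helix12():
    return make_ideal_helix(12)


@pytest.fixture(scope="session")
def helix24():
    return make_ideal_helix(24)


@pytest.fixture(scope="session")
def strand12():
    return make_ideal_strand(12)


@pytest.fixture(scope="session")
def sheet8():
    return make_antiparallel_pair(8)
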