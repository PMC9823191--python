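import numpy as np
import pytest

from asnase import reference as ref
from asnase.response_surface import make_design


@pytest.fixture(scope="session")
def protoplast_surface():
    return ref.PROTOPLAST_SURFACE


@pytest.fixture(scope="session")
def yield_surface():
    return ref.ATPS_YIELD_SURFACE


@pytest.fixture(scope="session")
def purification_surface():
    return ref.ATPS_PURIFICATION_SURFACE


@pytest.fixture(scope="session")
def bbd3():
    """Box-Behnken design in 3 factors with 5 center runs (17 runs)."""
    return make_design("box_behnken", 3, center_points=5)


@pytest.fixture(scope="session")
def ccd5():
    """Face-centred central composite design in 5 factors."""
    return make_design("central_composite", 5, center_points=5, alpha=1.0)
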