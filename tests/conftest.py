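import numpy as np
import pytest

from clusterbind.designs import BindingSite, ClusterDesign
from clusterbind.synthetic import fixture_library


@pytest.fixture(scope="session")
def library():
    """Fixture design library keyed by target id."""
    return {d.target_id: d for d in fixture_library()}


@pytest.fixture
def two_overlapping_sites():
    """Two length-9 consensus sites sharing 3 bp (starts 0 and 6)."""
    return ClusterDesign(
        target_id="pair",
        sites=[BindingSite("a", 0), BindingSite("b", 6)],
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
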