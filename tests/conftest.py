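import numpy as np
import pytest

from octaq import generate_angiogram


@pytest.fixture(scope="session")
def macular_scan():
    """Default synthetic macular SCP angiogram + truth (304 px, seed 1)."""
    return generate_angiogram(seed=1, layer="SCP")


@pytest.fixture(scope="session")
def disc_scan():
    """Default synthetic disc RPC angiogram + truth (304 px, seed 3)."""
    return generate_angiogram(
        seed=3, layer="RPC", scan_type="disc", field_mm=4.5
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
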