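import numpy as np
import pytest

from fescheck import Thermo


@pytest.fixture(scope="session")
def thermo() -> Thermo:
    return Thermo()


@pytest.fixture(scope="session")
def kt(thermo) -> float:
    return thermo.kt


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260927)
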