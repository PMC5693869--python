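import numpy as np
import pytest

from rodeca.synth import simulate_case


@pytest.fixture(scope="session")
def case_a_20db():
    """One case-A scene with 20 dB noise (shared, read-only)."""
    return simulate_case("A", 20.0, seed=0)


@pytest.fixture(scope="session")
def case_a_clean():
    """One noiseless case-A scene (shared, read-only)."""
    return simulate_case("A", np.inf, seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
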