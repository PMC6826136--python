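import numpy as np
import pytest

from redrift import AgingSimSpec, simulate_study


@pytest.fixture(scope="session")
def default_spec() -> AgingSimSpec:
    return AgingSimSpec()


@pytest.fixture(scope="session")
def default_study(default_spec):
    """One full simulated aging study at the default parameterization.

    Session-scoped: the generative model plus pipeline quantification take a
    few seconds, and many tests only read from the result.
    """
    return simulate_study(default_spec)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
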