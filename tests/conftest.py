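import pytest

from tsdnorm import McmcConfig, load_gekko_fixture


@pytest.fixture(scope="session")
def gekko():
    """The packaged three-population gecko incubation dataset."""
    return load_gekko_fixture()


@pytest.fixture()
def light_config():
    """A short MCMC configuration for tests that only need a rough posterior."""
    return McmcConfig(seed=42, n_iterations=6_000, burn_in=1_000, thin=5)
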