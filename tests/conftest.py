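import pytest

import f2link as fl


@pytest.fixture(scope="session")
def owb_config():
    return fl.owb_default_config()


@pytest.fixture(scope="session")
def owb_population(owb_config):
    """One simulated population at the default study size (n = 303)."""
    return fl.simulate_population(owb_config, seed=11)


@pytest.fixture(scope="session")
def owb_population_large(owb_config):
    """A large population for distributional checks."""
    return fl.simulate_population(owb_config, seed=7, n=10_000)
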