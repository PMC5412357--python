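import pytest
from hypothesis import settings

from mitocomp import synthetic_data as sd

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_genome():
    """One default synthetic genome with its truth sidecar (seed 1)."""
    return sd.generate_genome(sd.GeneratorConfig(seed=1))


@pytest.fixture(scope="session")
def genome(default_genome):
    return default_genome[0]


@pytest.fixture(scope="session")
def truth(default_genome):
    return default_genome[1]


@pytest.fixture(scope="session")
def templates():
    return sd.load_cloverleaf_templates()
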