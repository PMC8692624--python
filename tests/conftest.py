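import pytest
from hypothesis import settings

from mitocompare import SimulationConfig, load_reference_annotation, simulate_clade

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def reference_annotation():
    """The packaged 16.6 kb duck mitogenome annotation (no sequence)."""
    return load_reference_annotation()


@pytest.fixture(scope="session")
def default_clade():
    """The default 4-taxon simulated clade at the default seed."""
    return simulate_clade(SimulationConfig(seed=0))
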