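import pytest
from hypothesis import settings

from smartprotocols.authoring import SynthConfig, running_example, synthesize_protocol
from smartprotocols.rdf import build_term_registry

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def fixture_protocol():
    """The built-in TRIzol RNA-extraction running example."""
    return running_example()


@pytest.fixture(scope="session")
def registry():
    return build_term_registry()


@pytest.fixture()
def synth():
    """Factory for seeded synthetic protocols."""
    def make(seed=0, **kwargs):
        return synthesize_protocol(SynthConfig(seed=seed, **kwargs))
    return make
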