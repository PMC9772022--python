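import pytest

from neurospan.synthesis import make_fixture


@pytest.fixture(scope="session")
def fixture():
    """The deterministic mini-ontology fixture shared across the suite."""
    return make_fixture()
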