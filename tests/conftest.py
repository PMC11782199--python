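import pytest

from irrnet import fixture_graphs, platonic


@pytest.fixture(scope="session")
def octahedron():
    return platonic("OCTAHEDRON")


@pytest.fixture(scope="session")
def icosahedron():
    return platonic("ICOSAHEDRON")


@pytest.fixture(scope="session")
def fixtures():
    """The deterministic fixture-graph suite, built once per session."""
    return fixture_graphs()
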