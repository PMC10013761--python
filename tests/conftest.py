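import pytest

from fssim import CavityConfig, Medium, ParticleSpec, build_field


@pytest.fixture(scope="session")
def water():
    return Medium.water()


@pytest.fixture(scope="session")
def cavity():
    return CavityConfig()


@pytest.fixture(scope="session")
def field(cavity, water):
    return build_field(cavity, water)


@pytest.fixture(scope="session")
def cell():
    return ParticleSpec.cell()


@pytest.fixture(scope="session")
def mid_node(field):
    """A node near mid-height, away from both boundaries."""
    return float(field.node_positions[68])
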