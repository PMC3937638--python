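import pytest

from linkgag.complex_modeler import default_restraints
from linkgag.synthetic_data import FixtureSpec, fixture_maps, make_receptor_fixture


@pytest.fixture(scope="session")
def receptor_and_pose():
    """Synthetic groove receptor plus the reference HA8^AN pose it encodes."""
    return make_receptor_fixture(FixtureSpec())


@pytest.fixture(scope="session")
def receptor(receptor_and_pose):
    return receptor_and_pose[0]


@pytest.fixture(scope="session")
def reference_pose(receptor_and_pose):
    return receptor_and_pose[1]


@pytest.fixture(scope="session")
def maps():
    return fixture_maps()


@pytest.fixture(scope="session")
def restraints():
    return default_restraints()
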