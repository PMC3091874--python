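import pytest

from modresc.core import HostBackground, Strain
from modresc.fixtures import six_strain_fixture, table2_assignment


@pytest.fixture(scope="session")
def six_matrix():
    return six_strain_fixture()


@pytest.fixture(scope="session")
def table2():
    return table2_assignment()


@pytest.fixture
def gk(request):
    """Shorthand goalkeeper strain factory."""
    def make(label, q1, q2):
        return Strain(id=label, gk=(q1, q2))
    return make


@pytest.fixture
def lk(request):
    """Shorthand lock-key strain factory."""
    def make(label, locks, keys, suicidal=False):
        return Strain(id=label, locks=frozenset(map(str, locks)),
                      keys=frozenset(map(str, keys)), suicidal=suicidal)
    return make


@pytest.fixture
def zero_host():
    return HostBackground.zero(2)
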