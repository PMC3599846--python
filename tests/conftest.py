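import pytest

from gosempub import fixtures as fx
from gosempub.annotations import parse_gaf
from gosempub.ontology import parse_obo


@pytest.fixture(scope="session")
def fig7():
    """Parsed mini-ontology and annotation table (2 direct / 5 expanded genes)."""
    obo, gaf = fx.fig7_fixture()
    return parse_obo(obo), parse_gaf(gaf)


@pytest.fixture(scope="session")
def lipid_graph():
    return parse_obo(fx.lipid_fixture())


@pytest.fixture(scope="session")
def world():
    """One default synthetic world shared by read-only tests."""
    return fx.generate_world(fx.GeneratorConfig(seed=11))


CHAIN_OBO = """\
format-version: 1.2

[Term]
id: GO:0000001
name: top process
namespace: biological_process

[Term]
id: GO:0000002
name: middle process
namespace: biological_process
is_a: GO:0000001

[Term]
id: GO:0000003
name: bottom process
namespace: biological_process
is_a: GO:0000002
"""

DIAMOND_OBO = """\
format-version: 1.2

[Term]
id: GO:0000010
name: root process
namespace: biological_process

[Term]
id: GO:0000011
name: mid process
namespace: biological_process
is_a: GO:0000010

[Term]
id: GO:0000012
name: double parent process
namespace: biological_process
is_a: GO:0000011
is_a: GO:0000010
"""


@pytest.fixture(scope="session")
def chain_graph():
    return parse_obo(CHAIN_OBO)


@pytest.fixture(scope="session")
def diamond_graph():
    return parse_obo(DIAMOND_OBO)
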