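import io

import pytest

from goqa.ontology import parse_obo
from goqa.synthetic import SynthConfig, make_corpus, make_ontology

TINY_OBO = """\
format-version: 1.2

[Term]
id: GO:0000001
name: molecular function
namespace: molecular_function

[Term]
id: GO:0000002
name: catalytic activity
namespace: molecular_function
synonym: "enzyme activity" EXACT []
synonym: "Catalytic  Activity" EXACT []
alt_id: GO:9000002
is_a: GO:0000001 ! molecular function

[Term]
id: GO:0000003
name: nitrile hydratase activity
namespace: molecular_function
is_a: GO:0000002 ! catalytic activity
"""

# DAG where the longest root-to-B path has 2 edges even though root is
# also a direct parent of B: root -> A -> B plus root -> B.
DIAMOND_OBO = """\
[Term]
id: GO:0000001
name: root function
namespace: molecular_function

[Term]
id: GO:0000002
name: term alpha
namespace: molecular_function
is_a: GO:0000001

[Term]
id: GO:0000003
name: term beta
namespace: molecular_function
is_a: GO:0000002
is_a: GO:0000001
"""

MIXED_OBO = """\
[Term]
id: GO:0000001
name: molecular function
namespace: molecular_function

[Term]
id: GO:0000002
name: kinase activity
namespace: molecular_function
is_a: GO:0000001

[Term]
id: GO:0000003
name: transporter activity
namespace: molecular_function
is_a: GO:0000001

[Term]
id: GO:0000004
name: binding
namespace: molecular_function
is_a: GO:0000001

[Term]
id: GO:0000005
name: protein binding
namespace: molecular_function
is_a: GO:0000004

[Term]
id: GO:0000010
name: cellular component
namespace: cellular_component

[Term]
id: GO:0000011
name: membrane
namespace: cellular_component
is_a: GO:0000010

[Term]
id: GO:0000012
name: nucleus
namespace: cellular_component
is_a: GO:0000010

[Term]
id: GO:0000013
name: retired compartment
namespace: cellular_component
is_obsolete: true
"""


@pytest.fixture
def tiny_ontology():
    return parse_obo(io.StringIO(TINY_OBO))


@pytest.fixture
def diamond_ontology():
    return parse_obo(io.StringIO(DIAMOND_OBO))


@pytest.fixture
def mixed_ontology():
    """5 molecular_function + 2 cellular_component live terms, 1 obsolete."""
    return parse_obo(io.StringIO(MIXED_OBO))


@pytest.fixture(scope="session")
def synth_config():
    return SynthConfig(seed=1)


@pytest.fixture(scope="session")
def synth_ontology(synth_config):
    return make_ontology(synth_config)


@pytest.fixture(scope="session")
def synth_corpus_kb(synth_config, synth_ontology):
    return make_corpus(synth_config, synth_ontology)
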