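import pytest
from hypothesis import HealthCheck, settings

from ontofuse import FusionConfig, OntologyGraph
from ontofuse.fixtures import load_fixture_pair
from ontofuse.synthetic import standard_pair

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


def build_graph(edges, extra_nodes=(), labels=None, name="g"):
    """Ontology from an edge list; classes auto-created in first-seen order."""
    onto = OntologyGraph(name)
    labels = labels or {}
    for p, c in edges:
        for node in (p, c):
            if node not in onto:
                onto.add_class(node, labels.get(node, node))
    for node in extra_nodes:
        if node not in onto:
            onto.add_class(node, labels.get(node, node))
    for p, c in edges:
        onto.add_edge(p, c)
    return onto


@pytest.fixture
def chain():
    """Directed chain a->b->c->d->e."""
    return build_graph([("a", "b"), ("b", "c"), ("c", "d"), ("d", "e")])


@pytest.fixture
def default_cfg():
    return FusionConfig()


@pytest.fixture(scope="session")
def fixture_pair():
    """The packaged ~60-class synthetic OWL pair with its reference."""
    return load_fixture_pair()


@pytest.fixture(scope="session")
def small_pair():
    """A small seeded synthetic pair for end-to-end checks."""
    return standard_pair(11, n=80)
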