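import pytest

from kgweave.fixtures import FixtureParams, gen_fixture
from kgweave.ontology import clean_ontology, merge_ontologies
from kgweave.rdf import NodeRef, Triple, TripleGraph

SMALL_PARAMS = FixtureParams(
    n_classes=14, n_restrictions=4, n_deprecated=2,
    n_edge_types=3, edges_per_type=12, seed=11,
)


@pytest.fixture
def small_params():
    return SMALL_PARAMS


@pytest.fixture
def fixture_bundle(small_params):
    return gen_fixture(small_params)


@pytest.fixture
def cleaned_core(fixture_bundle):
    return merge_ontologies(
        [clean_ontology(g)[0] for g in fixture_bundle.ontologies])


def iri(v: str) -> NodeRef:
    return NodeRef.iri(v)


def t(s, p, o) -> Triple:
    return Triple(s, p, o)


def graph_of(*triples) -> TripleGraph:
    return TripleGraph(triples)
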