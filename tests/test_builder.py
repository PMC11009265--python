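"""Deterministic node minting, anchoring, relation expansion, builds."""

import hashlib

import pytest

from kgweave import vocab
from kgweave.builder import (
    BuildConfig,
    BuildError,
    RelationMap,
    all_variant_configs,
    anchor_entities,
    build_kg,
    construct_graph,
    expand_relations,
    materialize_edge,
    mint_class_proxy,
    mint_edge_node,
)
from kgweave.edges import EdgeList
from kgweave.fixtures import gen_fixture, write_fixture_bundle
from kgweave.ontology import ConfigurationError
from kgweave.rdf import NodeRef, Triple, TripleGraph

S = "https://example.org/data/gene/BRCA1"
R = "https://example.org/rel/edge/interacts_with"
O = "https://example.org/onto/TOYA_0000003"

_TYPE = NodeRef.iri(vocab.RDF_TYPE)
_SUB = NodeRef.iri(vocab.RDFS_SUBCLASSOF)


def _edge_list(pairs, relation=R, **kw):
    return EdgeList(edge_type=kw.pop("edge_type", "toy"), relation=relation,
                    inverse_relation=kw.pop("inverse_relation", None),
                    symmetric=kw.pop("symmetric", False),
                    pairs=list(pairs), provenance={})


# ---------------------------------------------------------------------------
# minting
# ---------------------------------------------------------------------------

def test_mint_is_deterministic_and_relation_sensitive():
    assert mint_edge_node(S, R, O) == mint_edge_node(S, R, O)
    assert mint_edge_node(S, R, O) != mint_edge_node(S, R + "2", O)
    assert mint_edge_node(S, R, O) != mint_edge_node(O, R, S)


def test_mint_matches_independent_md5_oracle():
    """Digest frozen from an independently computed md5 of the
    concatenation (s+'subject') || r || (o+'object')."""
    node = mint_edge_node(S, R, O)
    assert node.kind == "anon"
    assert node.value == "2c7cfa499427fec23d1a5526a67575d3"
    assert node.value == hashlib.md5(
        (S + "subject" + R + O + "object").encode()).hexdigest()
    assert mint_class_proxy(O).value == "9a6f1ec8f911d3c57a096ad573e52e93"


def test_mint_rejects_non_iri_input():
    with pytest.raises(ValueError):
        mint_edge_node("not an iri", R, O)
    with pytest.raises(ValueError):
        mint_class_proxy("relative/path")


# ---------------------------------------------------------------------------
# anchoring
# ---------------------------------------------------------------------------

def test_class_model_anchoring_emits_exact_pattern():
    anchored = anchor_entities([_edge_list([(S, O)])], {S: O},
                               "class_based", {O})
    assert set(anchored) == {
        Triple(NodeRef.iri(S), _TYPE, NodeRef.iri(vocab.OWL_CLASS)),
        Triple(NodeRef.iri(S), _SUB, NodeRef.iri(O)),
    }


def test_instance_model_anchoring_emits_exact_pattern():
    anchored = anchor_entities([_edge_list([(S, O)])], {S: O},
                               "instance_based", {O})
    assert set(anchored) == {
        Triple(NodeRef.iri(S), _TYPE,
               NodeRef.iri(vocab.OWL_NAMED_INDIVIDUAL)),
        Triple(NodeRef.iri(S), _TYPE, NodeRef.iri(O)),
    }


def test_entity_in_three_edge_lists_is_anchored_once():
    lists = [_edge_list([(S, O)], edge_type=f"t{i}",
                        relation=R + str(i)) for i in range(3)]
    anchored = anchor_entities(lists, {S: O}, "class_based", {O})
    assert len(anchored) == 2


def test_missing_anchor_aborts_listing_entities():
    with pytest.raises(BuildError, match="BRCA1"):
        anchor_entities([_edge_list([(S, O)])], {}, "class_based", {O})


# ---------------------------------------------------------------------------
# relation expansion
# ---------------------------------------------------------------------------

def test_inverse_strategy_doubles_invertible_type():
    relmap = RelationMap(inverses={R: R + "_inv", R + "_inv": R})
    pairs = [(f"https://x.org/s{i}", f"https://x.org/o{i}")
             for i in range(10)]
    std = expand_relations(_edge_list(pairs), relmap, "standard")
    inv = expand_relations(_edge_list(pairs), relmap, "inverse")
    assert len(std) == 10
    assert len(inv) == 20
    assert ("https://x.org/o0", R + "_inv", "https://x.org/s0") in inv


def test_inverse_strategy_doubles_symmetric_type():
    pairs = [(f"https://x.org/g{i}", f"https://x.org/g{i + 1}")
             for i in range(0, 10, 2)]
    inv = expand_relations(_edge_list(pairs, symmetric=True),
                           RelationMap(), "inverse")
    assert len(inv) == 10
    assert ("https://x.org/g1", R, "https://x.org/g0") in inv


def test_inverse_less_relation_is_unchanged():
    pairs = [(f"https://x.org/s{i}", f"https://x.org/o{i}")
             for i in range(7)]
    inv = expand_relations(_edge_list(pairs), RelationMap(), "inverse")
    assert len(inv) == 7


def test_symmetric_expansion_skips_already_reciprocal_pairs():
    pairs = [("https://x.org/a", "https://x.org/b"),
             ("https://x.org/b", "https://x.org/a")]
    inv = expand_relations(_edge_list(pairs, symmetric=True),
                           RelationMap(), "inverse")
    assert len(inv) == 2  # reciprocals already present; nothing added


def test_symmetric_with_inverse_is_configuration_error():
    relmap = RelationMap(inverses={R: R + "_inv", R + "_inv": R})
    with pytest.raises(ConfigurationError):
        expand_relations(_edge_list([("https://x.org/a", "https://x.org/b")],
                                    symmetric=True), relmap, "inverse")


def test_relation_map_must_be_mutually_inverse():
    with pytest.raises(ConfigurationError):
        RelationMap(inverses={R: R + "_inv"})


# ---------------------------------------------------------------------------
# edge materialization
# ---------------------------------------------------------------------------

def test_class_model_edge_is_four_triple_restriction():
    triples = materialize_edge((S, R, O), "class_based", {S})
    b = mint_edge_node(S, R, O)
    assert triples == {
        Triple(NodeRef.iri(S), _SUB, b),
        Triple(b, _TYPE, NodeRef.iri(vocab.OWL_RESTRICTION)),
        Triple(b, NodeRef.iri(vocab.OWL_ON_PROPERTY), NodeRef.iri(R)),
        Triple(b, NodeRef.iri(vocab.OWL_SOME_VALUES_FROM), NodeRef.iri(O)),
    }


def test_instance_model_edge_between_anchored_entities_is_one_triple():
    other = "https://example.org/data/gene/TP53"
    triples = materialize_edge((S, R, other), "instance_based", {S, other})
    assert triples == {Triple(NodeRef.iri(S), NodeRef.iri(R),
                              NodeRef.iri(other))}


def test_instance_model_class_participant_gets_one_reusable_proxy():
    cache = {}
    first = materialize_edge((S, R, O), "instance_based", {S}, cache)
    second = materialize_edge((S, R + "2", O), "instance_based", {S}, cache)
    proxy = mint_class_proxy(O)
    assert Triple(proxy, _TYPE, NodeRef.iri(O)) in first
    assert all(t.object != NodeRef.iri(O) or t.subject != proxy
               for t in second)  # typing emitted only once
    assert Triple(NodeRef.iri(S), NodeRef.iri(R + "2"), proxy) in second


def test_duplicate_assertion_adds_no_new_triples():
    g = TripleGraph()
    g.update(materialize_edge((S, R, O), "class_based", {S}))
    before = len(g)
    g.update(materialize_edge((S, R, O), "class_based", {S}))
    assert len(g) == before


# ---------------------------------------------------------------------------
# construction accounting and full builds
# ---------------------------------------------------------------------------

def test_toy_build_triple_count_hand_accounted():
    """core + 2 anchoring triples per entity + 4 per class-model edge."""
    core = TripleGraph()
    classes = [f"https://x.org/C{i}" for i in range(3)]
    for c in classes:
        core.add(Triple(NodeRef.iri(c), _TYPE,
                        NodeRef.iri(vocab.OWL_CLASS)))
    entities = [f"https://x.org/e{i}" for i in range(5)]
    pairs = [(entities[i], classes[i % 3]) for i in range(5)] \
        + [(entities[0], classes[1]), (entities[1], classes[2]),
           (entities[2], classes[0]), (entities[3], classes[1]),
           (entities[4], classes[2])]
    anchors = {e: classes[0] for e in entities}
    graph, assertions = construct_graph(
        core, [_edge_list(pairs)], anchors, RelationMap(),
        "class_based", "standard")
    assert len(assertions) == 10
    assert len(graph) == len(core) + 2 * len(entities) + 4 * 10


def test_build_with_empty_edge_lists_equals_cleaned_core(tmp_path, small_params):
    fixture = gen_fixture(small_params)
    bundle = write_fixture_bundle(fixture, tmp_path / "fx")
    config = BuildConfig.from_yaml(bundle / "config.yaml",
                                   edge_spec_paths=[],
                                   output_directory=str(tmp_path / "out"))
    result = build_kg(config)
    from kgweave.ontology import clean_ontology, merge_ontologies

    expected = merge_ontologies(
        [clean_ontology(g)[0] for g in fixture.ontologies])
    assert result.graph == expected


def test_identical_rebuild_is_byte_identical(tmp_path, small_params):
    fixture = gen_fixture(small_params)
    bundle = write_fixture_bundle(fixture, tmp_path / "fx")
    outputs = []
    for run in ("a", "b"):
        config = BuildConfig.from_yaml(
            bundle / "config.yaml",
            knowledge_model="instance_based",
            relation_strategy="inverse",
            output_directory=str(tmp_path / run))
        result = build_kg(config)
        outputs.append(result.graph_path.read_bytes())
    assert outputs[0] == outputs[1]


def test_build_writes_metadata_and_log_artifacts(tmp_path, small_params):
    bundle = write_fixture_bundle(gen_fixture(small_params), tmp_path / "fx")
    out = tmp_path / "out"
    config = BuildConfig.from_yaml(bundle / "config.yaml",
                                   output_directory=str(out))
    build_kg(config)
    for name in ("node_metadata.tsv", "stats.json",
                 "ontology_cleaning_report.txt",
                 "ontology_source_metadata.txt", "edge_source_metadata.txt",
                 "pkt_build_log.log"):
        assert (out / name).exists(), name
    log = (out / "pkt_build_log.log").read_text()
    for stage in ("clean", "merge", "assemble", "construct", "serialize"):
        assert f"[{stage}]" in log


def test_twelve_variant_matrix_is_complete_and_unique():
    configs = all_variant_configs(BuildConfig(output_directory="x"))
    names = [c.variant_name for c in configs]
    assert len(names) == 12 and len(set(names)) == 12


def test_build_config_validation():
    with pytest.raises(ConfigurationError):
        BuildConfig(knowledge_model="nope")
    with pytest.raises(ConfigurationError):
        BuildConfig(relation_strategy="bidirectional")
    with pytest.raises(ConfigurationError):
        BuildConfig(abstraction="owlnets2")
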