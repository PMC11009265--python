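"""Core RDF model: canonical N-Triples I/O, merging, list decoding."""

import gzip
import io

import pytest
from hypothesis import given, settings, strategies as st

from kgweave import vocab
from kgweave.rdf import (
    MalformedListError,
    NodeRef,
    ParseError,
    Triple,
    TripleGraph,
    decode_rdf_list,
    dumps_ntriples,
    loads_ntriples,
    merge_graphs,
    parse_ntriples,
    serialize_ntriples,
)

EX = "https://example.org/"


def _iri(name):
    return NodeRef.iri(EX + name)


def _t(s, p, o):
    return Triple(_iri(s), _iri(p), _iri(o) if isinstance(o, str) else o)


# ---------------------------------------------------------------------------
# node / triple contracts
# ---------------------------------------------------------------------------

def test_noderef_rejects_relative_iri_and_literal_subject():
    with pytest.raises(ValueError):
        NodeRef.iri("relative/path")
    with pytest.raises(ValueError):
        Triple(NodeRef.literal("x"), _iri("p"), _iri("o"))
    with pytest.raises(ValueError):
        Triple(_iri("s"), NodeRef.anon("b0"), _iri("o"))


def test_literal_comparison_is_lexical():
    assert NodeRef.literal("1.0") != NodeRef.literal("1.00")
    assert NodeRef.literal("x", lang="en") != NodeRef.literal("x")


# ---------------------------------------------------------------------------
# parsing
# ---------------------------------------------------------------------------

def test_parse_empty_stream_gives_empty_graph():
    assert len(loads_ntriples("")) == 0


def test_parse_deduplicates_identical_lines():
    line = f"<{EX}s> <{EX}p> <{EX}o> ."
    other = f"<{EX}s> <{EX}p> <{EX}o2> ."
    graph = loads_ntriples("\n".join([line, other, line]))
    assert len(graph) == 2


def test_parse_preserves_blank_node_labels_verbatim():
    graph = loads_ntriples(f"_:abc123 <{EX}p> _:Zz9 .")
    (t,) = list(graph)
    assert t.subject == NodeRef.anon("abc123")
    assert t.object == NodeRef.anon("Zz9")


def test_parse_literal_forms():
    text = "\n".join([
        f'<{EX}s> <{EX}p> "plain" .',
        f'<{EX}s> <{EX}p> "typed"^^<{vocab.XSD_STRING}> .',
        f'<{EX}s> <{EX}p> "tagged"@en-GB .',
        f'<{EX}s> <{EX}p> "esc\\"q\\n\\\\" .',
    ])
    graph = loads_ntriples(text)
    values = {t.object for t in graph}
    assert NodeRef.literal("plain") in values
    assert NodeRef.literal("typed", datatype=vocab.XSD_STRING) in values
    assert NodeRef.literal("tagged", lang="en-GB") in values
    assert NodeRef.literal('esc"q\n\\') in values


@pytest.mark.parametrize("bad, lineno", [
    (f"<{EX}s> <{EX}p> <{EX}o>", 1),              # missing dot
    (f"<{EX}s> <{EX}p> .", 1),                    # missing object
    (f'"lit" <{EX}p> <{EX}o> .', 1),              # literal subject
    (f"<{EX}s> _:b <{EX}o> .", 1),                # bnode predicate
    (f"<{EX}ok> <{EX}p> <{EX}o> .\n<rel> <{EX}p> <{EX}o> .", 2),  # relative
])
def test_parse_errors_cite_line_number(bad, lineno):
    with pytest.raises(ParseError) as err:
        loads_ntriples(bad)
    assert err.value.lineno == lineno


def test_comments_and_blank_lines_are_skipped():
    graph = loads_ntriples(f"# header\n\n<{EX}s> <{EX}p> <{EX}o> .\n")
    assert len(graph) == 1


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def test_serialize_empty_graph_is_empty():
    assert dumps_ntriples(TripleGraph()) == ""


def test_serialize_sorts_lines_lexicographically():
    graph = TripleGraph([_t("b", "p", "x"), _t("a", "p", "x")])
    expected = (f"<{EX}a> <{EX}p> <{EX}x> .\n"
                f"<{EX}b> <{EX}p> <{EX}x> .\n")
    assert dumps_ntriples(graph) == expected


def test_serialization_is_byte_deterministic_across_insert_orders():
    triples = [_t(f"s{i}", "p", f"o{i}") for i in range(20)]
    a = dumps_ntriples(TripleGraph(triples))
    b = dumps_ntriples(TripleGraph(reversed(triples)))
    assert a == b
    assert dumps_ntriples(TripleGraph(triples)) == a


def test_gzip_file_round_trip(tmp_path):
    graph = TripleGraph([_t("s", "p", "o"), _t("s2", "p", "o")])
    path = tmp_path / "g.nt.gz"
    serialize_ntriples(graph, path)
    with gzip.open(path, "rt") as fh:
        assert fh.read() == dumps_ntriples(graph)
    assert parse_ntriples(path) == graph


# ---------------------------------------------------------------------------
# round-trip property
# ---------------------------------------------------------------------------

_iris = st.builds(
    lambda tail: NodeRef.iri(EX + tail),
    st.text(alphabet="abcXYZ019/#.-_~", min_size=1, max_size=12))
_anons = st.builds(
    NodeRef.anon,
    st.text(alphabet="abcdef0123456789", min_size=1, max_size=32))
_literals = st.one_of(
    st.builds(NodeRef.literal, st.text(max_size=20)),
    st.builds(lambda v: NodeRef.literal(v, datatype=vocab.XSD_STRING),
              st.text(max_size=10)),
    st.builds(lambda v: NodeRef.literal(v, lang="en"), st.text(max_size=10)),
)
_triples = st.builds(
    Triple,
    st.one_of(_iris, _anons),
    _iris,
    st.one_of(_iris, _anons, _literals))
_graphs = st.builds(TripleGraph, st.lists(_triples, max_size=30))


@settings(max_examples=60, deadline=None, derandomize=True)
@given(_graphs)
def test_parse_serialize_round_trip(graph):
    assert loads_ntriples(dumps_ntriples(graph)) == graph


@settings(max_examples=25, deadline=None, derandomize=True)
@given(_graphs, _graphs, _graphs)
def test_merge_is_associative_commutative_idempotent(a, b, c):
    ab_c = merge_graphs([merge_graphs([a, b]), c])
    a_bc = merge_graphs([a, merge_graphs([b, c])])
    assert ab_c == a_bc
    assert merge_graphs([a, b]) == merge_graphs([b, a])
    assert merge_graphs([a, a]) == a


def test_rdflib_accepts_canonical_output():
    """Independent parser oracle: rdflib reads our serialization and sees
    the same number of statements."""
    rdflib = pytest.importorskip("rdflib")
    graph = TripleGraph([
        _t("s", "p", "o"),
        _t("s", "p", NodeRef.literal('a "quoted"\nvalue', lang="en")),
        Triple(NodeRef.anon("deadbeef"), _iri("p"),
               NodeRef.literal("42", datatype=vocab.XSD_INTEGER)),
    ])
    rg = rdflib.Graph()
    rg.parse(data=dumps_ntriples(graph), format="nt")
    assert len(rg) == len(graph)
    iri_triples = {(str(t.subject), str(t.predicate), str(t.object))
                   for t in graph
                   if t.subject.kind == t.object.kind == "iri"
                   and t.subject.kind == "iri"}
    rdflib_iri_triples = {
        (str(s), str(p), str(o)) for s, p, o in rg
        if isinstance(s, rdflib.URIRef) and isinstance(o, rdflib.URIRef)}
    assert {(t.subject.value, t.predicate.value, t.object.value)
            for t in graph if t.subject.kind == "iri"
            and t.object.kind == "iri"} == rdflib_iri_triples


# ---------------------------------------------------------------------------
# merge examples
# ---------------------------------------------------------------------------

def test_merge_with_empty_is_identity():
    g = TripleGraph([_t("s", "p", "o")])
    assert merge_graphs([g, TripleGraph()]) == g


def test_merge_overlapping_graphs_counts_shared_triples_once():
    shared = _t("x", "p", "y")
    g5 = TripleGraph([shared] + [_t(f"a{i}", "p", "o") for i in range(4)])
    g3 = TripleGraph([shared] + [_t(f"b{i}", "p", "o") for i in range(2)])
    assert len(merge_graphs([g5, g3])) == 7


def test_merge_namespace_conflict_keeps_first_binding(caplog):
    a = TripleGraph(namespaces={"ex": EX})
    b = TripleGraph(namespaces={"ex": "https://other.org/"})
    merged = merge_graphs([a, b])
    assert merged.namespaces["ex"] == EX


# ---------------------------------------------------------------------------
# RDF collections
# ---------------------------------------------------------------------------

def _chain(members):
    graph = TripleGraph()
    first = NodeRef.iri(vocab.RDF_FIRST)
    rest = NodeRef.iri(vocab.RDF_REST)
    nil = NodeRef.iri(vocab.RDF_NIL)
    cells = [NodeRef.anon(f"c{i}") for i in range(len(members))]
    for i, m in enumerate(members):
        graph.add(Triple(cells[i], first, m))
        graph.add(Triple(cells[i], rest,
                         cells[i + 1] if i + 1 < len(members) else nil))
    return graph, (cells[0] if cells else nil)


def test_decode_nil_is_empty_sequence():
    assert decode_rdf_list(TripleGraph(), NodeRef.iri(vocab.RDF_NIL)) == []


def test_decode_single_and_three_member_chains():
    members = [_iri("m1"), _iri("m2"), _iri("m3")]
    graph, head = _chain(members[:1])
    assert decode_rdf_list(graph, head) == members[:1]
    graph, head = _chain(members)
    assert decode_rdf_list(graph, head) == members


def test_decode_broken_chain_names_head():
    graph, head = _chain([_iri("m1"), _iri("m2")])
    for t in list(graph.matching(p=NodeRef.iri(vocab.RDF_REST))):
        if t.object == NodeRef.iri(vocab.RDF_NIL):
            graph.discard(t)
    with pytest.raises(MalformedListError) as err:
        decode_rdf_list(graph, head)
    assert head.value in str(err.value)


def test_decode_cyclic_chain_raises():
    graph, head = _chain([_iri("m1"), _iri("m2")])
    rest = NodeRef.iri(vocab.RDF_REST)
    for t in list(graph.matching(p=rest)):
        if t.object == NodeRef.iri(vocab.RDF_NIL):
            graph.discard(t)
            graph.add(Triple(t.subject, rest, head))
    with pytest.raises(MalformedListError):
        decode_rdf_list(graph, head)
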