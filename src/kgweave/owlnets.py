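"""Semantic abstraction of OWL graphs into hybrid named-entity graphs.

OWL encodes each class-model edge through scaffolding that is logically
necessary but not biologically meaningful: an anonymous
``owl:Restriction`` node, its ``owl:onProperty``/``owl:someValuesFrom``
arms, collection cells, and so on. Abstraction decodes that scaffolding
back into direct ``(subject, relation, object)`` edges between named
entities, routes annotation triples to node metadata, and drops the
rest with exact per-construct accounting:

    retained + decoded_source + sum(dropped) == input triples

The transformation is deliberately lossy — negation (complementOf,
disjointWith) and undecodable constructs are dropped and loss-logged —
trading logical expressivity for a graph that network methods can
consume directly.

Harmonization ("purification") then makes the hybrid graph consistent
with one knowledge model: class-based rewrites ``rdf:type`` to
``rdfs:subClassOf``; instance-based rewrites ``rdfs:subClassOf`` to
``rdf:type``; set semantics deduplicate, so triple count can only
decrease or stay.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

from . import vocab
from .rdf import (
    MalformedListError,
    NodeRef,
    Triple,
    TripleGraph,
    decode_rdf_list,
    list_cell_triples,
)

logger = logging.getLogger(__name__)

_RDF_TYPE = NodeRef.iri(vocab.RDF_TYPE)
_RDFS_SUBCLASSOF = NodeRef.iri(vocab.RDFS_SUBCLASSOF)
_OWL_RESTRICTION = NodeRef.iri(vocab.OWL_RESTRICTION)
_OWL_ON_PROPERTY = NodeRef.iri(vocab.OWL_ON_PROPERTY)
_OWL_EQUIVALENT = NodeRef.iri(vocab.OWL_EQUIVALENT_CLASS)
_OWL_CLASS = NodeRef.iri(vocab.OWL_CLASS)

_FILLER_PREDICATES = (
    NodeRef.iri(vocab.OWL_SOME_VALUES_FROM),
    NodeRef.iri(vocab.OWL_ALL_VALUES_FROM),
    NodeRef.iri(vocab.OWL_ON_CLASS),
)
_COLLECTION_PREDICATES = (
    NodeRef.iri(vocab.OWL_INTERSECTION_OF),
    NodeRef.iri(vocab.OWL_UNION_OF),
)
_NEGATION_PREDICATES = {
    NodeRef.iri(vocab.OWL_COMPLEMENT_OF),
    NodeRef.iri(vocab.OWL_DISJOINT_WITH),
}
_FILTER_PREDICATES = {NodeRef.iri(p) for p in vocab.OWL_FILTER_PREDICATES}
_ANNOTATION_PREDICATES = {NodeRef.iri(p) for p in vocab.ANNOTATION_PREDICATES}
_OWL_BUILTINS = {NodeRef.iri(c) for c in vocab.OWL_BUILTIN_CLASSES}


@dataclass
class AbstractionResult:
    """Hybrid graph plus exact accounting of the transformation."""

    graph: TripleGraph
    decoded_count: int = 0
    retained_count: int = 0
    decoded_source_count: int = 0
    dropped: dict = field(default_factory=dict)
    loss_log: list = field(default_factory=list)
    annotations: TripleGraph = field(default_factory=TripleGraph)
    input_count: int = 0

    def accounts_exactly(self) -> bool:
        total = (self.retained_count + self.decoded_source_count
                 + sum(self.dropped.values()))
        return total == self.input_count

    def node_metadata(self):
        """Metadata extracted from the annotation triples routed out of
        the graph during abstraction."""
        from .ontology import extract_node_metadata

        return extract_node_metadata(self.annotations)

    def write_loss_log(self, dest) -> None:
        from pathlib import Path

        text = "\n".join(self.loss_log) + ("\n" if self.loss_log else "")
        Path(dest).write_text(text, encoding="utf-8")


def _restriction_heads(graph: TripleGraph) -> set[NodeRef]:
    return {t.subject for t in graph.matching(p=_RDF_TYPE, o=_OWL_RESTRICTION)
            if t.subject.kind == "anon"}


def decode_restriction(graph: TripleGraph, head: NodeRef,
                       subject: Optional[NodeRef] = None
                       ) -> Optional[tuple[NodeRef, NodeRef, NodeRef]]:
    """Decode one anonymous all-some restriction into (s, r, o).

    Requires exactly one ``owl:onProperty`` value and a named filler
    under ``owl:someValuesFrom`` / ``owl:allValuesFrom`` (a qualified
    cardinality's ``owl:onClass`` filler decodes the same way). The
    subject is the named class attached via ``rdfs:subClassOf`` or
    ``owl:equivalentClass`` unless supplied explicitly. Undecodable
    constructs return ``None`` and are logged by the caller.
    """
    props = [o for o in graph.objects(head, _OWL_ON_PROPERTY) if o.is_named]
    if len(props) != 1:
        return None
    fillers = []
    for pred in _FILLER_PREDICATES:
        fillers.extend(o for o in graph.objects(head, pred) if o.is_named)
    if len(fillers) != 1:
        return None
    if subject is None:
        subjects = sorted(
            {t.subject for pred in (_RDFS_SUBCLASSOF, _OWL_EQUIVALENT)
             for t in graph.matching(p=pred, o=head)
             if t.subject.is_named},
            key=lambda n: n.value)
        if not subjects:
            return None
        subject = subjects[0]
    return (subject, props[0], fillers[0])


def abstract_graph(graph: TripleGraph) -> AbstractionResult:
    """Run semantic abstraction over *graph*.

    Every input triple is claimed by exactly one category: retained
    (named-to-named, non-scaffold predicate), decoded source (consumed
    while decoding a restriction, a class-proxy typing, or a
    proxy-carried assertion), or dropped (collections, annotations,
    negation, OWL declarations, undecodable constructs). The result
    graph contains no anonymous nodes and no filter-list predicates.
    """
    result = AbstractionResult(graph=TripleGraph(namespaces=graph.namespaces),
                               input_count=len(graph))
    dropped = result.dropped
    claimed: set[Triple] = set()

    def claim(triples, category: str) -> int:
        n = 0
        for t in triples:
            if t in claimed or t not in graph:
                continue
            claimed.add(t)
            n += 1
        if category:
            dropped[category] = dropped.get(category, 0) + n
        return n

    def consume(triples) -> None:
        n = claim(triples, "")
        result.decoded_source_count += n

    emitted: set[Triple] = set()
    heads = _restriction_heads(graph)

    # -- 1. collections attached to named classes ---------------------------
    pending_subjects: dict[NodeRef, set[NodeRef]] = {}
    for pred in _COLLECTION_PREDICATES:
        for t in list(graph.matching(p=pred)):
            owner, head = t.subject, t.object
            attachment: list[Triple] = [t]
            if owner.is_named:
                attached_class: Optional[NodeRef] = owner
            else:
                named = sorted(
                    {a.subject
                     for p2 in (_OWL_EQUIVALENT, _RDFS_SUBCLASSOF)
                     for a in graph.matching(p=p2, o=owner)
                     if a.subject.is_named},
                    key=lambda n: n.value)
                attached_class = named[0] if named else None
                for p2 in (_OWL_EQUIVALENT, _RDFS_SUBCLASSOF):
                    attachment.extend(graph.matching(p=p2, o=owner))
                attachment.extend(graph.matching(s=owner))
            try:
                members = decode_rdf_list(graph, head)
            except MalformedListError as exc:
                result.loss_log.append(f"collection: {exc}")
                claim(attachment, "collections")
                claim(list_cell_triples(graph, head), "collections")
                continue
            claim(attachment, "collections")
            claim(list_cell_triples(graph, head), "collections")
            if attached_class is None:
                result.loss_log.append(
                    f"collection at {owner.value}: no named attached class")
                continue
            for member in members:
                if member.is_named:
                    emitted.add(Triple(attached_class, _RDFS_SUBCLASSOF,
                                       member))
                elif member in heads:
                    pending_subjects.setdefault(member, set()).add(
                        attached_class)
                else:
                    result.loss_log.append(
                        f"collection member {member.value} under "
                        f"{attached_class.value}: undecodable")

    # -- 2. restrictions ----------------------------------------------------
    for head in sorted(heads, key=lambda n: n.value):
        construct = list(graph.matching(s=head))
        attachments = [
            t for pred in (_RDFS_SUBCLASSOF, _OWL_EQUIVALENT)
            for t in graph.matching(p=pred, o=head)]
        subjects = sorted(
            {t.subject for t in attachments if t.subject.is_named}
            | pending_subjects.get(head, set()),
            key=lambda n: n.value)
        decoded_any = False
        for subj in subjects:
            edge = decode_restriction(graph, head, subject=subj)
            if edge is not None:
                emitted.add(Triple(*edge))
                decoded_any = True
        if decoded_any:
            result.decoded_count += 1
            consume(construct)
            consume(attachments)
        else:
            result.loss_log.append(
                f"restriction {head.value}: undecodable construct")
            claim(construct, "restrictions")
            claim(attachments, "restrictions")

    # -- 3. class-proxy typings (instance-model minted individuals) ---------
    proxies: dict[NodeRef, NodeRef] = {}
    for t in list(graph.matching(p=_RDF_TYPE)):
        if t in claimed:
            continue
        if (t.subject.kind == "anon" and t.object.is_named
                and t.object not in _OWL_BUILTINS):
            if t.subject in proxies:
                # ambiguous proxy: keep lexicographically first class
                if t.object.value < proxies[t.subject].value:
                    proxies[t.subject] = t.object
            else:
                proxies[t.subject] = t.object
            consume([t])

    # -- 4. everything else -------------------------------------------------
    for t in graph:
        if t in claimed:
            continue
        s, p, o = t.subject, t.predicate, t.object
        if p == _RDF_TYPE and o in _OWL_BUILTINS:
            claim([t], "owl_declarations")
        elif p in _ANNOTATION_PREDICATES or o.kind == "literal":
            claim([t], "annotations")
            result.annotations.add(t)
        elif p in _NEGATION_PREDICATES:
            claim([t], "negations")
            result.loss_log.append(
                f"negation: {s.value} {p.value} "
                f"{o.value if o.kind != 'literal' else '<literal>'}")
        elif p in _FILTER_PREDICATES:
            claim([t], "owl_scaffold")
        elif s.kind == "anon" or o.kind == "anon":
            rs = proxies.get(s, s if s.is_named else None)
            ro = proxies.get(o, o if o.is_named else None)
            if rs is not None and ro is not None:
                emitted.add(Triple(rs, p, ro))
                consume([t])
            else:
                claim([t], "other_anon")
                result.loss_log.append(
                    f"anonymous participant: {s.value} {p.value} {o.value}")
        else:
            claim([t], "")
            result.retained_count += 1
            result.graph.add(t)

    for t in emitted:
        if (t.subject.is_named and t.object.is_named
                and t.predicate not in _FILTER_PREDICATES):
            result.graph.add(t)

    assert result.accounts_exactly(), "abstraction accounting out of balance"
    return result


def harmonize(graph: TripleGraph, model: str) -> TripleGraph:
    """Rewrite the hybrid graph to one knowledge model's idiom.

    class_based: every ``rdf:type`` becomes ``rdfs:subClassOf``.
    instance_based: every ``rdfs:subClassOf`` becomes ``rdf:type``.
    Rewritten triples deduplicate against existing ones, so the count
    never increases, and the rewrite is idempotent.
    """
    if model == "class_based":
        src, dst = _RDF_TYPE, _RDFS_SUBCLASSOF
    elif model == "instance_based":
        src, dst = _RDFS_SUBCLASSOF, _RDF_TYPE
    else:
        raise ValueError(f"unknown knowledge model {model!r}")
    out = TripleGraph(namespaces=graph.namespaces)
    for t in graph:
        if t.predicate == src:
            out.add(Triple(t.subject, dst, t.object))
        else:
            out.add(t)
    return out
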