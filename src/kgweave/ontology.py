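"""Ontology merging, cleaning, and node-metadata extraction.

OBO-Foundry-style ontologies arrive with known defect classes:
deprecated classes still wired into the hierarchy, malformed IRIs,
cross-references to classes never declared, and duplicated labels.
``clean_ontology`` runs a fixed, extensible registry of checks — two
repairing (they remove triples) and two auditing (report-only) — and
returns a report whose arithmetic balances exactly:

    triples_after == triples_before - triples_removed + triples_added
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Optional, Sequence

from . import vocab
from .rdf import NodeRef, Triple, TripleGraph, is_absolute_iri, merge_graphs

logger = logging.getLogger(__name__)

_RDF_TYPE = NodeRef.iri(vocab.RDF_TYPE)
_OWL_CLASS = NodeRef.iri(vocab.OWL_CLASS)
_OWL_DEPRECATED = NodeRef.iri(vocab.OWL_DEPRECATED)
_RDFS_LABEL = NodeRef.iri(vocab.RDFS_LABEL)
_RDFS_SUBCLASSOF = NodeRef.iri(vocab.RDFS_SUBCLASSOF)
_OWL_EQUIVALENT = NodeRef.iri(vocab.OWL_EQUIVALENT_CLASS)

_STRICT_IRI_FORBIDDEN = set(' <>"{}|\\^`')


class ConfigurationError(ValueError):
    """An operation was invoked with an invalid configuration."""


@dataclass
class CleaningReport:
    """Per-check counts for one cleaned ontology; balances exactly."""

    classes_removed: int = 0
    triples_removed: int = 0
    triples_added: int = 0
    dangling_references: int = 0
    duplicate_labels: int = 0
    classes_before: int = 0
    classes_after: int = 0
    triples_before: int = 0
    triples_after: int = 0

    def balances(self) -> bool:
        return (self.triples_after
                == self.triples_before - self.triples_removed
                + self.triples_added)


@dataclass
class NodeMetadata:
    """Label/synonym/definition annotations attached to one IRI."""

    iri: str
    label: Optional[str] = None
    synonyms: set = field(default_factory=set)
    definition: Optional[str] = None
    namespace: str = ""


def merge_ontologies(ontologies: Sequence[TripleGraph]) -> TripleGraph:
    """Merge parsed ontologies into one deduplicated core ontology."""
    if not ontologies:
        raise ConfigurationError("no ontologies supplied to merge")
    merged = merge_graphs(ontologies)
    for i, g in enumerate(ontologies):
        logger.info("ontology %d contributed %d triples", i, len(g))
    logger.info("merged core ontology: %d triples", len(merged))
    return merged


def declared_classes(graph: TripleGraph) -> set[NodeRef]:
    """Named nodes declared ``rdf:type owl:Class``."""
    return {s for s in graph.subjects(_RDF_TYPE, _OWL_CLASS) if s.is_named}


# ---------------------------------------------------------------------------
# Cleaning checks. Each check takes a mutable graph and a report and
# applies/audits in place. Order matters and is fixed by DEFAULT_CHECKS.
# ---------------------------------------------------------------------------

def _is_deprecated_true(node: NodeRef) -> bool:
    return node.kind == "literal" and node.value.lower() == "true"


def check_deprecated_classes(graph: TripleGraph,
                             report: CleaningReport) -> None:
    """Remove every class annotated owl:deprecated "true" together with
    all triples mentioning it (no rewiring of subclass chains)."""
    deprecated = {
        t.subject for t in graph.matching(p=_OWL_DEPRECATED)
        if _is_deprecated_true(t.object) and t.subject.is_named
    }
    if not deprecated:
        return
    doomed = [t for t in graph
              if t.subject in deprecated or t.object in deprecated]
    for t in doomed:
        graph.discard(t)
    report.classes_removed += len(deprecated)
    report.triples_removed += len(doomed)
    logger.info("removed %d deprecated classes (%d triples)",
                len(deprecated), len(doomed))


def check_malformed_iris(graph: TripleGraph, report: CleaningReport) -> None:
    """Drop triples carrying an IRI that fails strict absolute-IRI
    validation (scheme present, no whitespace or angle-bracket chars)."""

    def bad(node: NodeRef) -> bool:
        if node.kind != "iri":
            return False
        return (not is_absolute_iri(node.value)
                or any(c in _STRICT_IRI_FORBIDDEN for c in node.value))

    doomed = [t for t in graph
              if bad(t.subject) or bad(t.predicate) or bad(t.object)]
    for t in doomed:
        graph.discard(t)
    report.triples_removed += len(doomed)
    if doomed:
        logger.info("removed %d triples with malformed IRIs", len(doomed))


def check_dangling_references(graph: TripleGraph,
                              report: CleaningReport) -> None:
    """Audit-only: count subclass/equivalence targets never declared as
    classes. The graph is left unchanged."""
    declared = declared_classes(graph)
    dangling = set()
    for pred in (_RDFS_SUBCLASSOF, _OWL_EQUIVALENT):
        for t in graph.matching(p=pred):
            if t.object.is_named and t.object not in declared:
                dangling.add(t.object)
    report.dangling_references += len(dangling)


def check_duplicate_labels(graph: TripleGraph,
                           report: CleaningReport) -> None:
    """Audit-only: count label strings shared by more than one IRI."""
    by_label: dict[str, set[NodeRef]] = {}
    for t in graph.matching(p=_RDFS_LABEL):
        if t.object.kind == "literal" and t.subject.is_named:
            by_label.setdefault(t.object.value, set()).add(t.subject)
    dupes = sum(1 for owners in by_label.values() if len(owners) > 1)
    report.duplicate_labels += dupes


CheckFn = Callable[[TripleGraph, CleaningReport], None]

#: Fixed-order registry; extend by appending (name, fn) pairs.
DEFAULT_CHECKS: list[tuple[str, CheckFn]] = [
    ("deprecated_classes", check_deprecated_classes),
    ("malformed_iris", check_malformed_iris),
    ("dangling_references", check_dangling_references),
    ("duplicate_labels", check_duplicate_labels),
]

_CHECK_NAMES = {name for name, _ in DEFAULT_CHECKS}


def clean_ontology(graph: TripleGraph,
                   checks: Optional[Sequence[str]] = None
                   ) -> tuple[TripleGraph, CleaningReport]:
    """Apply the cleaning-check registry; defects are reported, not fatal.

    Returns a new graph and a :class:`CleaningReport` whose arithmetic
    balances exactly. ``checks`` selects a subset of the registry by
    name (default: all, in fixed order).
    """
    if checks is None:
        selected = DEFAULT_CHECKS
    else:
        unknown = set(checks) - _CHECK_NAMES
        if unknown:
            raise ConfigurationError(f"unknown cleaning checks: {sorted(unknown)}")
        selected = [(n, f) for n, f in DEFAULT_CHECKS if n in set(checks)]

    cleaned = graph.copy()
    report = CleaningReport(
        classes_before=len(declared_classes(graph)),
        triples_before=len(graph),
    )
    for _name, fn in selected:
        fn(cleaned, report)
    report.classes_after = len(declared_classes(cleaned))
    report.triples_after = len(cleaned)
    assert report.balances(), "cleaning report arithmetic out of balance"
    return cleaned, report


def render_cleaning_report(reports: dict[str, CleaningReport]) -> str:
    """Plain-text report, one section per ontology, one line per check."""
    lines = ["ontology cleaning report", "=" * 40]
    for name in sorted(reports):
        r = reports[name]
        lines += [
            "",
            f"[{name}]",
            f"  classes: {r.classes_before} -> {r.classes_after}",
            f"  triples: {r.triples_before} -> {r.triples_after}",
            f"  deprecated classes removed: {r.classes_removed}",
            f"  triples removed: {r.triples_removed}",
            f"  triples added: {r.triples_added}",
            f"  dangling references (audit): {r.dangling_references}",
            f"  duplicate labels (audit): {r.duplicate_labels}",
        ]
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Node metadata
# ---------------------------------------------------------------------------

_SYNONYM = NodeRef.iri(vocab.OBO_EXACT_SYNONYM)
_DEFINITION = NodeRef.iri(vocab.IAO_DEFINITION)


def _namespace_of(iri: str, namespaces: dict[str, str]) -> str:
    for prefix, ns in sorted(namespaces.items(),
                             key=lambda kv: -len(kv[1])):
        if iri.startswith(ns):
            return prefix
    for sep in ("#", "/"):
        idx = iri.rfind(sep)
        if idx > 0:
            return iri[: idx + 1]
    return iri


def extract_node_metadata(graph: TripleGraph) -> dict[str, NodeMetadata]:
    """Collect labels (rdfs:label), exact synonyms and definitions for
    every named node in the graph; annotation triples stay in the graph.

    Multiple labels on one IRI resolve to the lexicographically first
    (deterministic regardless of input order); the conflict is logged.
    """
    records: dict[str, NodeMetadata] = {}

    def rec(node: NodeRef) -> Optional[NodeMetadata]:
        if not node.is_named:
            return None
        if node.value not in records:
            records[node.value] = NodeMetadata(
                iri=node.value,
                namespace=_namespace_of(node.value, graph.namespaces))
        return records[node.value]

    labels: dict[str, set[str]] = {}
    for t in graph:
        rec(t.subject)
        rec(t.object)
        if t.object.kind != "literal" or not t.subject.is_named:
            continue
        if t.predicate == _RDFS_LABEL:
            labels.setdefault(t.subject.value, set()).add(t.object.value)
        elif t.predicate == _SYNONYM:
            records[t.subject.value].synonyms.add(t.object.value)
        elif t.predicate == _DEFINITION:
            r = records[t.subject.value]
            if r.definition is None or t.object.value < r.definition:
                r.definition = t.object.value

    for iri_value, found in labels.items():
        if len(found) > 1:
            logger.warning("IRI %s has %d labels; keeping %r",
                           iri_value, len(found), min(found))
        records[iri_value].label = min(found)
    return records


def write_node_metadata_tsv(metadata: dict[str, NodeMetadata],
                            dest) -> None:
    """TSV: iri, label, definition, pipe-joined synonyms; sorted by IRI."""
    lines = ["iri\tlabel\tdefinition\tsynonyms"]
    for iri_value in sorted(metadata):
        m = metadata[iri_value]
        lines.append("\t".join([
            m.iri,
            m.label or "",
            m.definition or "",
            "|".join(sorted(m.synonyms)),
        ]))
    text = "\n".join(lines) + "\n"
    if isinstance(dest, (str, Path)):
        Path(dest).write_text(text, encoding="utf-8")
    else:
        dest.write(text)
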