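"""Minimal RDF data model with canonical, byte-deterministic N-Triples I/O.

The in-memory containers are deliberately small: a :class:`NodeRef` is an
IRI, a deterministic anonymous (blank) node, or a literal; a
:class:`Triple` is a subject/predicate/object assertion; a
:class:`TripleGraph` is a deduplicated triple set plus a prefix registry.
Together they hold a Description Logics knowledge base K = <T, A>, where
TBox triples relate named classes/properties and ABox triples involve
typed individuals.

N-Triples is the only interchange syntax. Serialization is canonical:
one triple per line, lines sorted lexicographically, fixed escaping —
two serializations of equal graphs are byte-identical, and blank-node
labels round-trip verbatim (they are minted deterministically elsewhere,
so relabeling would break build reproducibility).
"""

from __future__ import annotations

import gzip
import io
import logging
import os
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence, Union

from . import vocab

logger = logging.getLogger(__name__)

__all__ = [
    "NodeRef",
    "Triple",
    "TripleGraph",
    "ParseError",
    "MalformedListError",
    "parse_ntriples",
    "loads_ntriples",
    "serialize_ntriples",
    "dumps_ntriples",
    "merge_graphs",
    "decode_rdf_list",
    "is_absolute_iri",
]

_SCHEME_RE = re.compile(r"^[A-Za-z][A-Za-z0-9+.\-]*:")
_ANON_LABEL_RE = re.compile(r"^[A-Za-z0-9_][A-Za-z0-9_.\-]*$")


class ParseError(ValueError):
    """Malformed N-Triples input; carries the offending line number."""

    def __init__(self, message: str, lineno: Optional[int] = None):
        self.lineno = lineno
        if lineno is not None:
            message = f"line {lineno}: {message}"
        super().__init__(message)


class MalformedListError(ValueError):
    """An rdf:first/rdf:rest chain is broken or cyclic."""


def is_absolute_iri(value: str) -> bool:
    """True if *value* looks like an absolute IRI (has a scheme)."""
    return bool(_SCHEME_RE.match(value))


@dataclass(frozen=True)
class NodeRef:
    """One RDF term: an IRI, an anonymous node, or a literal.

    ``kind`` is one of ``"iri"``, ``"anon"``, ``"literal"``.  For IRIs the
    value must be absolute; anonymous-node values are blank-node labels
    (the builder mints 32-character lowercase hex md5 digests); literal
    values are lexical forms compared lexically (no value-space
    normalization).
    """

    kind: str
    value: str
    datatype: Optional[str] = None
    lang: Optional[str] = None

    def __post_init__(self) -> None:
        if self.kind == "iri":
            if not is_absolute_iri(self.value):
                raise ValueError(f"IRI is not absolute: {self.value!r}")
            if self.datatype or self.lang:
                raise ValueError("IRI node cannot carry datatype/lang")
        elif self.kind == "anon":
            if not _ANON_LABEL_RE.match(self.value):
                raise ValueError(f"invalid blank-node label: {self.value!r}")
            if self.datatype or self.lang:
                raise ValueError("anon node cannot carry datatype/lang")
        elif self.kind == "literal":
            if self.datatype and self.lang:
                raise ValueError("literal cannot have both datatype and lang")
        else:
            raise ValueError(f"unknown node kind: {self.kind!r}")

    @staticmethod
    def iri(value: str) -> "NodeRef":
        return NodeRef("iri", value)

    @staticmethod
    def anon(label: str) -> "NodeRef":
        return NodeRef("anon", label)

    @staticmethod
    def literal(value: str, datatype: Optional[str] = None,
                lang: Optional[str] = None) -> "NodeRef":
        return NodeRef("literal", value, datatype=datatype, lang=lang)

    @property
    def is_named(self) -> bool:
        return self.kind == "iri"


@dataclass(frozen=True)
class Triple:
    """A subject/predicate/object assertion; equality is component-wise."""

    subject: NodeRef
    predicate: NodeRef
    object: NodeRef

    def __post_init__(self) -> None:
        if self.subject.kind == "literal":
            raise ValueError("literal cannot appear in subject position")
        if self.predicate.kind != "iri":
            raise ValueError("predicate must be an IRI")


def triple(s: NodeRef, p: NodeRef, o: NodeRef) -> Triple:
    return Triple(s, p, o)


class TripleGraph:
    """A deduplicated set of triples with a prefix->IRI namespace registry.

    Membership and equality are exact (set semantics). Simple
    subject/predicate indexes back the pattern-matching helpers.
    """

    def __init__(self, triples: Iterable[Triple] = (),
                 namespaces: Optional[dict] = None):
        self._triples: set[Triple] = set()
        self._by_subject: dict[NodeRef, set[Triple]] = {}
        self._by_predicate: dict[NodeRef, set[Triple]] = {}
        self.namespaces: dict[str, str] = dict(namespaces or {})
        for t in triples:
            self.add(t)

    # -- container protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self._triples)

    def __iter__(self) -> Iterator[Triple]:
        return iter(self._triples)

    def __contains__(self, t: Triple) -> bool:
        return t in self._triples

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TripleGraph):
            return NotImplemented
        return self._triples == other._triples

    def __repr__(self) -> str:
        return f"<TripleGraph with {len(self)} triples>"

    # -- mutation -----------------------------------------------------------
    def add(self, t: Triple) -> None:
        if t in self._triples:
            return
        self._triples.add(t)
        self._by_subject.setdefault(t.subject, set()).add(t)
        self._by_predicate.setdefault(t.predicate, set()).add(t)

    def update(self, triples: Iterable[Triple]) -> None:
        for t in triples:
            self.add(t)

    def discard(self, t: Triple) -> None:
        if t not in self._triples:
            return
        self._triples.discard(t)
        self._by_subject[t.subject].discard(t)
        if not self._by_subject[t.subject]:
            del self._by_subject[t.subject]
        self._by_predicate[t.predicate].discard(t)
        if not self._by_predicate[t.predicate]:
            del self._by_predicate[t.predicate]

    def copy(self) -> "TripleGraph":
        return TripleGraph(self._triples, self.namespaces)

    # -- queries ------------------------------------------------------------
    def matching(self, s: Optional[NodeRef] = None, p: Optional[NodeRef] = None,
                 o: Optional[NodeRef] = None) -> Iterator[Triple]:
        """Triples matching the pattern; ``None`` is a wildcard."""
        if s is not None:
            pool: Iterable[Triple] = self._by_subject.get(s, ())
        elif p is not None:
            pool = self._by_predicate.get(p, ())
        else:
            pool = self._triples
        for t in pool:
            if p is not None and t.predicate != p:
                continue
            if o is not None and t.object != o:
                continue
            if s is not None and t.subject != s:
                continue
            yield t

    def objects(self, s: NodeRef, p: NodeRef) -> list[NodeRef]:
        return [t.object for t in self.matching(s=s, p=p)]

    def subjects(self, p: NodeRef, o: NodeRef) -> list[NodeRef]:
        return [t.subject for t in self.matching(p=p, o=o)]

    def terms(self) -> set[NodeRef]:
        """All subject/object terms (predicates excluded)."""
        out: set[NodeRef] = set()
        for t in self._triples:
            out.add(t.subject)
            out.add(t.object)
        return out

    def predicates(self) -> set[NodeRef]:
        return set(self._by_predicate)


# ---------------------------------------------------------------------------
# N-Triples reading
# ---------------------------------------------------------------------------

_IRIREF_RE = re.compile(r'<([^\x00-\x20<>"{}|^`\\]*)>')
_BNODE_RE = re.compile(r"_:([A-Za-z0-9_][A-Za-z0-9_.\-]*)")
_LITERAL_RE = re.compile(r'"((?:[^"\\\n\r]|\\.)*)"')
_LANGTAG_RE = re.compile(r"@([A-Za-z]+(?:-[A-Za-z0-9]+)*)")
_UCHAR_RE = re.compile(r"\\u([0-9A-Fa-f]{4})|\\U([0-9A-Fa-f]{8})")

_SIMPLE_UNESCAPES = {
    "t": "\t", "b": "\b", "n": "\n", "r": "\r", "f": "\f",
    '"': '"', "'": "'", "\\": "\\",
}


def _unescape(raw: str, lineno: int) -> str:
    out = []
    i = 0
    n = len(raw)
    while i < n:
        c = raw[i]
        if c != "\\":
            out.append(c)
            i += 1
            continue
        if i + 1 >= n:
            raise ParseError("dangling backslash in string", lineno)
        e = raw[i + 1]
        if e in _SIMPLE_UNESCAPES:
            out.append(_SIMPLE_UNESCAPES[e])
            i += 2
        elif e == "u":
            m = _UCHAR_RE.match(raw, i)
            if not m:
                raise ParseError("bad \\u escape", lineno)
            out.append(chr(int(m.group(1), 16)))
            i += 6
        elif e == "U":
            m = _UCHAR_RE.match(raw, i)
            if not m:
                raise ParseError("bad \\U escape", lineno)
            out.append(chr(int(m.group(2), 16)))
            i += 10
        else:
            raise ParseError(f"unknown escape \\{e}", lineno)
    return "".join(out)


def _parse_iri(line: str, pos: int, lineno: int) -> tuple[NodeRef, int]:
    m = _IRIREF_RE.match(line, pos)
    if not m:
        raise ParseError(f"expected IRI at column {pos}", lineno)
    raw = _unescape(m.group(1), lineno)
    if not is_absolute_iri(raw):
        raise ParseError(f"relative IRI not allowed: {raw!r}", lineno)
    return NodeRef.iri(raw), m.end()


def _parse_term(line: str, pos: int, lineno: int,
                position: str) -> tuple[NodeRef, int]:
    c = line[pos] if pos < len(line) else ""
    if c == "<":
        return _parse_iri(line, pos, lineno)
    if c == "_":
        if position == "predicate":
            raise ParseError("blank node cannot be a predicate", lineno)
        m = _BNODE_RE.match(line, pos)
        if not m:
            raise ParseError("malformed blank-node label", lineno)
        return NodeRef.anon(m.group(1)), m.end()
    if c == '"':
        if position != "object":
            raise ParseError(f"literal not allowed in {position} position",
                             lineno)
        m = _LITERAL_RE.match(line, pos)
        if not m:
            raise ParseError("malformed literal", lineno)
        value = _unescape(m.group(1), lineno)
        end = m.end()
        if line.startswith("^^", end):
            dt, end = _parse_iri(line, end + 2, lineno)
            return NodeRef.literal(value, datatype=dt.value), end
        mlang = _LANGTAG_RE.match(line, end)
        if mlang:
            return NodeRef.literal(value, lang=mlang.group(1)), mlang.end()
        return NodeRef.literal(value), end
    raise ParseError(f"unexpected character {c!r} at column {pos}", lineno)


def _skip_ws(line: str, pos: int) -> int:
    while pos < len(line) and line[pos] in " \t":
        pos += 1
    return pos


def _parse_line(line: str, lineno: int) -> Optional[Triple]:
    stripped = line.strip()
    if not stripped or stripped.startswith("#"):
        return None
    if not stripped.endswith("."):
        raise ParseError("line does not end with '.'", lineno)
    body = stripped[:-1].rstrip()
    pos = 0
    s, pos = _parse_term(body, _skip_ws(body, pos), lineno, "subject")
    p, pos = _parse_term(body, _skip_ws(body, pos), lineno, "predicate")
    o, pos = _parse_term(body, _skip_ws(body, pos), lineno, "object")
    if _skip_ws(body, pos) != len(body):
        raise ParseError("trailing content after object term", lineno)
    try:
        return Triple(s, p, o)
    except ValueError as exc:  # e.g. literal subject slipped through
        raise ParseError(str(exc), lineno) from exc


def _open_text(path: Union[str, Path], mode: str):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode + "t", encoding="utf-8")
    return open(path, mode, encoding="utf-8")


def parse_ntriples(source) -> TripleGraph:
    """Parse N-Triples from a path (``.gz`` transparently) or text stream.

    Duplicate lines collapse (set semantics); blank-node labels are
    preserved verbatim as anon identifiers. Malformed lines and relative
    IRIs raise :class:`ParseError` citing the line number.
    """
    if isinstance(source, (str, Path)):
        with _open_text(source, "r") as fh:
            return _parse_stream(fh)
    return _parse_stream(source)


def _parse_stream(stream) -> TripleGraph:
    graph = TripleGraph()
    for lineno, line in enumerate(stream, start=1):
        t = _parse_line(line, lineno)
        if t is not None:
            graph.add(t)
    return graph


def loads_ntriples(text: str) -> TripleGraph:
    """Parse N-Triples from an in-memory string."""
    return _parse_stream(io.StringIO(text))


# ---------------------------------------------------------------------------
# N-Triples writing
# ---------------------------------------------------------------------------

def _escape(value: str) -> str:
    out = []
    for c in value:
        if c == "\\":
            out.append("\\\\")
        elif c == '"':
            out.append('\\"')
        elif c == "\n":
            out.append("\\n")
        elif c == "\r":
            out.append("\\r")
        elif c == "\t":
            out.append("\\t")
        elif ord(c) < 0x20:
            out.append(f"\\u{ord(c):04X}")
        else:
            out.append(c)
    return "".join(out)


def format_term(node: NodeRef) -> str:
    if node.kind == "iri":
        return f"<{node.value}>"
    if node.kind == "anon":
        return f"_:{node.value}"
    lex = f'"{_escape(node.value)}"'
    if node.datatype:
        return f"{lex}^^<{node.datatype}>"
    if node.lang:
        return f"{lex}@{node.lang}"
    return lex


def format_triple(t: Triple) -> str:
    return (f"{format_term(t.subject)} {format_term(t.predicate)} "
            f"{format_term(t.object)} .")


def dumps_ntriples(graph: TripleGraph) -> str:
    """Canonical serialization: sorted lines, deterministic bytes."""
    lines = sorted(format_triple(t) for t in graph)
    if not lines:
        return ""
    return "\n".join(lines) + "\n"


def serialize_ntriples(graph: TripleGraph, dest=None) -> Optional[str]:
    """Serialize canonically; to a path (``.gz`` aware), a stream, or a
    returned string when *dest* is ``None``."""
    text = dumps_ntriples(graph)
    if dest is None:
        return text
    if isinstance(dest, (str, Path)):
        with _open_text(dest, "w") as fh:
            fh.write(text)
        return None
    dest.write(text)
    return None


# ---------------------------------------------------------------------------
# Graph algebra
# ---------------------------------------------------------------------------

def merge_graphs(graphs: Sequence[TripleGraph]) -> TripleGraph:
    """Set union of triple sets; namespace maps merge first-wins.

    A prefix bound to two different IRIs logs a warning and keeps the
    first binding. Union is associative, commutative and idempotent.
    """
    merged = TripleGraph()
    for g in graphs:
        merged.update(g)
        for prefix, ns in g.namespaces.items():
            if prefix in merged.namespaces and merged.namespaces[prefix] != ns:
                logger.warning(
                    "prefix %r bound to %r and %r; keeping first",
                    prefix, merged.namespaces[prefix], ns)
                continue
            merged.namespaces.setdefault(prefix, ns)
    return merged


_RDF_NIL = NodeRef.iri(vocab.RDF_NIL)
_RDF_FIRST = NodeRef.iri(vocab.RDF_FIRST)
_RDF_REST = NodeRef.iri(vocab.RDF_REST)


def decode_rdf_list(graph: TripleGraph, head: NodeRef) -> list[NodeRef]:
    """Walk an rdf:first/rdf:rest chain, returning members in order.

    ``rdf:nil`` decodes to the empty sequence. A missing/ambiguous
    rdf:first or rdf:rest, or a cycle, raises :class:`MalformedListError`
    naming the head node.
    """
    members: list[NodeRef] = []
    seen: set[NodeRef] = set()
    node = head
    while node != _RDF_NIL:
        if node in seen:
            raise MalformedListError(f"cyclic RDF list at {head}")
        seen.add(node)
        firsts = graph.objects(node, _RDF_FIRST)
        rests = graph.objects(node, _RDF_REST)
        if len(firsts) != 1 or len(rests) != 1:
            raise MalformedListError(
                f"malformed RDF list at head {head}: node {node} has "
                f"{len(firsts)} rdf:first and {len(rests)} rdf:rest")
        members.append(firsts[0])
        node = rests[0]
    return members


def list_cell_triples(graph: TripleGraph, head: NodeRef) -> set[Triple]:
    """All rdf:first/rdf:rest triples making up a well-formed list."""
    cells: set[Triple] = set()
    seen: set[NodeRef] = set()
    node = head
    while node != _RDF_NIL and node not in seen:
        seen.add(node)
        nxt = None
        for t in graph.matching(s=node):
            if t.predicate in (_RDF_FIRST, _RDF_REST):
                cells.add(t)
                if t.predicate == _RDF_REST:
                    nxt = t.object
        if nxt is None:
            break
        node = nxt
    return cells
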