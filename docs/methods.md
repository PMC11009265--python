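# Methods

## The construction procedure

A build runs a fixed pipeline:

1. **Clean** each input ontology (N-Triples) with the check registry
   below and record a balancing report.
2. **Merge** the cleaned ontologies into one core ontology by set union
   of triples (namespace prefixes merge first-wins, conflicts logged).
3. **Assemble** per-edge-type lists from delimited tables:
   parse → filter (conjunctive clauses) → map subject identifiers →
   map object identifiers → project to (subject, object) → deduplicate
   preserving first occurrence. Provenance records the row count after
   every stage; counts only grow at identifier mapping, where a
   one-to-many map unnests a row into one row per target.
4. **Anchor** every non-ontology entity under its anchor class
   (class model: `rdf:type owl:Class` + `rdfs:subClassOf`; instance
   model: `rdf:type owl:NamedIndividual` + `rdf:type anchor`), exactly
   once per entity. A missing anchor aborts the build listing every
   unanchored entity.
5. **Expand relations** per the strategy. Under the inverse strategy an
   invertible relation adds `(o, r⁻¹, s)`, a symmetric edge type adds
   `(o, r, s)`, and an inverse-less relation adds nothing. Expansion
   deduplicates, so a source that already contains reciprocal pairs is
   not double-counted — doubling is exact precisely when the source has
   no reciprocals, which the synthetic generator guarantees by sampling
   ordered pairs with `i < j`.
6. **Materialize** each assertion (4-triple restriction pattern in the
   class model; direct assertion between individuals in the instance
   model).
7. **Abstract** (optional) and **serialize** canonically.

### Deterministic minting

Edge restriction nodes are named by
`md5((s + "subject") ‖ r ‖ (o + "object"))`, concatenated in that fixed
order with no separator; class-proxy individuals by `md5(class IRI)`.
The concatenation order is pinned here and covered by an independent
md5 oracle in the tests. Minted identifiers are 32-character lowercase
hex blank-node labels; the associated mint namespace is a configurable
IRI prefix (default `https://example.org/kgweave/pkt/`) registered in
the graph's prefix map.

### Instance-model proxies

Anchored data entities act as their own individuals. Each ontology
class that participates in an edge gets **one** reusable minted
individual (typed once), rather than one per edge. This keeps instance
builds strictly smaller than class builds on the same inputs — the
ordering benchmark releases report — whereas per-edge individuals would
invert it. During abstraction the proxy is resolved back to its class,
which is what makes the instance-model round trip exact.

## Canonical N-Triples

N-Triples is the only interchange syntax; other RDF serializations are
a conversion concern outside this package. Serialization is canonical:
one triple per line, lines sorted lexicographically, fixed escaping —
so equal graphs serialize byte-identically across runs and hosts, and
`parse(serialize(G)) == G` including verbatim blank-node labels (a
parser that relabels blank nodes would break rebuild determinism, which
is why the reader/writer is implemented here; rdflib serves as an
independent parser oracle in the tests). Literal equality is lexical:
`"1.0"` and `"1.00"` are distinct. Relative IRIs are rejected at parse
time with the line number.

## Ontology cleaning

The check registry is fixed and extensible, applied in order:

1. **Deprecated-class removal** — every class annotated
   `owl:deprecated "true"` is removed with *all* triples mentioning it.
   No rewiring of subclass chains around the removed class: deletion is
   the simplest auditable semantics.
2. **Malformed-IRI removal** — triples carrying an IRI that fails
   strict validation (missing scheme, embedded whitespace or reserved
   characters) are dropped.
3. **Dangling-reference audit** (report-only) — subclass/equivalence
   targets never declared as classes.
4. **Duplicate-label audit** (report-only) — label strings shared by
   more than one IRI.

The report balances exactly
(`after = before − removed + added`; the built-in checks never add
triples, but the registry admits repair-style checks that do). The two
mutating checks are idempotent — a second pass removes nothing — while
the audits re-report the same counts on an unchanged graph. Label
conflicts during metadata extraction resolve to the lexicographically
first label, deterministic regardless of input order.
Description-logic reasoning is out of scope; the registry is the hook
where a reasoner-backed consistency check could be added.

## Semantic abstraction

Abstraction classifies every input triple into exactly one category —
retained, decoded source, or dropped (per construct) — and asserts
`retained + decoded_source + Σ dropped = input` after every run.

* A restriction decodes when it has exactly one named `owl:onProperty`
  value, a named filler under `owl:someValuesFrom`/`owl:allValuesFrom`
  (or `owl:onClass` for qualified cardinality, which preserves the
  relation signal; unqualified cardinality is loss-logged), and a named
  attached subject via `rdfs:subClassOf` or `owl:equivalentClass`.
* `owl:intersectionOf`/`owl:unionOf` collections attached to a named
  class are walked via the rdf:first/rest chain: named members become
  `rdfs:subClassOf` edges of the attached class, restriction members
  decode against it. Union members are treated identically to
  intersection members — a deliberate lossy choice (exact union
  semantics cannot be expressed in a hybrid graph anyway).
* Annotation triples (labels, synonyms, definitions, comments, any
  literal object) are routed to node metadata, not the graph.
* Negation (`owl:complementOf`, `owl:disjointWith`) is dropped and
  loss-logged: abstraction deliberately trades logical expressivity for
  a graph that network algorithms can consume.
* `owl:equivalentClass` between two named classes is retained as an
  edge; dropping it would disconnect cross-ontology bridges.
* Anonymous nodes typed by a named non-OWL class are treated as class
  proxies and substituted by their class in relation triples.

The output graph contains no anonymous nodes and no OWL-scaffold
predicates, and is never larger than its source on builder-generated
inputs.

**Harmonization** rewrites `rdf:type → rdfs:subClassOf` (class model)
or `rdfs:subClassOf → rdf:type` (instance model) and deduplicates; it
is idempotent and non-increasing. Class-model hybrids built over
OBO-style inputs contain no `rdf:type` triples (entity typings all hit
OWL built-in classes, which are dropped), so class harmonization is a
no-op there — the tests pin this structural fact.

## Graph statistics

* `n` = distinct subject/object terms excluding literals, anonymous
  nodes included; `m` = triple count; relations = distinct predicates.
* average degree ≡ `m/n`, rounded to 2 decimals. The published
  benchmark tables this definition was checked against are reproduced
  cell-for-cell by `m/n` (e.g. 4,044,658 / 1,399,756 → 2.89), which
  rules out the undirected `2m/n` convention.
* density ≡ `m/(n(n−1))`, the directed simple-graph formula, reported
  to 3 significant figures; an empty or single-node graph reports 0.
* Connected components are counted on the undirected projection
  ignoring predicates (networkx), cross-checked by a hand-written
  union-find oracle in the tests.

## The synthetic generator

`kgweave.fixtures` emulates the *mechanics* of real inputs, not their
biology: OBO-style ontologies (rooted subclass DAG, labels/synonyms/
definitions on every class, some all-some restrictions, deprecated
leaf classes), edge tables with seeded duplicate rows, unmappable
identifiers, one-to-many map entries (every 7th subject token), one
numerically filtered edge type, and invertible/symmetric/inverse-less
edge-type roles. Defaults (20 classes, 3 edge types, 30 edges per
type, 10% duplicates, 10% unmapped) keep a full 12-variant matrix in
the hundreds-of-triples range so the whole matrix builds in seconds;
the acceptance checks that exercise published edge-set sizes (167,681
pairs) run the expansion machinery at full scale instead. Ground truth
(expected unique pairs, seeded drop counts) is computed by an
independent brute-force walk over the emitted rows and shipped with
the bundle, so downstream checks never derive their oracle from the
code under test.

What passing tests therefore show: the construction, expansion,
abstraction and accounting machinery is exact on inputs with the real
inputs' structure. What they do not show: behavior on real ontologies'
scale, degree distributions, or annotation idiosyncrasies beyond the
defect classes modeled here.

## Known limitations

* No reasoner integration: inconsistencies survive cleaning.
* Filter grammar is conjunction-only; disjunction is expressed through
  the `in` operator.
* Tabular sources are delimited text (± gzip); other formats must be
  pre-converted.
* Abstraction is lossy by design and cannot be inverted back to OWL.
* The cleaning registry fixes four checks; real ontology repair
  pipelines apply many more.
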