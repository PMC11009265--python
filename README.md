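# kgweave

Deterministic construction of biomedical knowledge graphs from OWL
ontologies and tabular edge sources.

Heterogeneous biomedical mechanisms — chemicals treating diseases,
variants influencing genes, proteins participating in pathways — are
naturally modeled as a knowledge graph (KG) over the OBO Foundry
ontologies: RDF triples ⟨subject, predicate, object⟩ connecting ontology
classes and database entities. How those triples are *represented* is a
modeling decision with real downstream consequences, and kgweave makes
that decision explicit and reproducible. It is aimed at computational
biologists who need mechanistic KG benchmarks whose representation they
control, and who want the same inputs to rebuild byte-for-byte.

## The model

A KG is a Description Logics knowledge base **K = ⟨T, A⟩** (TBox +
ABox). Three independent parameters select one of **12 build variants**:

1. **Knowledge model.**
   *Class-based*: each database entity `E` with anchor ontology class
   `A` is added as `E rdfs:subClassOf A`, and each edge `(s, r, o)` is
   encoded as an anonymous all-some restriction —
   `s rdfs:subClassOf [owl:Restriction; owl:onProperty r;
   owl:someValuesFrom o]` (4 triples/edge).
   *Instance-based*: entities are typed individuals and each edge is a
   single direct assertion between individuals, with one reusable
   minted individual standing for each participating ontology class.
2. **Relation strategy.** *Standard* asserts each directed pair once;
   *inverse* additionally asserts the Relation-Ontology inverse
   `(o, r⁻¹, s)`, or the symmetric reciprocal `(o, r, s)` for
   interaction-type edges; relations without an inverse stay directed.
3. **Semantic abstraction.** *None* keeps the full OWL encoding;
   *OWL-NETS* decodes every restriction back into a direct edge and
   drops the OWL scaffolding with exact per-construct accounting;
   *harmonization* ("purification") additionally rewrites
   `rdf:type` ↔ `rdfs:subClassOf` to match the knowledge model.

Anonymous nodes are minted deterministically as the md5 hex digest of
`(s + "subject") ‖ r ‖ (o + "object")`, so identical inputs always
rebuild identical graphs. Every build emits descriptive statistics:
n nodes, m triples, relations, self-loops, average degree m/n, density
m/(n(n−1)), and connected components.

## Worked example

No downloads are needed: the `kgweave.fixtures` module generates
complete synthetic input bundles (toy ontologies, edge tables,
identifier/anchor/relation maps) with ground truth. Running
`python examples/04_semantic_abstraction.py` builds a class-based KG
with inverse relations and abstracts it:

```
complex OWL graph:     947 triples
hybrid graph:          245 triples
restrictions decoded:  159
dropped by construct:  {'annotations': 147, 'owl_declarations': 78}
asserted edges:        149
recovered exactly:     True
harmonized (class):    245 triples (no-op: True)
```

The 149 asserted edges (here 947-triple OWL graph → 245-triple hybrid)
survive the OWL round trip *exactly*; class-model hybrids contain no
`rdf:type` triples, so class harmonization is a no-op — a structural
property of class-based builds over OBO-style ontologies. The other
examples build a single variant (`01`), the full 12-variant matrix
(`02`) and an edge list with filters, identifier unnesting and
provenance (`03`).

The same functionality is available from the shell:

```bash
kgweave demo --out demo --seed 5 --all-variants
kgweave build --config demo/fixture/config.yaml \
    --knowledge-model instance --relation-strategy inverse \
    --abstraction owlnets --out build/
kgweave stats build/kg_instance_inverse_owlnets.nt
```

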