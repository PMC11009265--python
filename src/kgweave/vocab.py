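"""Well-known RDF/RDFS/OWL vocabulary IRIs used across the package."""

RDF = "http://www.w3.org/1999/02/22-rdf-syntax-ns#"
RDFS = "http://www.w3.org/2000/01/rdf-schema#"
OWL = "http://www.w3.org/2002/07/owl#"
XSD = "http://www.w3.org/2001/XMLSchema#"
OBO = "http://purl.obolibrary.org/obo/"
OBOINOWL = "http://www.geneontology.org/formats/oboInOwl#"

RDF_TYPE = RDF + "type"
RDF_FIRST = RDF + "first"
RDF_REST = RDF + "rest"
RDF_NIL = RDF + "nil"

RDFS_SUBCLASSOF = RDFS + "subClassOf"
RDFS_LABEL = RDFS + "label"
RDFS_COMMENT = RDFS + "comment"
RDFS_SUBPROPERTYOF = RDFS + "subPropertyOf"
RDFS_DOMAIN = RDFS + "domain"
RDFS_RANGE = RDFS + "range"

OWL_CLASS = OWL + "Class"
OWL_RESTRICTION = OWL + "Restriction"
OWL_NAMED_INDIVIDUAL = OWL + "NamedIndividual"
OWL_OBJECT_PROPERTY = OWL + "ObjectProperty"
OWL_ANNOTATION_PROPERTY = OWL + "AnnotationProperty"
OWL_DATATYPE_PROPERTY = OWL + "DatatypeProperty"
OWL_ONTOLOGY = OWL + "Ontology"
OWL_THING = OWL + "Thing"

OWL_ON_PROPERTY = OWL + "onProperty"
OWL_SOME_VALUES_FROM = OWL + "someValuesFrom"
OWL_ALL_VALUES_FROM = OWL + "allValuesFrom"
OWL_HAS_VALUE = OWL + "hasValue"
OWL_ON_CLASS = OWL + "onClass"
OWL_MIN_CARDINALITY = OWL + "minCardinality"
OWL_MAX_CARDINALITY = OWL + "maxCardinality"
OWL_CARDINALITY = OWL + "cardinality"
OWL_QUALIFIED_CARDINALITY = OWL + "qualifiedCardinality"
OWL_MIN_QUALIFIED_CARDINALITY = OWL + "minQualifiedCardinality"
OWL_MAX_QUALIFIED_CARDINALITY = OWL + "maxQualifiedCardinality"

OWL_INTERSECTION_OF = OWL + "intersectionOf"
OWL_UNION_OF = OWL + "unionOf"
OWL_COMPLEMENT_OF = OWL + "complementOf"
OWL_ONE_OF = OWL + "oneOf"
OWL_DISJOINT_WITH = OWL + "disjointWith"
OWL_INVERSE_OF = OWL + "inverseOf"
OWL_EQUIVALENT_CLASS = OWL + "equivalentClass"
OWL_DEPRECATED = OWL + "deprecated"

XSD_BOOLEAN = XSD + "boolean"
XSD_STRING = XSD + "string"
XSD_INTEGER = XSD + "integer"

# Annotation properties routed to node metadata rather than the graph.
OBO_EXACT_SYNONYM = OBOINOWL + "hasExactSynonym"
OBO_RELATED_SYNONYM = OBOINOWL + "hasRelatedSynonym"
OBO_BROAD_SYNONYM = OBOINOWL + "hasBroadSynonym"
OBO_NARROW_SYNONYM = OBOINOWL + "hasNarrowSynonym"
OBO_DB_XREF = OBOINOWL + "hasDbXref"
OBO_ID = OBOINOWL + "id"
IAO_DEFINITION = OBO + "IAO_0000115"

ANNOTATION_PREDICATES = frozenset({
    RDFS_LABEL,
    RDFS_COMMENT,
    OBO_EXACT_SYNONYM,
    OBO_RELATED_SYNONYM,
    OBO_BROAD_SYNONYM,
    OBO_NARROW_SYNONYM,
    OBO_DB_XREF,
    OBO_ID,
    IAO_DEFINITION,
    OWL_DEPRECATED,
})

# OWL built-in classes that carry no biological meaning as edge targets.
OWL_BUILTIN_CLASSES = frozenset({
    OWL_CLASS,
    OWL_RESTRICTION,
    OWL_NAMED_INDIVIDUAL,
    OWL_OBJECT_PROPERTY,
    OWL_ANNOTATION_PROPERTY,
    OWL_DATATYPE_PROPERTY,
    OWL_ONTOLOGY,
    OWL_THING,
})

# Predicates that are pure OWL scaffolding: they never survive semantic
# abstraction into the hybrid (property-graph-like) output.
OWL_FILTER_PREDICATES = frozenset({
    OWL_ON_PROPERTY,
    OWL_SOME_VALUES_FROM,
    OWL_ALL_VALUES_FROM,
    OWL_HAS_VALUE,
    OWL_ON_CLASS,
    OWL_MIN_CARDINALITY,
    OWL_MAX_CARDINALITY,
    OWL_CARDINALITY,
    OWL_QUALIFIED_CARDINALITY,
    OWL_MIN_QUALIFIED_CARDINALITY,
    OWL_MAX_QUALIFIED_CARDINALITY,
    OWL_INTERSECTION_OF,
    OWL_UNION_OF,
    OWL_COMPLEMENT_OF,
    OWL_ONE_OF,
    OWL_DISJOINT_WITH,
    OWL_INVERSE_OF,
    RDF_FIRST,
    RDF_REST,
})

# Default namespace under which deterministic anonymous nodes are minted.
DEFAULT_MINT_NAMESPACE = "https://example.org/kgweave/pkt/"
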