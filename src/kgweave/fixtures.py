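"""Deterministic synthetic inputs for the full build pipeline.

The generator emulates the shape of the real inputs — OBO-style
ontologies (a rooted subclass DAG with labels, synonyms, definitions,
some all-some restrictions, and a few deprecated classes), tabular
edge sources with duplicate and unmappable rows, identifier maps,
entity-anchor maps and a relation inverse map — while staying tiny
enough that all 12 build variants run in seconds. It emits ground
truth (expected unique pairs, seeded duplicate/unmapped/filtered row
counts) computed by an independent brute-force walk over the emitted
rows, so downstream checks never re-derive their oracle from the code
under test.

Generation is a pure function of :class:`FixtureParams`; a fixed seed
reproduces byte-identical files.
"""

from __future__ import annotations

import gzip
import json
import random
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

from . import vocab
from .builder import RelationMap, mint_edge_node
from .edges import EdgeList, EdgeSpec, FilterClause
from .ontology import ConfigurationError
from .rdf import NodeRef, Triple, TripleGraph, serialize_ntriples

CLASS_NS = "https://example.org/onto/"
ONTO_REL_NS = "https://example.org/rel/onto/"
EDGE_REL_NS = "https://example.org/rel/edge/"
DATA_NS = "https://example.org/data/"

_RDF_TYPE = NodeRef.iri(vocab.RDF_TYPE)
_RDFS_SUBCLASSOF = NodeRef.iri(vocab.RDFS_SUBCLASSOF)
_RDFS_LABEL = NodeRef.iri(vocab.RDFS_LABEL)
_OWL_CLASS = NodeRef.iri(vocab.OWL_CLASS)
_OWL_OBJECT_PROPERTY = NodeRef.iri(vocab.OWL_OBJECT_PROPERTY)
_OWL_RESTRICTION = NodeRef.iri(vocab.OWL_RESTRICTION)
_OWL_ON_PROPERTY = NodeRef.iri(vocab.OWL_ON_PROPERTY)
_OWL_SOME = NodeRef.iri(vocab.OWL_SOME_VALUES_FROM)
_OWL_DEPRECATED = NodeRef.iri(vocab.OWL_DEPRECATED)
_SYNONYM = NodeRef.iri(vocab.OBO_EXACT_SYNONYM)
_DEFINITION = NodeRef.iri(vocab.IAO_DEFINITION)


@dataclass(frozen=True)
class FixtureParams:
    """Knobs of the synthetic study system.

    ``subclass_density`` is the probability that a class receives a
    second parent (every non-root class has at least one, giving a
    rooted DAG). ``duplicate_fraction`` / ``unmapped_fraction`` seed
    redundant rows and rows whose identifier is absent from the
    identifier map. The first ``invertible_types`` edge types get a
    Relation-Ontology-style inverse, the next ``symmetric_types`` are
    symmetric interaction types, and the rest are inverse-less.
    """

    n_classes: int = 20
    subclass_density: float = 0.3
    n_restrictions: int = 5
    n_deprecated: int = 2
    n_edge_types: int = 3
    edges_per_type: int = 30
    duplicate_fraction: float = 0.1
    unmapped_fraction: float = 0.1
    symmetric_types: int = 1
    invertible_types: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_classes", "n_restrictions", "n_deprecated",
                     "n_edge_types", "edges_per_type", "symmetric_types",
                     "invertible_types"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be non-negative")
        for name in ("subclass_density", "duplicate_fraction",
                     "unmapped_fraction"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1]")
        if self.n_deprecated >= self.n_classes:
            raise ConfigurationError("n_deprecated must be < n_classes")
        if self.symmetric_types + self.invertible_types > self.n_edge_types:
            raise ConfigurationError(
                "symmetric_types + invertible_types exceeds n_edge_types")


def _class_iri(tag: str, i: int) -> str:
    return f"{CLASS_NS}{tag}_{i:07d}"


def gen_toy_ontology(params: FixtureParams, tag: str = "TOYA",
                     seed_offset: int = 0) -> TripleGraph:
    """One OBO-style toy ontology, a pure function of (params, tag).

    Emits ``n_classes`` named classes in a rooted subclass DAG,
    ``n_restrictions`` all-some restriction patterns over a small
    ontology-internal relation vocabulary, ``n_deprecated`` classes
    annotated ``owl:deprecated "true"``, and a label, definition and
    two exact synonyms on every class. Deprecated classes are leaves
    that no restriction touches, so cleaning removes exactly their own
    axioms.
    """
    rng = random.Random((params.seed + seed_offset) % (2**31))
    g = TripleGraph(namespaces={
        tag.lower(): CLASS_NS, "rel": ONTO_REL_NS,
        "owl": vocab.OWL, "rdfs": vocab.RDFS,
    })

    classes = [NodeRef.iri(_class_iri(tag, i))
               for i in range(params.n_classes)]
    n_live = params.n_classes - params.n_deprecated
    live = classes[:n_live]
    deprecated = classes[n_live:]

    relations = [NodeRef.iri(f"{ONTO_REL_NS}R{j}") for j in range(3)]
    for j, r in enumerate(relations):
        g.add(Triple(r, _RDF_TYPE, _OWL_OBJECT_PROPERTY))
        g.add(Triple(r, _RDFS_LABEL,
                     NodeRef.literal(f"toy relation {j}", lang="en")))

    for i, c in enumerate(classes):
        g.add(Triple(c, _RDF_TYPE, _OWL_CLASS))
        g.add(Triple(c, _RDFS_LABEL,
                     NodeRef.literal(f"{tag} class {i}", lang="en")))
        g.add(Triple(c, _DEFINITION,
                     NodeRef.literal(f"The {i}th synthetic {tag} class.")))
        g.add(Triple(c, _SYNONYM, NodeRef.literal(f"{tag}-{i}")))
        g.add(Triple(c, _SYNONYM, NodeRef.literal(f"{tag} synonym {i}")))
        if i > 0:
            parent_pool = live[:i] if i < n_live else live
            parent = rng.choice(parent_pool)
            g.add(Triple(c, _RDFS_SUBCLASSOF, parent))
            if rng.random() < params.subclass_density and i >= 2:
                extra = rng.choice(parent_pool)
                g.add(Triple(c, _RDFS_SUBCLASSOF, extra))

    if params.n_restrictions and n_live >= 2:
        chosen: set[tuple[str, str, str]] = set()
        n_wanted = min(params.n_restrictions, n_live * (n_live - 1) * 3)
        while len(chosen) < n_wanted:
            s = rng.choice(live)
            o = rng.choice(live)
            if s == o:
                continue
            r = rng.choice(relations)
            chosen.add((s.value, r.value, o.value))
        for s_iri, r_iri, o_iri in sorted(chosen):
            b = mint_edge_node(s_iri, r_iri, o_iri)
            g.add(Triple(NodeRef.iri(s_iri), _RDFS_SUBCLASSOF, b))
            g.add(Triple(b, _RDF_TYPE, _OWL_RESTRICTION))
            g.add(Triple(b, _OWL_ON_PROPERTY, NodeRef.iri(r_iri)))
            g.add(Triple(b, _OWL_SOME, NodeRef.iri(o_iri)))

    for c in deprecated:
        g.add(Triple(c, _OWL_DEPRECATED,
                     NodeRef.literal("true", datatype=vocab.XSD_BOOLEAN)))
    return g


@dataclass
class Fixture:
    """A complete in-memory input bundle plus its ground truth."""

    params: FixtureParams
    ontologies: list[TripleGraph]
    rows: dict[str, list[dict]]
    specs: list[EdgeSpec]
    idmap: dict[str, tuple[str, ...]]
    anchors: dict[str, str]
    relmap: RelationMap
    ground_truth: dict[str, dict]

    @property
    def core_ontology(self) -> TripleGraph:
        from .rdf import merge_graphs

        return merge_graphs(self.ontologies)

    def expected_edge_lists(self) -> list[EdgeList]:
        """Edge lists as the ground-truth brute force predicts them."""
        out = []
        for spec in self.specs:
            gt = self.ground_truth[spec.edge_type]
            out.append(EdgeList(
                edge_type=spec.edge_type,
                relation=spec.relation,
                inverse_relation=spec.inverse_relation,
                symmetric=spec.symmetric,
                pairs=[tuple(p) for p in gt["expected_pairs"]],
                provenance={"source": "ground_truth"},
            ))
        return out


def _edge_type_role(params: FixtureParams, index: int) -> str:
    if index < params.invertible_types:
        return "invertible"
    if index < params.invertible_types + params.symmetric_types:
        return "symmetric"
    return "inverse_less"


def gen_fixture(params: FixtureParams) -> Fixture:
    """Generate the whole bundle: two overlapping toy ontologies, per-type
    edge tables with seeded duplicates/unmapped rows, identifier and
    anchor maps, a relation map, and brute-force ground truth."""
    rng = random.Random(params.seed % (2**31))
    onto_a = gen_toy_ontology(params, tag="TOYA", seed_offset=0)
    onto_b = gen_toy_ontology(params, tag="TOYB", seed_offset=1)

    n_live = params.n_classes - params.n_deprecated
    anchorable = [_class_iri("TOYA", i) for i in range(n_live)]

    idmap: dict[str, tuple[str, ...]] = {}
    anchors: dict[str, str] = {}
    inverses: dict[str, str] = {}
    symmetric: set[str] = set()
    rows: dict[str, list[dict]] = {}
    specs: list[EdgeSpec] = []
    ground_truth: dict[str, dict] = {}

    for k in range(params.n_edge_types):
        edge_type = f"et{k}"
        role = _edge_type_role(params, k)
        relation = f"{EDGE_REL_NS}{edge_type}"
        inverse_relation = None
        if role == "invertible":
            inverse_relation = f"{EDGE_REL_NS}inverse_of_{edge_type}"
            inverses[relation] = inverse_relation
            inverses[inverse_relation] = relation
        elif role == "symmetric":
            symmetric.add(relation)

        n_pairs = params.edges_per_type
        base_pairs: list[tuple[str, str]]
        if role == "symmetric":
            # entity-entity, i < j: no self-pairs, no reciprocals
            pool = max(4, int((2 * n_pairs) ** 0.5) + 3)
            combos = [(i, j) for i in range(pool) for j in range(pool)
                      if i < j]
            picked = rng.sample(combos, min(n_pairs, len(combos)))
            base_pairs = [(f"G{k}_{i}", f"G{k}_{j}") for i, j in picked]
        else:
            # entity -> ontology class
            n_subjects = max(3, n_pairs // 2)
            combos = [(i, j) for i in range(n_subjects)
                      for j in range(len(anchorable))]
            picked = rng.sample(combos, min(n_pairs, len(combos)))
            base_pairs = [(f"S{k}_{i}", f"O{j}") for i, j in picked]

        # identifier map entries (subjects one-to-many every 7th token)
        for raw_s, raw_o in base_pairs:
            if raw_s not in idmap:
                iri = f"{DATA_NS}{edge_type}/{raw_s}"
                targets = [iri]
                if raw_s.startswith(("S", "G")) and _token_index(raw_s) % 7 == 6:
                    targets.append(iri + "b")
                idmap[raw_s] = tuple(sorted(targets))
                for t in targets:
                    anchors[t] = rng.choice(anchorable)
            if raw_o not in idmap:
                if raw_o.startswith("O"):
                    idmap[raw_o] = (anchorable[int(raw_o[1:])],)
                else:
                    iri = f"{DATA_NS}{edge_type}/{raw_o}"
                    idmap[raw_o] = (iri,)
                    anchors[iri] = rng.choice(anchorable)

        table = [{
            "subject_id": s, "object_id": o,
            "score": f"{rng.uniform(0.0, 1.0):.3f}",
            "evidence": rng.choice(["exp", "pred", "curated"]),
        } for s, o in base_pairs]

        n_unmapped = round(params.unmapped_fraction * len(base_pairs))
        for u in range(n_unmapped):
            table.append({
                "subject_id": f"UNMAPPED_{edge_type}_{u}",
                "object_id": base_pairs[u % len(base_pairs)][1],
                "score": f"{rng.uniform(0.3, 1.0):.3f}",
                "evidence": "exp",
            })

        n_duplicates = round(params.duplicate_fraction * len(base_pairs))
        for d in range(n_duplicates):
            table.append(dict(table[d % len(base_pairs)]))

        rng.shuffle(table)

        filters: tuple[FilterClause, ...] = ()
        if k == 0:
            filters = (FilterClause("score", ">=", 0.25,
                                    value_type="number"),)

        spec = EdgeSpec(
            edge_type=edge_type,
            source_path=(f"edges_{edge_type}.tsv.gz"
                         if k == params.n_edge_types - 1 and k > 0
                         else f"edges_{edge_type}.tsv"),
            subject_column="subject_id",
            object_column="object_id",
            relation=relation,
            symmetric=(role == "symmetric"),
            filters=filters,
            subject_map="idmap.tsv",
            object_map="idmap.tsv",
        )
        specs.append(spec)
        rows[edge_type] = table

        # --- brute-force ground truth over the emitted rows -------------
        expected_pairs: list[tuple[str, str]] = []
        seen: set[tuple[str, str]] = set()
        n_filtered = n_unmapped_seen = 0
        for row in table:
            if filters and float(row["score"]) < 0.25:
                n_filtered += 1
                continue
            if row["subject_id"] not in idmap or row["object_id"] not in idmap:
                n_unmapped_seen += 1
                continue
            for s_iri in idmap[row["subject_id"]]:
                for o_iri in idmap[row["object_id"]]:
                    pair = (s_iri, o_iri)
                    if pair not in seen:
                        seen.add(pair)
                        expected_pairs.append(pair)

        n_std = len(expected_pairs)
        expected_inverse = n_std if role == "inverse_less" else 2 * n_std
        ground_truth[edge_type] = {
            "role": role,
            "relation": relation,
            "inverse_relation": inverse_relation,
            "expected_pairs": [list(p) for p in expected_pairs],
            "n_rows_emitted": len(table),
            "n_duplicate_rows": n_duplicates,
            "n_unmapped_rows": n_unmapped,
            "n_filtered_rows": n_filtered,
            "expected_standard_assertions": n_std,
            "expected_inverse_assertions": expected_inverse,
        }

    relmap = RelationMap(inverses=inverses, symmetric=symmetric)
    return Fixture(
        params=params,
        ontologies=[onto_a, onto_b],
        rows=rows,
        specs=specs,
        idmap=idmap,
        anchors=anchors,
        relmap=relmap,
        ground_truth=ground_truth,
    )


def _token_index(token: str) -> int:
    return int(token.rsplit("_", 1)[-1])


def write_fixture_bundle(fixture: Fixture, directory) -> Path:
    """Serialize a fixture to disk: ontology .nt files, edge TSVs (one
    gzipped when several types exist), specs YAML, maps TSV, ground
    truth JSON and a ready-to-run build config. Returns the directory."""
    import yaml

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)

    serialize_ntriples(fixture.ontologies[0], directory / "ontology_a.nt")
    serialize_ntriples(fixture.ontologies[1], directory / "ontology_b.nt")

    for spec in fixture.specs:
        table = fixture.rows[spec.edge_type]
        header = "subject_id\tobject_id\tscore\tevidence"
        body = "\n".join(
            f"{r['subject_id']}\t{r['object_id']}\t{r['score']}"
            f"\t{r['evidence']}" for r in table)
        text = header + ("\n" + body if body else "") + "\n"
        path = directory / spec.source_path
        if path.suffix == ".gz":
            with gzip.open(path, "wt", encoding="utf-8") as fh:
                fh.write(text)
        else:
            path.write_text(text, encoding="utf-8")

    (directory / "idmap.tsv").write_text(
        "".join(f"{src}\t{dst}\n"
                for src in sorted(fixture.idmap)
                for dst in fixture.idmap[src]),
        encoding="utf-8")
    (directory / "anchor_map.tsv").write_text(
        "".join(f"{e}\t{a}\n" for e, a in sorted(fixture.anchors.items())),
        encoding="utf-8")

    rel_lines = [f"{r}\t{inv}" for r, inv in sorted(
        fixture.relmap.inverses.items())]
    rel_lines += [f"{r}\t{r}" for r in sorted(fixture.relmap.symmetric)]
    (directory / "relation_map.tsv").write_text(
        "\n".join(rel_lines) + "\n", encoding="utf-8")

    spec_docs = []
    for spec in fixture.specs:
        doc = {
            "edge_type": spec.edge_type,
            "source_path": spec.source_path,
            "subject_column": spec.subject_column,
            "object_column": spec.object_column,
            "relation": spec.relation,
            "symmetric": spec.symmetric,
            "subject_map": spec.subject_map,
            "object_map": spec.object_map,
        }
        if spec.inverse_relation:
            doc["inverse_relation"] = spec.inverse_relation
        if spec.filters:
            doc["filters"] = [{
                "column": c.column, "operator": c.operator,
                "value": c.value, "value_type": c.value_type,
            } for c in spec.filters]
        spec_docs.append(doc)
    (directory / "edge_specs.yaml").write_text(
        yaml.safe_dump({"edges": spec_docs}, sort_keys=False),
        encoding="utf-8")

    (directory / "ground_truth.json").write_text(
        json.dumps(fixture.ground_truth, indent=2, sort_keys=True) + "\n",
        encoding="utf-8")

    config = {
        "knowledge_model": "class_based",
        "relation_strategy": "standard",
        "abstraction": "none",
        "ontology_paths": ["ontology_a.nt", "ontology_b.nt"],
        "edge_spec_paths": ["edge_specs.yaml"],
        "anchor_map_path": "anchor_map.tsv",
        "relation_map_path": "relation_map.tsv",
        "output_directory": "build",
        "seed": fixture.params.seed,
    }
    (directory / "config.yaml").write_text(
        yaml.safe_dump(config, sort_keys=False), encoding="utf-8")
    return directory
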