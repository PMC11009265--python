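"""Knowledge-graph construction: attach edge lists to a core ontology.

Three representation parameters jointly select one of twelve build
variants:

* **knowledge model** — ``class_based`` adds each non-ontology entity as
  a subclass of its anchor ontology class and encodes every edge as an
  anonymous all-some restriction (4 triples per edge);
  ``instance_based`` adds entities as typed individuals and asserts each
  edge directly between individuals (~1 triple per edge, plus one
  reusable minted individual per ontology class that participates).
* **relation strategy** — ``standard`` asserts each directed pair once;
  ``inverse`` additionally asserts the ontology-defined inverse (o,
  r_inv, s), or the symmetric reciprocal (o, r, s) for interaction-type
  edges; relations with no inverse stay directed.
* **semantic abstraction** — none / OWL-NETS / OWL-NETS + harmonization
  (see :mod:`kgweave.owlnets`).

Anonymous nodes are minted deterministically: the identifier is the md5
hex digest of the subject IRI suffixed "subject", the relation IRI, and
the object IRI suffixed "object", concatenated in that order with no
separator. Identical inputs therefore rebuild byte-identical graphs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

from . import vocab
from .edges import EdgeList, load_edge_specs, assemble_edge_list
from .ontology import (
    CleaningReport,
    ConfigurationError,
    clean_ontology,
    declared_classes,
    extract_node_metadata,
    merge_ontologies,
    render_cleaning_report,
    write_node_metadata_tsv,
)
from .rdf import (
    NodeRef,
    Triple,
    TripleGraph,
    is_absolute_iri,
    parse_ntriples,
    serialize_ntriples,
)

logger = logging.getLogger(__name__)

KNOWLEDGE_MODELS = ("class_based", "instance_based")
RELATION_STRATEGIES = ("standard", "inverse")
ABSTRACTION_MODES = ("none", "owlnets", "owlnets_harmonized")

_RDF_TYPE = NodeRef.iri(vocab.RDF_TYPE)
_RDFS_SUBCLASSOF = NodeRef.iri(vocab.RDFS_SUBCLASSOF)
_OWL_CLASS = NodeRef.iri(vocab.OWL_CLASS)
_OWL_NAMED_INDIVIDUAL = NodeRef.iri(vocab.OWL_NAMED_INDIVIDUAL)
_OWL_RESTRICTION = NodeRef.iri(vocab.OWL_RESTRICTION)
_OWL_ON_PROPERTY = NodeRef.iri(vocab.OWL_ON_PROPERTY)
_OWL_SOME_VALUES_FROM = NodeRef.iri(vocab.OWL_SOME_VALUES_FROM)


class BuildError(RuntimeError):
    """A build stage failed; the message is stage-tagged."""


# ---------------------------------------------------------------------------
# Deterministic node minting
# ---------------------------------------------------------------------------

def mint_edge_node(subject: str, relation: str, object: str) -> NodeRef:
    """Deterministic anonymous node for one (subject, relation, object).

    The identifier is the lowercase-hex md5 of
    ``subject + "subject"`` || ``relation`` || ``object + "object"``,
    concatenated in that fixed order with no separator.
    """
    for name, iri in (("subject", subject), ("relation", relation),
                      ("object", object)):
        if not is_absolute_iri(iri):
            raise ValueError(f"{name} must be an absolute IRI, got {iri!r}")
    digest = hashlib.md5(
        (subject + "subject" + relation + object + "object").encode("utf-8")
    ).hexdigest()
    return NodeRef.anon(digest)


def mint_class_proxy(class_iri: str) -> NodeRef:
    """Reusable minted individual standing for one ontology class in
    instance-based builds (one per class, md5 of the class IRI)."""
    if not is_absolute_iri(class_iri):
        raise ValueError(f"class IRI must be absolute, got {class_iri!r}")
    return NodeRef.anon(hashlib.md5(class_iri.encode("utf-8")).hexdigest())


# ---------------------------------------------------------------------------
# Configuration containers
# ---------------------------------------------------------------------------

@dataclass
class RelationMap:
    """Relation-Ontology-style inverse table plus the symmetric set.

    Loaded from a two-column TSV relation→inverse; a relation mapped to
    itself is symmetric. Inverse pairs must be mutually inverse.
    """

    inverses: dict[str, str] = field(default_factory=dict)
    symmetric: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        for r, inv in self.inverses.items():
            back = self.inverses.get(inv)
            if back != r:
                raise ConfigurationError(
                    f"relation map not mutually inverse: {r} -> {inv} "
                    f"but {inv} -> {back}")
        overlap = self.symmetric & {
            r for r, inv in self.inverses.items() if inv != r}
        if overlap:
            raise ConfigurationError(
                f"relations both symmetric and inverted: {sorted(overlap)}")

    @classmethod
    def from_tsv(cls, path: Union[str, Path]) -> "RelationMap":
        inverses: dict[str, str] = {}
        symmetric: set[str] = set()
        for lineno, line in enumerate(
                Path(path).read_text(encoding="utf-8").splitlines(), 1):
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ConfigurationError(
                    f"{path}: line {lineno} is not two tab-separated fields")
            r, inv = parts
            if r == inv:
                symmetric.add(r)
            else:
                inverses[r] = inv
        return cls(inverses=inverses, symmetric=symmetric)


def read_anchor_map(path: Union[str, Path]) -> dict[str, str]:
    """Two-column headerless TSV: entity IRI → anchor class IRI."""
    anchors: dict[str, str] = {}
    for lineno, line in enumerate(
            Path(path).read_text(encoding="utf-8").splitlines(), 1):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise ConfigurationError(
                f"{path}: line {lineno} is not two tab-separated fields")
        anchors[parts[0]] = parts[1]
    return anchors


@dataclass
class BuildConfig:
    """The three representation parameters plus input/output locations."""

    knowledge_model: str = "class_based"
    relation_strategy: str = "standard"
    abstraction: str = "none"
    ontology_paths: Sequence[str] = field(default_factory=list)
    edge_spec_paths: Sequence[str] = field(default_factory=list)
    anchor_map_path: Optional[str] = None
    relation_map_path: Optional[str] = None
    output_directory: str = "build"
    mint_namespace: str = vocab.DEFAULT_MINT_NAMESPACE
    seed: int = 0

    def __post_init__(self) -> None:
        if self.knowledge_model not in KNOWLEDGE_MODELS:
            raise ConfigurationError(
                f"knowledge_model must be one of {KNOWLEDGE_MODELS}")
        if self.relation_strategy not in RELATION_STRATEGIES:
            raise ConfigurationError(
                f"relation_strategy must be one of {RELATION_STRATEGIES}")
        if self.abstraction not in ABSTRACTION_MODES:
            raise ConfigurationError(
                f"abstraction must be one of {ABSTRACTION_MODES}")

    @property
    def variant_name(self) -> str:
        model = "class" if self.knowledge_model == "class_based" else "instance"
        abstraction = {"none": "none", "owlnets": "owlnets",
                       "owlnets_harmonized": "owlnets_purified"}[self.abstraction]
        return f"{model}_{self.relation_strategy}_{abstraction}"

    @classmethod
    def from_yaml(cls, path: Union[str, Path], **overrides) -> "BuildConfig":
        import yaml

        doc = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        doc.update(overrides)
        base = Path(path).parent

        def rel(p):
            p = Path(p)
            return str(p if p.is_absolute() else base / p)

        for key in ("ontology_paths", "edge_spec_paths"):
            if key in doc:
                doc[key] = [rel(p) for p in doc[key]]
        for key in ("anchor_map_path", "relation_map_path"):
            if doc.get(key):
                doc[key] = rel(doc[key])
        return cls(**doc)


# ---------------------------------------------------------------------------
# Relation expansion
# ---------------------------------------------------------------------------

def expand_relations(edge_list: EdgeList, relmap: RelationMap,
                     strategy: str) -> list[tuple[str, str, str]]:
    """Directed (subject, relation, object) assertions for one edge type.

    ``standard`` keeps one assertion per pair. ``inverse`` adds
    (o, r_inv, s) when the relation has an inverse, (o, r, s) when the
    edge type is symmetric, and nothing for inverse-less relations.
    Output is deduplicated preserving first occurrence, so pairs already
    reciprocal in the source do not double-count.
    """
    if strategy not in RELATION_STRATEGIES:
        raise ConfigurationError(f"unknown relation strategy {strategy!r}")
    r = edge_list.relation
    symmetric = edge_list.symmetric or r in relmap.symmetric
    inverse = edge_list.inverse_relation or relmap.inverses.get(r)
    if symmetric and inverse:
        raise ConfigurationError(
            f"edge type {edge_list.edge_type!r} is flagged symmetric but "
            f"also has inverse {inverse!r}")

    assertions: list[tuple[str, str, str]] = []
    seen: set[tuple[str, str, str]] = set()

    def emit(a: tuple[str, str, str]) -> None:
        if a not in seen:
            seen.add(a)
            assertions.append(a)

    for s, o in edge_list.pairs:
        emit((s, r, o))
        if strategy == "inverse":
            if symmetric:
                emit((o, r, s))
            elif inverse:
                emit((o, inverse, s))
    return assertions


# ---------------------------------------------------------------------------
# Entity anchoring and edge materialization
# ---------------------------------------------------------------------------

def anchor_entities(edge_lists: Sequence[EdgeList], anchors: dict[str, str],
                    model: str, ontology_classes: set[str]) -> TripleGraph:
    """Attach every non-ontology entity under its anchor ontology class.

    class_based: ``E rdf:type owl:Class; E rdfs:subClassOf A``.
    instance_based: ``E rdf:type owl:NamedIndividual; E rdf:type A``.
    Each entity is anchored exactly once no matter how many edge lists
    mention it. Entities without an anchor abort the build, listing all
    of them.
    """
    entities: set[str] = set()
    for el in edge_lists:
        for s, o in el.pairs:
            for term in (s, o):
                if term not in ontology_classes:
                    entities.add(term)
    missing = sorted(e for e in entities if e not in anchors)
    if missing:
        raise BuildError(
            f"anchoring: {len(missing)} entities have no anchor class: "
            f"{', '.join(missing[:20])}" + ("..." if len(missing) > 20 else ""))

    graph = TripleGraph()
    for entity in sorted(entities):
        e = NodeRef.iri(entity)
        a = NodeRef.iri(anchors[entity])
        if model == "class_based":
            graph.add(Triple(e, _RDF_TYPE, _OWL_CLASS))
            graph.add(Triple(e, _RDFS_SUBCLASSOF, a))
        else:
            graph.add(Triple(e, _RDF_TYPE, _OWL_NAMED_INDIVIDUAL))
            graph.add(Triple(e, _RDF_TYPE, a))
    return graph


def materialize_edge(assertion: tuple[str, str, str], model: str,
                     anchored_entities: set[str],
                     proxy_cache: Optional[dict[str, NodeRef]] = None
                     ) -> set[Triple]:
    """Triples encoding one directed assertion under a knowledge model.

    class_based mints an anonymous restriction B and emits::

        s rdfs:subClassOf B .
        B rdf:type owl:Restriction .
        B owl:onProperty r .
        B owl:someValuesFrom o .

    instance_based asserts ``proxy(s) r proxy(o)`` directly, where an
    anchored data entity is its own individual and an ontology class is
    represented by one reusable minted individual (typed once via the
    shared *proxy_cache*).
    """
    s, r, o = assertion
    rel = NodeRef.iri(r)
    if model == "class_based":
        b = mint_edge_node(s, r, o)
        return {
            Triple(NodeRef.iri(s), _RDFS_SUBCLASSOF, b),
            Triple(b, _RDF_TYPE, _OWL_RESTRICTION),
            Triple(b, _OWL_ON_PROPERTY, rel),
            Triple(b, _OWL_SOME_VALUES_FROM, NodeRef.iri(o)),
        }
    if model != "instance_based":
        raise ConfigurationError(f"unknown knowledge model {model!r}")

    cache = proxy_cache if proxy_cache is not None else {}
    out: set[Triple] = set()

    def proxy(term: str) -> NodeRef:
        if term in anchored_entities:
            return NodeRef.iri(term)
        if term not in cache:
            p = mint_class_proxy(term)
            cache[term] = p
            out.add(Triple(p, _RDF_TYPE, NodeRef.iri(term)))
        return cache[term]

    out.add(Triple(proxy(s), rel, proxy(o)))
    return out


def construct_graph(core: TripleGraph, edge_lists: Sequence[EdgeList],
                    anchors: dict[str, str], relmap: RelationMap,
                    model: str, strategy: str
                    ) -> tuple[TripleGraph, list[tuple[str, str, str]]]:
    """Attach edge lists to the (already cleaned/merged) core ontology.

    Returns the constructed graph and the expanded assertion list.
    The core graph is not mutated.
    """
    ontology_classes = {c.value for c in declared_classes(core)}
    graph = core.copy()

    anchored = anchor_entities(edge_lists, anchors, model, ontology_classes)
    graph.update(anchored)
    anchored_entities = {
        t.subject.value for t in anchored if t.subject.is_named}

    assertions: list[tuple[str, str, str]] = []
    for el in edge_lists:
        assertions.extend(expand_relations(el, relmap, strategy))

    proxy_cache: dict[str, NodeRef] = {}
    for assertion in assertions:
        s, r, o = assertion
        for term in (s, o):
            if term not in ontology_classes and term not in anchored_entities:
                raise BuildError(
                    f"materialize: unknown participant {term!r}")
        graph.update(materialize_edge(assertion, model, anchored_entities,
                                      proxy_cache))
    return graph, assertions


# ---------------------------------------------------------------------------
# Full build orchestration
# ---------------------------------------------------------------------------

@dataclass
class BuildResult:
    graph: TripleGraph
    stats: "object"
    cleaning_reports: dict[str, CleaningReport]
    edge_lists: list[EdgeList]
    assertions: list[tuple[str, str, str]]
    output_directory: Optional[Path] = None
    graph_path: Optional[Path] = None


class _BuildLog:
    """Timestamped stage log; timestamps never enter serialized graphs."""

    def __init__(self) -> None:
        self.lines: list[str] = []

    def stage(self, name: str, message: str) -> None:
        stamp = time.strftime("%Y-%m-%d %H:%M:%S")
        line = f"{stamp} [{name}] {message}"
        self.lines.append(line)
        logger.info("[%s] %s", name, message)

    def write(self, path: Path) -> None:
        path.write_text("\n".join(self.lines) + "\n", encoding="utf-8")


def build_kg(config: BuildConfig,
             write_outputs: bool = True) -> BuildResult:
    """Run one full build: clean → merge → assemble → anchor → expand →
    materialize → abstract → serialize.

    Outputs (graph N-Triples, node metadata TSV, stats JSON, source
    metadata files, cleaning report, build log) land in
    ``config.output_directory``. Two runs on identical inputs produce
    byte-identical graph/metadata/stats files.
    """
    from .metrics import compute_stats
    from .owlnets import abstract_graph, harmonize

    log = _BuildLog()
    out_dir = Path(config.output_directory)

    def run_stage(name, fn):
        try:
            return fn()
        except Exception as exc:
            log.stage(name, f"FAILED: {exc}")
            if write_outputs:
                out_dir.mkdir(parents=True, exist_ok=True)
                log.write(out_dir / "pkt_build_log.log")
            raise BuildError(f"stage {name!r} failed: {exc}") from exc

    # 1. ontologies: parse and clean each, then merge
    def stage_ontologies():
        cleaned, reports = [], {}
        if not config.ontology_paths:
            raise ConfigurationError("no ontology paths configured")
        for path in config.ontology_paths:
            g = parse_ntriples(path)
            cg, report = clean_ontology(g)
            name = Path(path).name
            reports[name] = report
            cleaned.append(cg)
            log.stage("clean", f"{name}: {report.triples_before} -> "
                               f"{report.triples_after} triples")
        core = merge_ontologies(cleaned)
        log.stage("merge", f"core ontology has {len(core)} triples")
        return core, reports

    core, reports = run_stage("ontologies", stage_ontologies)

    # 2. edge lists
    def stage_edges():
        edge_lists = []
        for spec_path in config.edge_spec_paths:
            for spec in load_edge_specs(spec_path):
                el = assemble_edge_list(spec,
                                        base_dir=Path(spec_path).parent)
                edge_lists.append(el)
                log.stage("assemble",
                          f"{el.edge_type}: {len(el.pairs)} unique pairs")
        return edge_lists

    edge_lists = run_stage("edges", stage_edges)

    # 3. maps
    def stage_maps():
        anchors = (read_anchor_map(config.anchor_map_path)
                   if config.anchor_map_path else {})
        relmap = (RelationMap.from_tsv(config.relation_map_path)
                  if config.relation_map_path else RelationMap())
        return anchors, relmap

    anchors, relmap = run_stage("maps", stage_maps)

    # 4. construction
    def stage_construct():
        graph, assertions = construct_graph(
            core, edge_lists, anchors, relmap,
            config.knowledge_model, config.relation_strategy)
        log.stage("construct",
                  f"{len(assertions)} assertions -> {len(graph)} triples "
                  f"({config.knowledge_model}, {config.relation_strategy})")
        return graph, assertions

    graph, assertions = run_stage("construct", stage_construct)

    # 5. abstraction
    def stage_abstract():
        if config.abstraction == "none":
            return graph
        result = abstract_graph(graph)
        log.stage("abstract",
                  f"decoded {result.decoded_count} restrictions; "
                  f"{len(result.graph)} triples retained")
        g = result.graph
        if config.abstraction == "owlnets_harmonized":
            g = harmonize(g, config.knowledge_model)
            log.stage("harmonize", f"{len(g)} triples after harmonization")
        return g

    final_graph = run_stage("abstract", stage_abstract)

    stats = compute_stats(final_graph)
    log.stage("stats", f"n={stats.nodes} m={stats.triples} "
                       f"components={stats.connected_components}")

    result = BuildResult(
        graph=final_graph,
        stats=stats,
        cleaning_reports=reports,
        edge_lists=edge_lists,
        assertions=assertions,
    )

    if write_outputs:
        def stage_outputs():
            out_dir.mkdir(parents=True, exist_ok=True)
            graph_path = out_dir / f"kg_{config.variant_name}.nt"
            serialize_ntriples(final_graph, graph_path)
            write_node_metadata_tsv(extract_node_metadata(final_graph),
                                    out_dir / "node_metadata.tsv")
            (out_dir / "stats.json").write_text(
                stats.to_json() + "\n", encoding="utf-8")
            (out_dir / "ontology_cleaning_report.txt").write_text(
                render_cleaning_report(reports), encoding="utf-8")
            (out_dir / "ontology_source_metadata.txt").write_text(
                "\n".join(f"{Path(p).name}\t{p}"
                          for p in config.ontology_paths) + "\n",
                encoding="utf-8")
            (out_dir / "edge_source_metadata.txt").write_text(
                "\n".join(
                    f"{el.edge_type}\t{el.provenance.get('source_path', '')}"
                    f"\t{len(el.pairs)} pairs"
                    for el in edge_lists) + "\n",
                encoding="utf-8")
            for el in edge_lists:
                (out_dir / f"edges_{el.edge_type}.json").write_text(
                    el.to_json(), encoding="utf-8")
            log.stage("serialize", f"wrote {graph_path.name} "
                                   f"({len(final_graph)} triples)")
            log.write(out_dir / "pkt_build_log.log")
            return graph_path

        result.graph_path = run_stage("outputs", stage_outputs)
        result.output_directory = out_dir
    return result


def all_variant_configs(base: BuildConfig) -> list[BuildConfig]:
    """The 12-way matrix of knowledge model × relation strategy ×
    abstraction, derived from one base configuration."""
    from dataclasses import replace

    configs = []
    for model in KNOWLEDGE_MODELS:
        for strategy in RELATION_STRATEGIES:
            for abstraction in ABSTRACTION_MODES:
                cfg = replace(base, knowledge_model=model,
                              relation_strategy=strategy,
                              abstraction=abstraction)
                cfg.output_directory = str(
                    Path(base.output_directory) / cfg.variant_name)
                configs.append(cfg)
    return configs


def build_all_variants(base: BuildConfig,
                       write_outputs: bool = True
                       ) -> dict[str, BuildResult]:
    """Run the full 12-variant build matrix; returns results by variant
    name and writes a stats matrix TSV alongside the per-variant dirs."""
    results: dict[str, BuildResult] = {}
    for cfg in all_variant_configs(base):
        results[cfg.variant_name] = build_kg(cfg, write_outputs=write_outputs)
    if write_outputs:
        out = Path(base.output_directory)
        out.mkdir(parents=True, exist_ok=True)
        header = ("variant\ttriples\tnodes\trelations\tself_loops\t"
                  "avg_degree\tdensity\tconnected_components")
        rows = [header]
        for name, res in results.items():
            s = res.stats
            rows.append(f"{name}\t{s.triples}\t{s.nodes}\t{s.relations}\t"
                        f"{s.self_loops}\t{s.avg_degree}\t{s.density}\t"
                        f"{s.connected_components}")
        (out / "stats_matrix.tsv").write_text("\n".join(rows) + "\n",
                                              encoding="utf-8")
    return results
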