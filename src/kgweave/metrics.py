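"""Descriptive statistics for built knowledge graphs.

Conventions (matched to how large biomedical KG releases report their
benchmark tables): *n* counts distinct subject/object terms excluding
literals (anonymous nodes included); *m* counts triples; average degree
is m / n rounded to 2 decimals; density is the directed simple-graph
formula m / (n·(n−1)) to 3 significant figures; connected components
are counted on the undirected projection that ignores predicates.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import networkx as nx

from .rdf import TripleGraph


def average_degree(triples: int, nodes: int) -> float:
    """m / n rounded to 2 decimals; 0.0 for an empty graph."""
    if nodes == 0:
        return 0.0
    return round(triples / nodes, 2)


def density(triples: int, nodes: int) -> float:
    """Directed simple-graph density m / (n·(n−1)) to 3 significant
    figures; 0.0 when undefined (n < 2)."""
    if nodes < 2:
        return 0.0
    return round_sig(triples / (nodes * (nodes - 1)), 3)


def round_sig(x: float, figures: int) -> float:
    if x == 0:
        return 0.0
    return float(f"{x:.{figures}g}")


@dataclass
class GraphStats:
    nodes: int
    triples: int
    relations: int
    self_loops: int
    avg_degree: float
    density: float
    connected_components: int

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)


def compute_stats(graph: TripleGraph) -> GraphStats:
    """All summary statistics for one graph; an empty graph reports
    zeros (density undefined is reported as 0)."""
    m = len(graph)
    nodes = set()
    self_loops = 0
    projection = nx.Graph()
    for t in graph:
        if t.subject == t.object:
            self_loops += 1
        for term in (t.subject, t.object):
            if term.kind != "literal":
                nodes.add(term)
                projection.add_node(term)
        if t.subject.kind != "literal" and t.object.kind != "literal":
            projection.add_edge(t.subject, t.object)
    n = len(nodes)
    components = (nx.number_connected_components(projection)
                  if projection.number_of_nodes() else 0)
    return GraphStats(
        nodes=n,
        triples=m,
        relations=len(graph.predicates()),
        self_loops=self_loops,
        avg_degree=average_degree(m, n),
        density=density(m, n),
        connected_components=components,
    )
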