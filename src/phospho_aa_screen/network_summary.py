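"""Degree computation and hub ranking over a protein interaction edge list.

Stands in for exploring a STRING-style export: given undirected edges
(optionally scored), count each queried protein's distinct neighbors
*within the queried set* and rank proteins by degree.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import networkx as nx

#: Edges scored below this confidence are ignored by default
#: (the customary "medium confidence" cut for STRING-style scores).
DEFAULT_MIN_WEIGHT = 0.4


def build_graph(
    edges: Iterable[Sequence],
    min_weight: float = DEFAULT_MIN_WEIGHT,
) -> nx.Graph:
    """An undirected simple graph from (a, b[, score]) edges.

    Unscored edges are always kept; scored edges must reach
    ``min_weight``.  Self-loops are dropped; parallel edges collapse.
    """
    graph = nx.Graph()
    for edge in edges:
        a, b = edge[0], edge[1]
        weight = edge[2] if len(edge) > 2 else None
        if a == b:
            continue
        if weight is not None and weight < min_weight:
            continue
        graph.add_edge(a, b)
    return graph


def degree_rank(
    edges: Iterable[Sequence],
    proteins: Iterable[str] | None = None,
    min_weight: float = DEFAULT_MIN_WEIGHT,
) -> list[tuple[str, int]]:
    """Proteins ranked by degree within the queried set.

    With ``proteins`` given, the graph is restricted to that set and
    every queried protein appears in the ranking (degree 0 if isolated);
    otherwise all graph nodes are ranked.  Ties break lexicographically.
    """
    graph = build_graph(edges, min_weight=min_weight)
    if proteins is None:
        nodes = list(graph.nodes)
        subgraph = graph
    else:
        nodes = sorted(set(proteins))
        subgraph = graph.subgraph(n for n in nodes if n in graph)
    degrees = {node: 0 for node in nodes}
    degrees.update(dict(subgraph.degree()))
    return sorted(degrees.items(), key=lambda item: (-item[1], item[0]))
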