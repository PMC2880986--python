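"""Shortest-path betweenness for the enzyme network.

Two variants are provided.  ``betweenness_bfs_tree`` is the breadth-first-tree
accumulation in which every tree vertex starts with a score of 1 and scores
propagate to predecessors split proportionally to shortest-path counts; its
totals therefore include endpoint mass.  ``betweenness_standard`` is the
usual pair-dependency betweenness (endpoints excluded).  A brute-force
enumeration oracle is included for verification on tiny graphs.

All edges have unit length.  Directional edges are traversed source→target
only; bidirectional edges are traversed both ways by default.
"""

from __future__ import annotations

from collections import deque

import networkx as nx
import pandas as pd

from .network_build import MetabolicNetwork, compute_degrees

__all__ = [
    "betweenness_bfs_tree",
    "betweenness_standard",
    "brute_force_betweenness",
    "centrality_table",
]


def _as_digraph(network, traverse_bidirectional: bool = True) -> nx.DiGraph:
    if isinstance(network, MetabolicNetwork):
        return network.to_networkx(traverse_bidirectional)
    if isinstance(network, nx.DiGraph):
        return network
    raise TypeError("network must be a MetabolicNetwork or networkx.DiGraph")


def _bfs_tree(g: nx.DiGraph, source):
    """Levels, shortest-path counts P, predecessor lists and BFS order."""
    level = {source: 0}
    paths = {source: 1}
    preds: dict = {source: []}
    order = [source]
    queue = deque([source])
    while queue:
        v = queue.popleft()
        for w in g.successors(v):
            if w not in level:
                level[w] = level[v] + 1
                paths[w] = 0
                preds[w] = []
                order.append(w)
                queue.append(w)
            if level[w] == level[v] + 1:
                paths[w] += paths[v]
                preds[w].append(v)
    return level, paths, preds, order


def betweenness_bfs_tree(
    network, traverse_bidirectional: bool = True
) -> dict[str, float]:
    """Breadth-first-tree betweenness with leaf initialization.

    For each source, every vertex of its shortest-path tree starts with
    score 1; processing vertices bottom-up, a vertex's accumulated score is
    added to its predecessors, split among multiple predecessors ``k``
    proportionally to ``P(k)/P(j)``.  B(j) is the sum, over all source
    trees containing j, of the accumulated score at j (endpoints included).
    """
    g = _as_digraph(network, traverse_bidirectional)
    if g.number_of_nodes() == 0:
        raise ValueError("network is empty")
    b = dict.fromkeys(g.nodes, 0.0)
    for source in g.nodes:
        _level, paths, preds, order = _bfs_tree(g, source)
        score = dict.fromkeys(order, 1.0)
        for v in reversed(order):
            for k in preds[v]:
                score[k] += score[v] * paths[k] / paths[v]
        for v in order:
            b[v] += score[v]
    return b


def betweenness_standard(
    network, traverse_bidirectional: bool = True
) -> dict[str, float]:
    """Pair-dependency betweenness: B(v) = Σ_{s≠v≠t} σ_st(v)/σ_st."""
    g = _as_digraph(network, traverse_bidirectional)
    if g.number_of_nodes() == 0:
        raise ValueError("network is empty")
    return dict(nx.betweenness_centrality(g, normalized=False))


def brute_force_betweenness(
    network, traverse_bidirectional: bool = True, max_nodes: int = 12
) -> dict[str, float]:
    """Betweenness by explicit enumeration of every shortest path.

    Test oracle only; refuses graphs above ``max_nodes`` nodes.  Returns the
    same quantity as :func:`betweenness_standard`.
    """
    g = _as_digraph(network, traverse_bidirectional)
    n = g.number_of_nodes()
    if n > max_nodes:
        raise ValueError(f"brute force limited to {max_nodes} nodes, got {n}")
    b = dict.fromkeys(g.nodes, 0.0)
    for s in g.nodes:
        level, _paths, preds, order = _bfs_tree(g, s)
        for t in order:
            if t == s:
                continue
            # enumerate all shortest s→t paths by walking predecessors
            paths_to_t: list[list] = []
            stack = [[t]]
            while stack:
                partial = stack.pop()
                head = partial[-1]
                if head == s:
                    paths_to_t.append(partial)
                    continue
                for p in preds[head]:
                    stack.append(partial + [p])
            sigma = len(paths_to_t)
            for path in paths_to_t:
                for v in path[1:-1]:  # interior vertices only
                    b[v] += 1.0 / sigma
    return b


def centrality_table(
    network: MetabolicNetwork, traverse_bidirectional: bool = True
) -> pd.DataFrame:
    """Per-enzyme degrees and both betweenness variants as a DataFrame."""
    degrees = compute_degrees(network)
    bp = betweenness_bfs_tree(network, traverse_bidirectional)
    bs = betweenness_standard(network, traverse_bidirectional)
    rows = [
        {
            "enzyme_id": enz,
            "in_degree": rec.in_degree,
            "out_degree": rec.out_degree,
            "betweenness_bfs_tree": bp[enz],
            "betweenness_standard": bs[enz],
        }
        for enz, rec in sorted(degrees.items())
    ]
    return pd.DataFrame(rows).set_index("enzyme_id")
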