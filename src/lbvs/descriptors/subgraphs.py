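"""Connected-subgraph enumeration for molecular connectivity indices.

Enumerates every connected edge-induced subgraph with a given number of
edges exactly once (ESU-style growth on the line graph: a subgraph is rooted
at its minimum edge index and only extended with higher-indexed edges), then
classifies it as *path*, *cluster* (tree with no vertex of internal degree
2, i.e. star-like branching), *chain* (a simple cycle), or other.  Only
paths, clusters and chains enter the chi indices; mixed path/cluster trees
and multi-cyclic subgraphs are deliberately not indexed.
"""

from __future__ import annotations

from enum import Enum
from typing import Iterator, Sequence

import networkx as nx


class SubgraphType(Enum):
    PATH = "path"
    CLUSTER = "cluster"
    PATH_CLUSTER = "path_cluster"
    CHAIN = "chain"
    OTHER = "other"


def connected_edge_subgraphs(g: nx.Graph, m: int) -> Iterator[frozenset]:
    """Yield each connected subgraph with exactly ``m`` edges once.

    Subgraphs are edge sets (frozensets of ``(u, v)`` tuples with ``u < v``).
    """
    edges = [tuple(sorted(e)) for e in g.edges()]
    index = {e: i for i, e in enumerate(edges)}
    # adjacency between edges sharing a vertex
    incident: dict = {}
    for e in edges:
        for v in e:
            incident.setdefault(v, []).append(e)

    def neighbors(e):
        for v in e:
            for f in incident[v]:
                if f != e:
                    yield f

    def shares_vertex(e, f) -> bool:
        return bool(set(e) & set(f))

    def extend(sub: list, ext: list, root: int):
        if len(sub) == m:
            yield frozenset(sub)
            return
        ext = list(ext)
        while ext:
            cand = ext.pop()
            # exclusive neighbors: adjacent to cand only, never to the older
            # part of the subgraph (prevents duplicate enumeration)
            excl = []
            for f in neighbors(cand):
                if index[f] <= root or f in ext or f == cand:
                    continue
                if any(shares_vertex(f, e) for e in sub):
                    continue
                excl.append(f)
            yield from extend(sub + [cand], ext + list(dict.fromkeys(excl)), root)

    for e in edges:
        root = index[e]
        ext = [f for f in neighbors(e) if index[f] > root]
        yield from extend([e], list(dict.fromkeys(ext)), root)


def classify(edge_set: frozenset) -> tuple[SubgraphType, tuple]:
    """Classify an edge set and return (type, vertex tuple)."""
    deg: dict = {}
    for u, v in edge_set:
        deg[u] = deg.get(u, 0) + 1
        deg[v] = deg.get(v, 0) + 1
    n_vertices = len(deg)
    n_edges = len(edge_set)
    vertices = tuple(deg)
    degrees = deg.values()
    if n_edges == n_vertices - 1:  # tree
        if max(degrees) <= 2:
            return SubgraphType.PATH, vertices
        if 2 not in degrees:
            return SubgraphType.CLUSTER, vertices
        return SubgraphType.PATH_CLUSTER, vertices
    if n_edges == n_vertices and all(d == 2 for d in degrees):
        return SubgraphType.CHAIN, vertices
    return SubgraphType.OTHER, vertices


def subgraph_vertices(
    g: nx.Graph, m: int, kind: SubgraphType
) -> list[tuple]:
    """Vertex tuples of all order-``m`` subgraphs of the requested kind."""
    out = []
    for es in connected_edge_subgraphs(g, m):
        t, verts = classify(es)
        if t is kind:
            out.append(verts)
    return out


def count_paths(g: nx.Graph, m: int) -> int:
    """Number of simple paths with ``m`` edges (each counted once)."""
    if m == 0:
        return g.number_of_nodes()
    return len(subgraph_vertices(g, m, SubgraphType.PATH))
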