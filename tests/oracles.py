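"""Independent brute-force oracles for descriptor tests.

Everything here recomputes graph invariants from first principles
(exhaustive enumeration over edge subsets, hand-applied definitions) and
deliberately shares no code with the package implementation.
"""

from __future__ import annotations

import itertools
import math

import networkx as nx


def brute_connected_subgraphs(g: nx.Graph, m: int) -> set[frozenset]:
    edges = [tuple(sorted(e)) for e in g.edges()]
    found = set()
    for combo in itertools.combinations(edges, m):
        h = nx.Graph()
        h.add_edges_from(combo)
        if nx.is_connected(h):
            found.add(frozenset(combo))
    return found


def _subgraph_kind(edge_set: frozenset) -> str:
    h = nx.Graph()
    h.add_edges_from(edge_set)
    degs = [d for _, d in h.degree()]
    if h.number_of_edges() == h.number_of_nodes() - 1:
        if max(degs) <= 2:
            return "path"
        if 2 not in degs:
            return "cluster"
        return "path_cluster"
    if h.number_of_edges() == h.number_of_nodes() and all(d == 2 for d in degs):
        return "chain"
    return "other"


def brute_chi(g: nx.Graph, m: int, kind: str, key: str = "delta") -> float:
    """Chi index by exhaustive subgraph enumeration."""
    if m == 0:
        return sum(
            g.nodes[v][key] ** -0.5 for v in g.nodes if g.nodes[v][key] > 0
        )
    total = 0.0
    for es in brute_connected_subgraphs(g, m):
        if _subgraph_kind(es) != kind:
            continue
        verts = set(itertools.chain.from_iterable(es))
        vals = [g.nodes[v][key] for v in verts]
        if any(v <= 0 for v in vals):
            continue
        total += math.prod(vals) ** -0.5
    return total


def brute_wiener(g: nx.Graph) -> int:
    nodes = list(g.nodes)
    total = 0
    for i, u in enumerate(nodes):
        for v in nodes[i + 1:]:
            total += nx.shortest_path_length(g, u, v)
    return total


def brute_centric(g: nx.Graph) -> int:
    h = g.copy()
    total = 0
    while h.number_of_nodes():
        leaves = [v for v in h if h.degree[v] <= 1]
        if not leaves:
            total += h.number_of_nodes() ** 2
            break
        total += len(leaves) ** 2
        h.remove_nodes_from(leaves)
    return total


def brute_path_count(g: nx.Graph, m: int) -> int:
    """Simple m-edge paths, each counted once, by endpoint enumeration."""
    if m == 0:
        return g.number_of_nodes()
    count = 0
    nodes = list(g.nodes)
    for u in nodes:
        for path in nx.all_simple_paths(g, u, nodes, cutoff=m):
            if len(path) == m + 1:
                count += 1
    return count // 2


def brute_kappa(g: nx.Graph) -> dict[str, float | None]:
    a = g.number_of_nodes()
    p1 = g.number_of_edges()
    p2 = brute_path_count(g, 2)
    p3 = brute_path_count(g, 3)
    out: dict[str, float | None] = {}
    out["k1"] = a * (a - 1) ** 2 / p1**2 if p1 else None
    out["k2"] = (a - 1) * (a - 2) ** 2 / p2**2 if p2 else None
    if p3:
        out["k3"] = (
            (a - 1) * (a - 3) ** 2 / p3**2
            if a % 2
            else (a - 3) * (a - 2) ** 2 / p3**2
        )
    else:
        out["k3"] = None
    return out


def brute_auc(scores, truth) -> float:
    """Mann–Whitney pair statistic with half credit for score ties."""
    pos = [s for s, t in zip(scores, truth) if t == 1]
    neg = [s for s, t in zip(scores, truth) if t == -1]
    total = 0.0
    for sp in pos:
        for sn in neg:
            if sp > sn:
                total += 1.0
            elif sp == sn:
                total += 0.5
    return total / (len(pos) * len(neg))
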