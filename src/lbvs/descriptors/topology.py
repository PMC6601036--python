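"""Topological, connectivity (chi) and shape (kappa) indices.

All functions operate on the hydrogen-suppressed graph produced by
:func:`lbvs.chemio.heavy_graph`, whose vertices carry ``delta`` (heavy
neighbor count) and ``delta_v`` (valence electrons minus attached
hydrogens).
"""

from __future__ import annotations

import math
from typing import Sequence

import networkx as nx

from .subgraphs import SubgraphType, count_paths, subgraph_vertices


def wiener_index(g: nx.Graph) -> int:
    """Sum of shortest-path lengths over unordered vertex pairs."""
    if g.number_of_nodes() > 1 and not nx.is_connected(g):
        raise ValueError("Wiener index requires a connected graph")
    total = 0
    for _, lengths in nx.all_pairs_shortest_path_length(g):
        total += sum(lengths.values())
    return total // 2


def centric_index(g: nx.Graph) -> int:
    """Balaban pruning centric index (Tcent).

    Repeatedly delete *all* degree-1 vertices; each step contributes
    (number deleted)^2.  A lone remaining vertex contributes 1 (a remaining
    edge is removed as a pair, contributing 4).  A remaining cyclic core of
    c vertices (every degree >= 2) contributes c^2 — the generalization
    adopted here for cycle-containing molecules.
    """
    h = g.copy()
    total = 0
    while h.number_of_nodes():
        leaves = [v for v in h.nodes if h.degree[v] <= 1]
        if not leaves:
            total += h.number_of_nodes() ** 2  # cyclic core
            break
        total += len(leaves) ** 2
        h.remove_nodes_from(leaves)
    return total


def zagreb_m1(g: nx.Graph) -> int:
    return sum(d * d for _, d in g.degree())


def zagreb_m2(g: nx.Graph) -> int:
    return sum(g.degree[u] * g.degree[v] for u, v in g.edges())


def platt_number(g: nx.Graph) -> int:
    return sum(g.degree[u] + g.degree[v] - 2 for u, v in g.edges())


def graph_radius(g: nx.Graph) -> int:
    if g.number_of_nodes() <= 1:
        return 0
    return nx.radius(g)


def graph_diameter(g: nx.Graph) -> int:
    if g.number_of_nodes() <= 1:
        return 0
    return nx.diameter(g)


# ---------------------------------------------------------------------------
# chi connectivity indices


def _chi_sum(g: nx.Graph, vertex_sets: Sequence[tuple], valence: bool) -> float:
    key = "delta_v" if valence else "delta"
    total = 0.0
    for verts in vertex_sets:
        prod = 1.0
        ok = True
        for v in verts:
            d = g.nodes[v][key]
            if d <= 0:
                ok = False  # degenerate vertex: subgraph contributes nothing
                break
            prod *= d
        if ok:
            total += prod ** -0.5
    return total


def chi_path(g: nx.Graph, order: int, valence: bool = False) -> float:
    """Order-m path chi: sum over simple m-edge paths of (prod delta)^-1/2."""
    key = "delta_v" if valence else "delta"
    if order == 0:
        return sum(
            g.nodes[v][key] ** -0.5 for v in g.nodes if g.nodes[v][key] > 0
        )
    sets = subgraph_vertices(g, order, SubgraphType.PATH)
    return _chi_sum(g, sets, valence)


def chi_cluster(g: nx.Graph, order: int, valence: bool = False) -> float:
    """Order-m cluster chi (star-branched tree subgraphs, m in 3..6)."""
    sets = subgraph_vertices(g, order, SubgraphType.CLUSTER)
    return _chi_sum(g, sets, valence)


def chi_chain(g: nx.Graph, order: int, valence: bool = False) -> float:
    """Order-m chain chi: simple cycles of exactly m edges, each once."""
    sets = subgraph_vertices(g, order, SubgraphType.CHAIN)
    return _chi_sum(g, sets, valence)


# ---------------------------------------------------------------------------
# kappa shape indices

# Kier alpha: covalent radius relative to sp3 carbon, by element and
# hybridization state.
_ALPHA_RADII = {
    ("C", 3): 0.77, ("C", 2): 0.67, ("C", 1): 0.60,
    ("N", 3): 0.74, ("N", 2): 0.62, ("N", 1): 0.55,
    ("O", 3): 0.74, ("O", 2): 0.62,
    ("F", 3): 0.72,
    ("P", 3): 1.10, ("P", 2): 1.00,
    ("S", 3): 1.04, ("S", 2): 0.94,
    ("Cl", 3): 0.99,
    ("Br", 3): 1.14,
    ("I", 3): 1.33,
}
_R_CSP3 = 0.77


def _hybridization(g: nx.Graph, v: int) -> int:
    """3 = sp3, 2 = sp2 (incl. aromatic), 1 = sp."""
    orders = [g.edges[v, u]["order"] for u in g.neighbors(v)]
    aromatic = any(g.edges[v, u]["aromatic"] for u in g.neighbors(v))
    if 3 in orders or orders.count(2) >= 2:
        return 1
    if 2 in orders or aromatic:
        return 2
    return 3


def kier_alpha(g: nx.Graph) -> float:
    """Sum over atoms of (r_i / r_Csp3 - 1)."""
    total = 0.0
    for v in g.nodes:
        el = g.nodes[v]["element"]
        hyb = _hybridization(g, v)
        r = _ALPHA_RADII.get((el, hyb)) or _ALPHA_RADII.get((el, 3))
        if r is None:
            raise ValueError(f"no alpha radius for element {el}")
        total += r / _R_CSP3 - 1.0
    return total


def kappa_indices(g: nx.Graph, alpha: bool = False) -> dict[str, float | None]:
    """Kier kappa 1-3 (optionally alpha-modified).

    Degenerate molecules (zero path-count denominators) yield ``None`` for
    the affected order rather than raising.
    """
    a = float(g.number_of_nodes())
    p1 = float(g.number_of_edges())
    p2 = float(count_paths(g, 2))
    p3 = float(count_paths(g, 3))
    al = kier_alpha(g) if alpha else 0.0
    aa, q1, q2, q3 = a + al, p1 + al, p2 + al, p3 + al
    out: dict[str, float | None] = {}
    out["k1"] = aa * (aa - 1.0) ** 2 / q1**2 if q1 > 0 else None
    out["k2"] = (aa - 1.0) * (aa - 2.0) ** 2 / q2**2 if q2 > 0 else None
    if q3 > 0:
        if g.number_of_nodes() % 2:  # odd A
            out["k3"] = (aa - 1.0) * (aa - 3.0) ** 2 / q3**2
        else:
            out["k3"] = (aa - 3.0) * (aa - 2.0) ** 2 / q3**2
    else:
        out["k3"] = None
    return out
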