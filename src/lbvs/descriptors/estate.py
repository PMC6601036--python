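"""Electrotopological-state (E-state) indices.

Per heavy atom i the intrinsic state is

    I_i = ((2 / N_i)^2 * delta_v_i + 1) / delta_i

with N the principal quantum number of the valence shell, and the field
perturbation

    dI_i = sum_j (I_i - I_j) / (d_ij + 1)^2

over all other heavy atoms (d = topological distance).  The E-state value
S_i = I_i + dI_i.  The perturbation terms are pairwise antisymmetric, so
sum_i dI_i = 0 and sum_i S_i = sum_i I_i for every molecule.

Molecular descriptors are sums of S_i over atoms of the same type.  The
type table below is a coarse, documented grouping of the Kier–Hall atom
types by element, aromaticity and bonding pattern; ``S27`` is the aromatic
carbon (":C::") type sum.
"""

from __future__ import annotations

import networkx as nx

#: Atom-type sums exposed as descriptors, in registry order.
ESTATE_TYPES = (
    "S27_arom_C",    # aromatic carbon (:C:: type)
    "S_CH3",         # -CH3
    "S_CH2",         # -CH2-
    "S_CH",          # >CH-
    "S_Cq",          # >C< quaternary
    "S_C_unsat",     # non-aromatic sp2/sp carbon
    "S_arom_N",      # aromatic nitrogen
    "S_N_sp3",       # amine nitrogen
    "S_N_unsat",     # imine / nitrile / nitro nitrogen
    "S_OH",          # hydroxyl oxygen
    "S_O_ether",     # -O- ether/ester oxygen
    "S_O_dbl",       # =O carbonyl-type oxygen
    "S_S",           # any sulfur
    "S_P",           # any phosphorus
    "S_halogen",     # F, Cl, Br, I
)


def intrinsic_states(g: nx.Graph) -> dict[int, float]:
    out = {}
    for v in g.nodes:
        d = g.nodes[v]
        delta = max(d["delta"], 1)  # lone heavy atom: use delta = 1
        n = d["pqn"]
        out[v] = ((2.0 / n) ** 2 * d["delta_v"] + 1.0) / delta
    return out


def estate_values(g: nx.Graph) -> dict[int, float]:
    """E-state S_i per atom: intrinsic state plus distance-damped field."""
    intr = intrinsic_states(g)
    dist = dict(nx.all_pairs_shortest_path_length(g))
    s = {}
    for i in g.nodes:
        di = 0.0
        for j in g.nodes:
            if j == i or j not in dist[i]:
                continue
            di += (intr[i] - intr[j]) / (dist[i][j] + 1.0) ** 2
        s[i] = intr[i] + di
    return s


def _atom_type(g: nx.Graph, v: int) -> str | None:
    d = g.nodes[v]
    el, arom, nh = d["element"], d["aromatic"], d["n_h"]
    orders = [g.edges[v, u]["order"] for u in g.neighbors(v)]
    unsat = (3 in orders) or (2 in orders)
    if el == "C":
        if arom:
            return "S27_arom_C"
        if unsat:
            return "S_C_unsat"
        return {3: "S_CH3", 2: "S_CH2", 1: "S_CH", 0: "S_Cq"}.get(nh, "S_Cq")
    if el == "N":
        if arom:
            return "S_arom_N"
        return "S_N_unsat" if unsat else "S_N_sp3"
    if el == "O":
        if 2 in orders:
            return "S_O_dbl"
        return "S_OH" if nh >= 1 else "S_O_ether"
    if el == "S":
        return "S_S"
    if el == "P":
        return "S_P"
    if el in ("F", "Cl", "Br", "I"):
        return "S_halogen"
    return None


def estate_sums(g: nx.Graph) -> dict[str, float]:
    """Atom-type E-state sums plus the whole-molecule total.

    A type with no atoms present sums to 0.0 (the descriptor is defined,
    just empty).
    """
    s = estate_values(g)
    out = {name: 0.0 for name in ESTATE_TYPES}
    total = 0.0
    for v, val in s.items():
        total += val
        t = _atom_type(g, v)
        if t is not None:
            out[t] += val
    out["S_total"] = total
    return out
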