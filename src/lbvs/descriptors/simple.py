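"""Simple (counting) molecular properties."""

from __future__ import annotations

from ..chemio import Molecule

#: Monoisotopic masses of the supported elements (u).
MONOISOTOPIC_MASS = {
    "H": 1.0078250319, "C": 12.0, "N": 14.0030740052, "O": 15.9949146221,
    "F": 18.9984031627, "P": 30.97376151, "S": 31.97207069,
    "Cl": 34.96885271, "Br": 78.9183376, "I": 126.904473,
}

HALOGENS = {"F", "Cl", "Br", "I"}


def _is_rotatable(mol: Molecule, bond, ring_bonds: set) -> bool:
    if bond.order != 1 or bond.aromatic:
        return False
    if (min(bond.i, bond.j), max(bond.i, bond.j)) in ring_bonds:
        return False
    deg = _heavy_degrees(mol)
    return deg[bond.i] >= 2 and deg[bond.j] >= 2


def _heavy_degrees(mol: Molecule) -> list[int]:
    deg = [0] * mol.n_heavy
    for b in mol.bonds:
        deg[b.i] += 1
        deg[b.j] += 1
    return deg


def _ring_bonds(mol: Molecule) -> set:
    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(range(mol.n_heavy))
    g.add_edges_from((b.i, b.j) for b in mol.bonds)
    rb = set()
    for cyc in nx.cycle_basis(g):
        for a, b in zip(cyc, cyc[1:] + cyc[:1]):
            rb.add((min(a, b), max(a, b)))
    return rb


def simple_properties(mol: Molecule) -> dict[str, float]:
    """Counting descriptors: mass, element counts, rings, donors/acceptors.

    H-bond donors are N/O atoms bearing at least one hydrogen; acceptors
    are all N/O atoms.  Rotatable bonds are acyclic single bonds between
    two heavy atoms that each have another heavy neighbor.  Ring count is
    the cyclomatic number (edges - vertices + components).
    """
    mass = 0.0
    counts = {"C": 0, "N": 0, "O": 0, "S": 0, "P": 0}
    n_hal = n_arom = donors = acceptors = 0
    n_h_total = 0
    for a in mol.atoms:
        mass += MONOISOTOPIC_MASS[a.element] + a.n_hydrogens * MONOISOTOPIC_MASS["H"]
        n_h_total += a.n_hydrogens
        if a.element in counts:
            counts[a.element] += 1
        if a.element in HALOGENS:
            n_hal += 1
        if a.aromatic:
            n_arom += 1
        if a.element in ("N", "O"):
            acceptors += 1
            if a.n_hydrogens >= 1:
                donors += 1
    n_components = 1 if mol.n_heavy else 0
    if mol.n_heavy:
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(range(mol.n_heavy))
        g.add_edges_from((b.i, b.j) for b in mol.bonds)
        n_components = nx.number_connected_components(g)
    n_rings = len(mol.bonds) - mol.n_heavy + n_components
    ring_bonds = _ring_bonds(mol)
    n_rot = sum(1 for b in mol.bonds if _is_rotatable(mol, b, ring_bonds))
    return {
        "MW": mass,
        "nHeavy": float(mol.n_heavy),
        "nC": float(counts["C"]),
        "nN": float(counts["N"]),
        "nO": float(counts["O"]),
        "nS": float(counts["S"]),
        "nP": float(counts["P"]),
        "nHalogen": float(n_hal),
        "nH": float(n_h_total),
        "nBonds": float(len(mol.bonds)),
        "nRings": float(n_rings),
        "nAromAtoms": float(n_arom),
        "nRotBonds": float(n_rot),
        "nHBD": float(donors),
        "nHBA": float(acceptors),
    }
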