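"""Small-molecule input, standardization and graph views.

Molecules enter as SMILES or V2000 SDF, are standardized (salt stripping,
charge neutralization, aromaticity re-perception) and exposed in two forms:
a plain :class:`Molecule` record (atoms, bonds, optional 3D coordinates) and
a hydrogen-suppressed :func:`heavy_graph` carrying the vertex degree ``delta``
and the Kier–Hall valence degree ``delta_v`` that every topological descriptor
consumes.

RDKit provides parsing, aromatic perception, canonicalization and the seeded
distance-geometry embedding; everything downstream works on the plain record.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Sequence

import networkx as nx
from rdkit import Chem, RDLogger
from rdkit.Chem import AllChem

logger = logging.getLogger(__name__)

RDLogger.DisableLog("rdApp.*")

#: Elements the descriptor engine knows how to type (common organic subset).
SUPPORTED_ELEMENTS = frozenset(
    {"H", "C", "N", "O", "S", "P", "F", "Cl", "Br", "I"}
)

#: Valence-electron counts used for the Kier–Hall valence degree.
VALENCE_ELECTRONS = {
    "H": 1, "C": 4, "N": 5, "O": 6, "F": 7,
    "P": 5, "S": 6, "Cl": 7, "Br": 7, "I": 7,
}

#: Principal quantum number of the valence shell (E-state intrinsic states).
PRINCIPAL_QUANTUM_NUMBER = {
    "H": 1, "C": 2, "N": 2, "O": 2, "F": 2,
    "P": 3, "S": 3, "Cl": 3, "Br": 4, "I": 5,
}


class ChemioError(ValueError):
    """Raised on unparsable input or unsupported chemistry."""


class UnsupportedElementError(ChemioError):
    """An atom falls outside the supported organic element subset."""


@dataclass(frozen=True)
class Atom:
    element: str
    formal_charge: int = 0
    n_hydrogens: int = 0
    aromatic: bool = False
    coords: tuple[float, float, float] | None = None


@dataclass(frozen=True)
class Bond:
    i: int
    j: int
    order: int  # 1, 2 or 3; aromatic bonds carry the Kekulé order
    aromatic: bool = False


@dataclass(frozen=True)
class Molecule:
    """Hydrogen-suppressed small-molecule record.

    ``atoms`` lists heavy atoms only; suppressed hydrogens are folded into
    each atom's ``n_hydrogens`` count.  If any atom carries coordinates, all
    do (enforced at construction).
    """

    id: str
    atoms: tuple[Atom, ...]
    bonds: tuple[Bond, ...]
    provenance: str = "smiles"
    smiles: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        n = len(self.atoms)
        seen: set[tuple[int, int]] = set()
        for b in self.bonds:
            if not (0 <= b.i < n and 0 <= b.j < n):
                raise ChemioError(f"{self.id}: bond endpoint out of range")
            if b.i == b.j:
                raise ChemioError(f"{self.id}: self-bond on atom {b.i}")
            key = (min(b.i, b.j), max(b.i, b.j))
            if key in seen:
                raise ChemioError(f"{self.id}: duplicate bond {key}")
            seen.add(key)
        with_xyz = sum(a.coords is not None for a in self.atoms)
        if with_xyz not in (0, n):
            raise ChemioError(f"{self.id}: partial coordinate block")

    @property
    def has_coords(self) -> bool:
        return bool(self.atoms) and self.atoms[0].coords is not None

    @property
    def n_heavy(self) -> int:
        return len(self.atoms)


def _from_rdkit(mol: Chem.Mol, mol_id: str, provenance: str) -> Molecule:
    mol = Chem.Mol(mol)
    Chem.SanitizeMol(mol)
    heavy = Chem.RemoveHs(mol)
    conf = heavy.GetConformer() if heavy.GetNumConformers() else None
    atoms = []
    for a in heavy.GetAtoms():
        xyz = None
        if conf is not None:
            p = conf.GetAtomPosition(a.GetIdx())
            xyz = (p.x, p.y, p.z)
        atoms.append(
            Atom(
                element=a.GetSymbol(),
                formal_charge=a.GetFormalCharge(),
                n_hydrogens=a.GetTotalNumHs(),
                aromatic=a.GetIsAromatic(),
                coords=xyz,
            )
        )
    kek = Chem.Mol(heavy)
    Chem.Kekulize(kek, clearAromaticFlags=True)
    bonds = []
    for b, bk in zip(heavy.GetBonds(), kek.GetBonds()):
        bonds.append(
            Bond(
                i=b.GetBeginAtomIdx(),
                j=b.GetEndAtomIdx(),
                order=int(bk.GetBondTypeAsDouble()),
                aromatic=b.GetIsAromatic(),
            )
        )
    return Molecule(
        id=mol_id,
        atoms=tuple(atoms),
        bonds=tuple(bonds),
        provenance=provenance,
        smiles=Chem.MolToSmiles(heavy),
    )


def to_rdkit(mol: Molecule) -> Chem.Mol:
    """Rebuild an RDKit molecule (hydrogens implicit) from the record."""
    em = Chem.RWMol()
    for a in mol.atoms:
        ra = Chem.Atom(a.element)
        ra.SetFormalCharge(a.formal_charge)
        ra.SetNumExplicitHs(a.n_hydrogens)
        ra.SetNoImplicit(True)
        em.AddAtom(ra)
    order_map = {1: Chem.BondType.SINGLE, 2: Chem.BondType.DOUBLE, 3: Chem.BondType.TRIPLE}
    for b in mol.bonds:
        em.AddBond(b.i, b.j, order_map[b.order])
    out = em.GetMol()
    Chem.SanitizeMol(out)
    if mol.has_coords:
        conf = Chem.Conformer(out.GetNumAtoms())
        for idx, a in enumerate(mol.atoms):
            conf.SetAtomPosition(idx, a.coords)
        out.AddConformer(conf)
    return out


def read_smiles(text: str, mol_id: str = "") -> Molecule:
    """Parse one SMILES string into a standardizable :class:`Molecule`.

    Raises :class:`ChemioError` on parse failure — never a partial record.
    """
    rd = Chem.MolFromSmiles(text)
    if rd is None:
        raise ChemioError(f"unparsable SMILES {text!r} (id={mol_id!r})")
    return _from_rdkit(rd, mol_id or text, "smiles")


def read_smiles_file(path) -> list[Molecule]:
    """One SMILES per line, optional tab-separated id; bad lines logged."""
    out: list[Molecule] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            smi = parts[0].strip()
            mol_id = parts[1].strip() if len(parts) > 1 else f"line{ln}"
            try:
                out.append(read_smiles(smi, mol_id))
            except ChemioError as exc:
                logger.warning("skipping line %d: %s", ln, exc)
    return out


def read_sdf(path) -> list[Molecule]:
    """Read a V2000 SDF; malformed records are skipped, logged and counted.

    3D coordinate blocks are preserved (an all-zero z column is treated as
    a 2D depiction and dropped).  Record order is preserved.
    """
    mols: list[Molecule] = []
    skipped = 0
    with open(path) as fh:
        if not fh.read().strip():
            return mols
    supplier = Chem.SDMolSupplier(str(path), sanitize=True, removeHs=False)
    for idx, rd in enumerate(supplier):
        if rd is None:
            skipped += 1
            logger.warning("SDF record %d in %s malformed; skipped", idx, path)
            continue
        mol_id = rd.GetProp("_Name") if rd.HasProp("_Name") and rd.GetProp("_Name") else f"mol{idx}"
        if rd.GetNumConformers():
            conf = rd.GetConformer()
            if not conf.Is3D() and all(
                abs(conf.GetAtomPosition(i).z) < 1e-8 for i in range(rd.GetNumAtoms())
            ):
                rd.RemoveAllConformers()
        mols.append(_from_rdkit(rd, mol_id, "sdf"))
    if skipped:
        logger.info("%s: %d record(s) skipped", path, skipped)
    return mols


def write_sdf(mols: Iterable[Molecule], path) -> None:
    writer = Chem.SDWriter(str(path))
    writer.SetForceV3000(False)
    for m in mols:
        rd = to_rdkit(m)
        rd.SetProp("_Name", m.id)
        if not rd.GetNumConformers():
            AllChem.Compute2DCoords(rd)
        writer.write(rd)
    writer.close()


def canonical_smiles(mol: Molecule) -> str:
    return Chem.MolToSmiles(to_rdkit(mol))


# Charge neutralization: protonation-state changes only (carboxylates,
# alkoxides, thiolates, protonated amines).  Zwitterions whose charges
# cannot be removed by a proton transfer are left intact.
_NEUTRALIZE = [
    (Chem.MolFromSmarts("[O-;$([O-][C,S,P]=O),$([O-][c,C]);!$([O-][N+])]"), +1),
    (Chem.MolFromSmarts("[S-;X1]"), +1),
    (Chem.MolFromSmarts("[N+;H1,H2,H3,H4;!$([N+][O-])]"), -1),
]


def standardize(mol: Molecule) -> Molecule:
    """Strip salts/counter-ions, neutralize protonation charges, re-perceive.

    Keeps the largest connected fragment by heavy-atom count; equal-size ties
    are broken by lexicographically smaller canonical SMILES.  Idempotent.
    Coordinates are retained only when the kept fragment is the whole input.
    """
    rd = to_rdkit(mol)
    frags = Chem.GetMolFrags(rd, asMols=True, sanitizeFrags=True)
    if len(frags) > 1:
        keyed = sorted(
            frags, key=lambda f: (-f.GetNumHeavyAtoms(), Chem.MolToSmiles(f))
        )
        rd = keyed[0]
    rw = Chem.RWMol(rd)
    for patt, delta_h in _NEUTRALIZE:
        for (aidx,) in rw.GetSubstructMatches(patt):
            a = rw.GetAtomWithIdx(aidx)
            new_h = a.GetTotalNumHs() + delta_h
            if new_h < 0:
                continue
            a.SetFormalCharge(a.GetFormalCharge() + delta_h)
            a.SetNoImplicit(True)
            a.SetNumExplicitHs(new_h)
    out = rw.GetMol()
    Chem.SanitizeMol(out)
    return _from_rdkit(out, mol.id, mol.provenance)


def embed_3d(mol: Molecule, seed: int = 2019) -> Molecule:
    """Attach seed-stable distance-geometry 3D coordinates (ETKDG + MMFF)."""
    rd = Chem.AddHs(to_rdkit(mol))
    params = AllChem.ETKDGv3()
    params.randomSeed = int(seed)
    if AllChem.EmbedMolecule(rd, params) != 0:
        raise ChemioError(f"{mol.id}: 3D embedding failed")
    try:
        AllChem.MMFFOptimizeMolecule(rd, maxIters=500)
    except Exception:  # pragma: no cover - optimization failure is non-fatal
        pass
    return _from_rdkit(rd, mol.id, mol.provenance)


def heavy_graph(mol: Molecule) -> nx.Graph:
    """Hydrogen-suppressed graph with Kier–Hall vertex attributes.

    Per vertex: ``element``, ``aromatic``, ``n_h``, ``delta`` (heavy-neighbor
    count) and ``delta_v`` = valence electrons − attached hydrogens.  Edges
    carry ``order`` and ``aromatic``.

    Raises :class:`UnsupportedElementError` for elements outside the common
    organic subset rather than producing a silently wrong ``delta_v``.
    """
    g = nx.Graph()
    for idx, a in enumerate(mol.atoms):
        if a.element not in SUPPORTED_ELEMENTS:
            raise UnsupportedElementError(
                f"{mol.id}: element {a.element!r} not supported"
            )
        zv = VALENCE_ELECTRONS[a.element]
        g.add_node(
            idx,
            element=a.element,
            aromatic=a.aromatic,
            n_h=a.n_hydrogens,
            formal_charge=a.formal_charge,
            delta_v=zv - a.n_hydrogens,
            pqn=PRINCIPAL_QUANTUM_NUMBER[a.element],
            coords=a.coords,
        )
    for b in mol.bonds:
        g.add_edge(b.i, b.j, order=b.order, aromatic=b.aromatic)
    for idx in g.nodes:
        g.nodes[idx]["delta"] = g.degree[idx]
    return g


def iter_valid(
    records: Iterable[tuple[str, str]]
) -> Iterator[Molecule]:
    """Yield standardized molecules from (smiles, id) pairs, skipping failures."""
    for smi, mol_id in records:
        try:
            yield standardize(read_smiles(smi, mol_id))
        except ChemioError as exc:
            logger.warning("%s", exc)
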