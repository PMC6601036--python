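"""Molecular descriptor engine.

A versioned :class:`DescriptorRegistry` fixes the feature-column order used
everywhere downstream.  The default registry covers four families —
simple counting properties, topological indices, connectivity chi indices,
kappa shape indices, electrotopological-state sums — plus geometric (3D)
descriptors, including the screening-relevant named descriptors Rugty
(molecular folding), Tcent (centric index), S(27) (aromatic-carbon E-state
sum) and 5chi_CH (five-membered-ring connectivity chi).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from ..chemio import Molecule, heavy_graph
from . import topology as _topo
from .estate import ESTATE_TYPES, estate_sums
from .geometry import geometric_descriptors
from .simple import simple_properties

REGISTRY_VERSION = "1.0"

#: Field-standard names for descriptors the registry must house.
NAMED_ALIASES = {
    "Rugty": "Rugty",
    "Tcent": "Tcent",
    "S(27)": "S27_arom_C",
    "5chi_CH": "Chi5CH",
}


@dataclass(frozen=True)
class RegistryEntry:
    name: str
    family: str  # simple | topological | connectivity | shape | estate | geometric
    requires_3d: bool = False


def _default_entries() -> tuple[RegistryEntry, ...]:
    entries: list[RegistryEntry] = []
    for name in (
        "MW", "nHeavy", "nC", "nN", "nO", "nS", "nP", "nHalogen", "nH",
        "nBonds", "nRings", "nAromAtoms", "nRotBonds", "nHBD", "nHBA",
    ):
        entries.append(RegistryEntry(name, "simple"))
    for name in ("Wiener", "Tcent", "ZagrebM1", "ZagrebM2", "Platt",
                 "Radius", "Diameter"):
        entries.append(RegistryEntry(name, "topological"))
    for m in range(7):
        entries.append(RegistryEntry(f"Chi{m}", "connectivity"))
    for m in range(7):
        entries.append(RegistryEntry(f"Chi{m}v", "connectivity"))
    for m in range(3, 7):
        entries.append(RegistryEntry(f"Chi{m}c", "connectivity"))
    for m in range(3, 7):
        entries.append(RegistryEntry(f"Chi{m}cv", "connectivity"))
    for m in range(3, 7):
        entries.append(RegistryEntry(f"Chi{m}CH", "connectivity"))
    for m in range(3, 7):
        entries.append(RegistryEntry(f"Chi{m}CHv", "connectivity"))
    for name in ("Kappa1", "Kappa2", "Kappa3", "KappaA1", "KappaA2", "KappaA3"):
        entries.append(RegistryEntry(name, "shape"))
    for name in ESTATE_TYPES:
        entries.append(RegistryEntry(name, "estate"))
    entries.append(RegistryEntry("S_total", "estate"))
    for name in ("Rugty", "Rgyr", "Span3D", "SASArea", "SASVolume"):
        entries.append(RegistryEntry(name, "geometric", requires_3d=True))
    return tuple(entries)


@dataclass(frozen=True)
class DescriptorRegistry:
    """Ordered, versioned descriptor list defining feature-column order."""

    entries: tuple[RegistryEntry, ...] = field(default_factory=_default_entries)
    version: str = REGISTRY_VERSION

    def __post_init__(self) -> None:
        names = [e.name for e in self.entries]
        if len(names) != len(set(names)):
            raise ValueError("duplicate descriptor names in registry")
        for alias, name in NAMED_ALIASES.items():
            if name not in names:
                raise ValueError(f"registry missing mandatory descriptor {alias}")

    @property
    def names(self) -> list[str]:
        return [e.name for e in self.entries]

    def __len__(self) -> int:
        return len(self.entries)

    def index(self, name: str) -> int:
        return self.names.index(NAMED_ALIASES.get(name, name))


DEFAULT_REGISTRY = DescriptorRegistry()


@dataclass
class DescriptorVector:
    """One molecule's feature row, aligned to a registry."""

    mol_id: str
    values: np.ndarray          # float, NaN where masked
    mask: np.ndarray            # True = missing
    registry_version: str = REGISTRY_VERSION

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.shape != self.mask.shape:
            raise ValueError("values/mask length mismatch")
        live = self.values[~self.mask]
        if live.size and not np.all(np.isfinite(live)):
            raise ValueError(f"{self.mol_id}: non-finite unmasked descriptor value")


class DescriptorError(ValueError):
    pass


def compute_all(
    mol: Molecule, registry: DescriptorRegistry = DEFAULT_REGISTRY
) -> DescriptorVector:
    """Fill every registry entry for one standardized molecule.

    Geometric entries are masked when the molecule has no coordinates;
    degenerate shape indices (tiny molecules) are masked, never raised.
    """
    try:
        g = heavy_graph(mol)
        vals: dict[str, float | None] = {}
        vals.update(simple_properties(mol))
        vals["Wiener"] = float(_topo.wiener_index(g))
        vals["Tcent"] = float(_topo.centric_index(g))
        vals["ZagrebM1"] = float(_topo.zagreb_m1(g))
        vals["ZagrebM2"] = float(_topo.zagreb_m2(g))
        vals["Platt"] = float(_topo.platt_number(g))
        vals["Radius"] = float(_topo.graph_radius(g))
        vals["Diameter"] = float(_topo.graph_diameter(g))
        for m in range(7):
            vals[f"Chi{m}"] = _topo.chi_path(g, m, valence=False)
            vals[f"Chi{m}v"] = _topo.chi_path(g, m, valence=True)
        for m in range(3, 7):
            vals[f"Chi{m}c"] = _topo.chi_cluster(g, m, valence=False)
            vals[f"Chi{m}cv"] = _topo.chi_cluster(g, m, valence=True)
            vals[f"Chi{m}CH"] = _topo.chi_chain(g, m, valence=False)
            vals[f"Chi{m}CHv"] = _topo.chi_chain(g, m, valence=True)
        for alpha, tag in ((False, ""), (True, "A")):
            kk = _topo.kappa_indices(g, alpha=alpha)
            for order in (1, 2, 3):
                vals[f"Kappa{tag}{order}"] = kk[f"k{order}"]
        vals.update(estate_sums(g))
        if mol.has_coords:
            vals.update(
                geometric_descriptors(
                    [a.element for a in mol.atoms],
                    [a.coords for a in mol.atoms],
                )
            )
    except Exception as exc:
        raise DescriptorError(f"descriptor computation failed for {mol.id}: {exc}") from exc

    values = np.full(len(registry), np.nan)
    mask = np.ones(len(registry), dtype=bool)
    for idx, entry in enumerate(registry.entries):
        v = vals.get(entry.name)
        if v is None:
            continue
        values[idx] = float(v)
        mask[idx] = False
    return DescriptorVector(mol.id, values, mask, registry.version)


def descriptor_table(
    mols: Iterable[Molecule], registry: DescriptorRegistry = DEFAULT_REGISTRY
) -> pd.DataFrame:
    """DataFrame of descriptor rows (index = molecule id, NaN = masked)."""
    rows, ids = [], []
    for m in mols:
        dv = compute_all(m, registry)
        rows.append(np.where(dv.mask, np.nan, dv.values))
        ids.append(dv.mol_id)
    return pd.DataFrame(rows, index=pd.Index(ids, name="id"), columns=registry.names)


def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, na_rep="")


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, index_col="id")
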