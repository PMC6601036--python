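"""Geometric descriptors from 3D coordinates (united-atom representation).

Hydrogens are folded into their heavy atoms, so united-atom van der Waals
radii are used.  Surface area is estimated with Shrake–Rupley sphere
sampling on a deterministic Fibonacci point set; volume with a cubic grid.
Rugosity ("Rugty", molecular folding) is the solvent-accessible surface
area divided by the surface area of the sphere of equal solvent-accessible
volume — 1.0 for a single sphere, growing as the surface folds.
"""

from __future__ import annotations

import math

import numpy as np

#: United-atom van der Waals radii (Angstrom).
VDW_RADII = {
    "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80,
    "F": 1.47, "Cl": 1.75, "Br": 1.85, "I": 1.98, "H": 1.20,
}

PROBE_RADIUS = 1.4   # water probe, Angstrom
GRID_SPACING = 0.4   # volume grid, Angstrom
N_SPHERE_POINTS = 256


def _fibonacci_sphere(n: int) -> np.ndarray:
    i = np.arange(n, dtype=float)
    phi = math.pi * (3.0 - math.sqrt(5.0))
    z = 1.0 - 2.0 * (i + 0.5) / n
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, 1.0))
    return np.column_stack([r * np.cos(phi * i), r * np.sin(phi * i), z])


def accessible_surface_area(
    coords: np.ndarray,
    radii: np.ndarray,
    probe: float = PROBE_RADIUS,
    n_points: int = N_SPHERE_POINTS,
) -> float:
    """Shrake–Rupley solvent-accessible surface area (Angstrom^2)."""
    coords = np.asarray(coords, dtype=float)
    rr = np.asarray(radii, dtype=float) + probe
    unit = _fibonacci_sphere(n_points)
    area = 0.0
    for i in range(len(coords)):
        pts = coords[i] + rr[i] * unit
        exposed = np.ones(n_points, dtype=bool)
        for j in range(len(coords)):
            if j == i:
                continue
            d2 = np.sum((pts - coords[j]) ** 2, axis=1)
            exposed &= d2 > rr[j] ** 2
        area += 4.0 * math.pi * rr[i] ** 2 * exposed.mean()
    return float(area)


def accessible_volume(
    coords: np.ndarray,
    radii: np.ndarray,
    probe: float = PROBE_RADIUS,
    spacing: float = GRID_SPACING,
) -> float:
    """Grid-counted solvent-accessible volume (Angstrom^3)."""
    coords = np.asarray(coords, dtype=float)
    rr = np.asarray(radii, dtype=float) + probe
    lo = (coords - rr[:, None]).min(axis=0) - spacing
    hi = (coords + rr[:, None]).max(axis=0) + spacing
    axes = [np.arange(lo[k] + spacing / 2.0, hi[k], spacing) for k in range(3)]
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    pts = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
    inside = np.zeros(len(pts), dtype=bool)
    for i in range(len(coords)):
        d2 = np.sum((pts - coords[i]) ** 2, axis=1)
        inside |= d2 <= rr[i] ** 2
    return float(inside.sum()) * spacing**3


def rugosity(
    coords: np.ndarray,
    radii: np.ndarray,
    probe: float = PROBE_RADIUS,
    spacing: float = GRID_SPACING,
    n_points: int = N_SPHERE_POINTS,
) -> float:
    """Surface area over the equal-volume sphere's surface area (>= ~1)."""
    area = accessible_surface_area(coords, radii, probe, n_points)
    vol = accessible_volume(coords, radii, probe, spacing)
    r_eq = (3.0 * vol / (4.0 * math.pi)) ** (1.0 / 3.0)
    return area / (4.0 * math.pi * r_eq**2)


def geometric_descriptors(elements, coords) -> dict[str, float]:
    """All 3D descriptors for one molecule (coords in Angstrom)."""
    coords = np.asarray(coords, dtype=float)
    radii = np.array([VDW_RADII[e] for e in elements])
    centroid = coords.mean(axis=0)
    centered = coords - centroid
    rgyr = float(np.sqrt((centered**2).sum(axis=1).mean()))
    if len(coords) > 1:
        from scipy.spatial.distance import pdist

        span = float(pdist(coords).max())
    else:
        span = 0.0
    area = accessible_surface_area(coords, radii)
    vol = accessible_volume(coords, radii)
    r_eq = (3.0 * vol / (4.0 * math.pi)) ** (1.0 / 3.0)
    return {
        "Rugty": area / (4.0 * math.pi * r_eq**2),
        "Rgyr": rgyr,
        "Span3D": span,
        "SASArea": area,
        "SASVolume": vol,
    }
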