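"""Dot-surface (Shrake-Rupley style) accessibility engine.

One core routine serves both the plain SASA order parameter and the
hydrophobic-patch analysis: dots are scattered on the solvent-accessible
sphere of each selected atom and a dot survives iff it lies outside every
other atom's accessible sphere.  Occluder spheres can be inflated per atom
(the polar-expansion trick used for hydrophobic patches).
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree

from ._geometry import fibonacci_sphere

MIN_DOT_DENSITY = 32


def accessible_dots(
    positions: np.ndarray,
    radii: np.ndarray,
    probe_radius: float = 0.14,
    dot_density: int = 960,
    generate_mask: np.ndarray | None = None,
    occluder_extra: np.ndarray | None = None,
):
    """Per-atom surviving surface dots.

    Parameters
    ----------
    positions, radii : (n, 3) and (n,) arrays in nm.
    probe_radius : solvent probe radius added to every sphere (nm).
    dot_density : dots per atom (>= 32; quadrature error ~1/n).
    generate_mask : dots are generated only for these atoms (default all).
    occluder_extra : extra inflation of each atom's *occluding* sphere (nm);
        used to mask nonpolar surface adjacent to polar atoms.

    Returns
    -------
    areas : (n,) per-atom accessible area (nm^2), zero for non-generated atoms.
    dot_counts : (n,) surviving dot counts.
    """
    positions = np.asarray(positions, dtype=float)
    radii = np.asarray(radii, dtype=float)
    n = positions.shape[0]
    if dot_density < MIN_DOT_DENSITY:
        raise ValueError(f"dot_density must be >= {MIN_DOT_DENSITY} for a usable quadrature")
    if probe_radius < 0:
        raise ValueError("probe_radius must be non-negative")
    if np.any(~np.isfinite(radii)) or np.any(radii <= 0):
        bad = int(np.flatnonzero(~np.isfinite(radii) | (radii <= 0))[0])
        raise ValueError(f"atom {bad} has no valid vdW radius")
    if generate_mask is None:
        generate_mask = np.ones(n, dtype=bool)
    if occluder_extra is None:
        occluder_extra = np.zeros(n, dtype=float)

    unit = fibonacci_sphere(dot_density)
    occ_radii = radii + probe_radius + occluder_extra
    tree = cKDTree(positions)
    max_occ = float(occ_radii.max())

    areas = np.zeros(n, dtype=float)
    counts = np.zeros(n, dtype=int)
    for i in np.flatnonzero(generate_mask):
        r = radii[i] + probe_radius
        dots = positions[i] + r * unit
        neigh = [j for j in tree.query_ball_point(positions[i], r + max_occ) if j != i]
        alive = np.ones(dot_density, dtype=bool)
        for j in neigh:
            d2 = ((dots - positions[j]) ** 2).sum(axis=1)
            alive &= d2 > occ_radii[j] ** 2
        counts[i] = int(alive.sum())
        areas[i] = 4.0 * np.pi * r * r * counts[i] / dot_density
    return areas, counts
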