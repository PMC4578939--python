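"""Contiguous exposed hydrophobic surface patches.

A dot surface is generated on nonpolar atoms only, with every polar atom's
occluding sphere inflated by a *polar expansion radius* (default 0.14 nm)
so that nonpolar surface immediately adjacent to polar atoms is masked
out.  Exposed nonpolar atoms are then clustered into contiguous patches by
accessible-sphere overlap, patches ranked by area, filtered at a
significance threshold (default 300 A^2, top five), and patch area can be
attributed to secondary-structure transition events (the EHSC breakdown).

Areas are reported in A^2, the unit surface-hydrophobicity results are
conventionally quoted in; coordinates stay in nm internally.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from ._dots import accessible_dots
from .order_parameters import sasa
from .secondary_structure import EVENT_CLASSES
from .structure_io import Structure

__all__ = [
    "Patch",
    "PatchSet",
    "hydrophobic_dot_surface",
    "find_patches",
    "significant_patches",
    "total_surface_hydrophobicity",
    "exposed_ivl_count",
    "ehsc",
    "motif_exposure",
    "write_patch_report",
]

NM2_TO_A2 = 100.0
DEFAULT_POLAR_EXPANSION = 0.14  # nm
DEFAULT_PROBE = 0.14  # nm (water)
SIGNIFICANCE_AREA_A2 = 300.0
TOP_K = 5
IVL = {"ILE", "VAL", "LEU"}


@dataclass
class Patch:
    atoms: tuple  # member atom indices
    residues: tuple  # contributing residue indices (internal, 0-based)
    area: float  # A^2
    residue_areas: dict  # residue index -> A^2

    def __post_init__(self):
        if self.area <= 0:
            raise ValueError("a patch must have positive area")
        total = sum(self.residue_areas.values())
        if abs(total - self.area) > 1e-6 * max(self.area, 1.0):
            raise ValueError("per-residue contributions do not sum to the patch area")


@dataclass
class PatchSet:
    patches: list  # sorted by descending area
    significance_threshold: float = SIGNIFICANCE_AREA_A2
    top_k: int = TOP_K
    params: dict = field(default_factory=dict)

    def __len__(self):
        return len(self.patches)

    @property
    def areas(self) -> np.ndarray:
        return np.array([p.area for p in self.patches])


def hydrophobic_dot_surface(structure: Structure, coords: np.ndarray | None = None,
                            probe_radius: float = DEFAULT_PROBE,
                            polar_expansion: float = DEFAULT_POLAR_EXPANSION,
                            dot_density: int = 960):
    """Accessible dot areas for nonpolar atoms under polar expansion.

    Returns ``(areas_nm2, dot_counts)`` over all atoms (zero for polar
    atoms, which generate no dots but occlude with inflated spheres).
    """
    positions = structure.coords if coords is None else np.asarray(coords, float)
    nonpolar = structure.nonpolar_mask
    extra = np.where(nonpolar, 0.0, polar_expansion)
    return accessible_dots(
        positions, structure.radii, probe_radius, dot_density,
        generate_mask=nonpolar, occluder_extra=extra,
    )


def find_patches(structure: Structure, coords: np.ndarray | None = None,
                 probe_radius: float = DEFAULT_PROBE,
                 polar_expansion: float = DEFAULT_POLAR_EXPANSION,
                 dot_density: int = 960,
                 significance_threshold: float = SIGNIFICANCE_AREA_A2,
                 top_k: int = TOP_K) -> PatchSet:
    """Contiguous hydrophobic patches of one conformer.

    Exposed nonpolar atoms (>= 1 surviving dot) are graph nodes; two atoms
    are adjacent when their accessible spheres overlap
    (``d < r_i + r_j + 2 * probe``); patches are the connected components,
    each carrying per-residue area contributions.
    """
    positions = structure.coords if coords is None else np.asarray(coords, float)
    areas_nm2, counts = hydrophobic_dot_surface(
        structure, positions, probe_radius, polar_expansion, dot_density
    )
    exposed = np.flatnonzero(counts > 0)
    patches: list[Patch] = []
    if exposed.size:
        pos = positions[exposed]
        radii = structure.radii[exposed]
        tree = cKDTree(pos)
        rows, cols = [], []
        rmax = float(radii.max())
        for a in range(exposed.size):
            for b in tree.query_ball_point(pos[a], radii[a] + rmax + 2 * probe_radius):
                if b <= a:
                    continue
                if np.linalg.norm(pos[a] - pos[b]) < radii[a] + radii[b] + 2 * probe_radius:
                    rows.append(a)
                    cols.append(b)
        adj = csr_matrix(
            (np.ones(len(rows)), (rows, cols)), shape=(exposed.size, exposed.size)
        )
        n_comp, labels = connected_components(adj, directed=False)
        for c in range(n_comp):
            members = exposed[labels == c]
            res_areas: dict[int, float] = {}
            for i in members:
                r = structure.atoms[i].residue_index
                res_areas[r] = res_areas.get(r, 0.0) + areas_nm2[i] * NM2_TO_A2
            area = float(sum(res_areas.values()))
            if area <= 0:
                continue
            patches.append(
                Patch(
                    atoms=tuple(int(i) for i in members),
                    residues=tuple(sorted(res_areas)),
                    area=area,
                    residue_areas=res_areas,
                )
            )
    patches.sort(key=lambda p: -p.area)
    return PatchSet(
        patches=patches,
        significance_threshold=significance_threshold,
        top_k=top_k,
        params={
            "probe_radius_nm": probe_radius,
            "polar_expansion_nm": polar_expansion,
            "dot_density": dot_density,
        },
    )


def significant_patches(patch_set: PatchSet) -> PatchSet:
    """Top-k patches by area, then filtered to the significance threshold."""
    top = patch_set.patches[: patch_set.top_k]
    keep = [p for p in top if p.area >= patch_set.significance_threshold]
    return PatchSet(
        patches=keep,
        significance_threshold=patch_set.significance_threshold,
        top_k=patch_set.top_k,
        params=dict(patch_set.params),
    )


def total_surface_hydrophobicity(patch_set: PatchSet) -> float:
    """Sum of significant patch areas (A^2)."""
    return float(significant_patches(patch_set).areas.sum())


def exposed_ivl_count(patch_set: PatchSet, structure: Structure) -> int:
    """Distinct Ile/Val/Leu residues contributing area to any significant
    patch (the chaperone-recognition cluster count)."""
    res_names = {r.index: r.name for r in structure.residues}
    hit = set()
    for p in significant_patches(patch_set).patches:
        for r, a in p.residue_areas.items():
            if a > 0 and res_names.get(r) in IVL:
                hit.add(r)
    return len(hit)


def ehsc(patch_set: PatchSet, events) -> dict:
    """Exposed Hydrophobic Surface Contribution per transition-event class.

    ``events`` maps residue index -> event class (or is the events table
    from :func:`~foldscape.secondary_structure.classify_transition_events`).
    Fractions are class area totals over the significant-patch grand total.
    """
    if isinstance(events, pd.DataFrame):
        events = dict(zip(events["residue"], events["event"]))
    totals = {c: 0.0 for c in EVENT_CLASSES}
    for p in significant_patches(patch_set).patches:
        for r, a in p.residue_areas.items():
            if r not in events:
                raise KeyError(f"no transition event recorded for residue {r}")
            totals[events[r]] += a
    grand = sum(totals.values())
    if grand <= 0:
        raise ValueError("zero significant patch area; EHSC undefined")
    return {c: totals[c] / grand for c in EVENT_CLASSES}


def motif_exposure(structure: Structure, motifs: dict,
                   coords: np.ndarray | None = None,
                   probe_radius: float = DEFAULT_PROBE,
                   dot_density: int = 960) -> float:
    """Mean accessible area per residue (A^2) over explicit motif residue
    sets (e.g. GroES-like binding motifs supplied as index lists)."""
    all_res = [r for residues in motifs.values() for r in residues]
    if not all_res:
        raise ValueError("no motif residues supplied")
    _, per_atom = sasa(structure, coords, probe_radius, dot_density)
    wanted = set(all_res)
    total = sum(
        per_atom[a.index] for a in structure.atoms if a.residue_index in wanted
    )
    return float(total * NM2_TO_A2 / len(all_res))


def write_patch_report(patch_set: PatchSet, patch_tsv, residue_tsv=None) -> None:
    rows = [
        {
            "patch_id": k,
            "area_A2": p.area,
            "n_atoms": len(p.atoms),
            "residues": ",".join(str(r) for r in p.residues),
        }
        for k, p in enumerate(patch_set.patches)
    ]
    pd.DataFrame(rows, columns=["patch_id", "area_A2", "n_atoms", "residues"]).to_csv(
        patch_tsv, sep="\t", index=False, float_format="%.3f"
    )
    if residue_tsv is not None:
        rrows = [
            {"patch_id": k, "residue": r, "area_A2": a}
            for k, p in enumerate(patch_set.patches)
            for r, a in sorted(p.residue_areas.items())
        ]
        pd.DataFrame(rrows, columns=["patch_id", "residue", "area_A2"]).to_csv(
            residue_tsv, sep="\t", index=False, float_format="%.3f"
        )
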