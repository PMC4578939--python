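"""Hydrogen-bond counting and HDX-protection concordance scoring.

The geometric criterion is donor-acceptor distance <= 0.35 nm plus, when
explicit hydrogens exist, an H-D-A angle <= 30 degrees; heavy-atom-only
structures fall back to the distance term alone.  Protein-solvent counts
per peptide segment are the simulation surrogate for amide protection in
HDX-MS: stably bonded (well-protected) segments make fewer bonds to water.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .structure_io import Structure, Trajectory

__all__ = [
    "HBondCriterion",
    "SegmentHBondReport",
    "count_protein_solvent_hbonds",
    "normalized_segment_hbonds",
    "count_mainchain_hbonds",
    "protection_concordance",
    "read_segments",
]


@dataclass(frozen=True)
class HBondCriterion:
    distance_cutoff: float = 0.35  # nm, donor-acceptor
    angle_cutoff: float = 30.0  # degrees, H-D-A; ignored without hydrogens

    def __post_init__(self):
        if self.distance_cutoff <= 0:
            raise ValueError("distance cutoff must be positive")


@dataclass
class SegmentHBondReport:
    segment_id: str
    start_residue: int  # internal 0-based, inclusive
    end_residue: int  # inclusive
    protection_class: str  # 'more' | 'less' | 'unknown'
    mean_count: float
    sd_count: float
    normalized_mean: float | None = None  # None => segment excluded (< 7 residues)


def _polar_atoms(structure: Structure, residue_indices) -> list[int]:
    residue_indices = set(residue_indices)
    return [
        a.index
        for a in structure.atoms
        if a.residue_index in residue_indices
        and not a.is_hydrogen
        and a.element.upper() in ("N", "O")
    ]


def _hydrogens_by_parent(structure: Structure) -> dict[int, list[int]]:
    """Hydrogen atom indices keyed by their bonded heavy atom (nearest
    heavy atom of the same residue)."""
    out: dict[int, list[int]] = {}
    by_res: dict[int, list] = {}
    for a in structure.atoms:
        by_res.setdefault(a.residue_index, []).append(a)
    for atoms in by_res.values():
        heavies = [a for a in atoms if not a.is_hydrogen]
        for h in atoms:
            if not h.is_hydrogen or not heavies:
                continue
            d = [np.linalg.norm(h.position - a.position) for a in heavies]
            out.setdefault(heavies[int(np.argmin(d))].index, []).append(h.index)
    return out


def _unique_positions(coords: np.ndarray, indices: list[int]) -> list[int]:
    """Drop records duplicating an identical position (counts are a function
    of the geometry set, not record multiplicity)."""
    seen = set()
    keep = []
    for i in indices:
        key = tuple(np.round(coords[i], 7))
        if key not in seen:
            seen.add(key)
            keep.append(i)
    return keep


def _count_pairs_frame(coords: np.ndarray, structure: Structure,
                       idx_a: list[int], idx_b: list[int],
                       criterion: HBondCriterion,
                       h_parent: dict[int, list[int]]) -> int:
    """Unordered donor/acceptor pairs between the two polar-atom groups."""
    idx_a = _unique_positions(coords, idx_a)
    idx_b = _unique_positions(coords, idx_b)
    if not idx_a or not idx_b:
        return 0
    pa = coords[idx_a]
    pb = coords[idx_b]
    d = np.sqrt(((pa[:, None, :] - pb[None, :, :]) ** 2).sum(-1))
    close = np.argwhere(d <= criterion.distance_cutoff)
    has_h = any(a.is_hydrogen for a in structure.atoms)
    count = 0
    for ia, ib in close:
        a, b = idx_a[ia], idx_b[ib]
        if a == b:
            continue
        if not has_h:
            count += 1
            continue
        # angle test: some hydrogen on either partner within the H-D-A cone
        good = False
        for donor, acceptor in ((a, b), (b, a)):
            for h in h_parent.get(donor, []):
                v1 = coords[h] - coords[donor]
                v2 = coords[acceptor] - coords[donor]
                cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
                ang = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
                if ang <= criterion.angle_cutoff:
                    good = True
                    break
            if good:
                break
        count += bool(good)
    return count


def count_protein_solvent_hbonds(trajectories, segment_residues,
                                 criterion: HBondCriterion = HBondCriterion()):
    """Mean +/- sd of per-frame H-bond counts between a peptide segment and
    solvent.

    With a single trajectory the sd is across frames; with several, the
    mean is the average of per-trajectory means and the sd is across
    trajectories (matching error bars over independent runs).
    """
    if isinstance(trajectories, Trajectory):
        trajectories = [trajectories]
    per_traj_means = []
    all_counts = []
    for traj in trajectories:
        structure = traj.topology
        waters = {r.index for r in structure.residues if r.is_water}
        if not waters:
            raise ValueError("topology contains no solvent molecules")
        seg_atoms = _polar_atoms(structure, segment_residues)
        wat_atoms = _polar_atoms(structure, waters)
        h_parent = _hydrogens_by_parent(structure)
        counts = [
            _count_pairs_frame(f, structure, seg_atoms, wat_atoms, criterion, h_parent)
            for f in traj.frames
        ]
        per_traj_means.append(float(np.mean(counts)))
        all_counts.extend(counts)
    if len(per_traj_means) == 1:
        return per_traj_means[0], float(np.std(all_counts))
    return float(np.mean(per_traj_means)), float(np.std(per_traj_means))


def terminal_residues(segment_residues, n_front: int = 4, n_back: int = 3):
    """The 7 terminal residues of a segment (first 4 + last 3).

    Segments shorter than 7 residues are excluded (returns ``None``): with
    fewer residues the front and back windows overlap and the
    length-normalization rationale collapses.
    """
    seg = list(segment_residues)
    if len(seg) < n_front + n_back:
        return None
    return seg[:n_front] + seg[-n_back:]


def normalized_segment_hbonds(trajectories, segment_residues,
                              criterion: HBondCriterion = HBondCriterion(),
                              n_front: int = 4, n_back: int = 3):
    """Protein-solvent count restricted to the segment's terminal residues;
    ``(None, None)`` marks an excluded (short) segment."""
    chosen = terminal_residues(segment_residues, n_front, n_back)
    if chosen is None:
        return None, None
    return count_protein_solvent_hbonds(trajectories, chosen, criterion)


def count_mainchain_hbonds(structure: Structure, coords: np.ndarray | None = None,
                           criterion: HBondCriterion = HBondCriterion(),
                           min_separation: int = 2) -> int:
    """Intra-molecular backbone N-H...O=C bonds in one frame.

    Pairs closer than ``min_separation`` in sequence are skipped: the
    peptide geometry itself puts O(i) within bonding distance of N(i+1).
    Unlike solvent bonds, the backbone amide hydrogen is always available:
    when the structure carries none it is reconstructed in the peptide
    plane (trans to the preceding carbonyl oxygen), so the angle term
    applies in both modes and distance-only shadows such as the helical
    N(i+3)...O(i) approach are rejected.
    """
    coords = structure.coords if coords is None else np.asarray(coords, float)
    res = structure.protein_residues()
    n_idx, o_idx, c_idx = {}, {}, {}
    chain_of = {r.index: r.chain_id for r in res}
    for a in structure.atoms:
        if a.name == "N":
            n_idx[a.residue_index] = a.index
        elif a.name == "O":
            o_idx[a.residue_index] = a.index
        elif a.name == "C":
            c_idx[a.residue_index] = a.index
    h_parent = _hydrogens_by_parent(structure)

    def amide_h(ri: int) -> np.ndarray | None:
        if ri in n_idx and h_parent.get(n_idx[ri]):
            return coords[h_parent[n_idx[ri]][0]]
        prev = ri - 1
        if prev in c_idx and prev in o_idx and chain_of.get(prev) == chain_of.get(ri):
            co = coords[c_idx[prev]] - coords[o_idx[prev]]
            norm = np.linalg.norm(co)
            if norm > 0:
                return coords[n_idx[ri]] + 0.1 * co / norm  # 0.1 nm N-H
        return None

    count = 0
    for ri in res:
        hpos = amide_h(ri.index) if ri.index in n_idx else None
        if hpos is None:
            continue
        ni = n_idx[ri.index]
        for rj in res:
            if abs(ri.index - rj.index) < min_separation or rj.index not in o_idx:
                continue
            oj = o_idx[rj.index]
            if np.linalg.norm(coords[ni] - coords[oj]) > criterion.distance_cutoff:
                continue
            v1 = hpos - coords[ni]
            v2 = coords[oj] - coords[ni]
            cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
            if np.degrees(np.arccos(np.clip(cosang, -1, 1))) <= criterion.angle_cutoff:
                count += 1
    return count


def protection_concordance(reports: list[SegmentHBondReport]) -> dict:
    """Summary of H-bond counts against HDX protection classes.

    Concordance counts the less-protected segments whose mean strictly
    exceeds the more-protected class mean (the expected direction: weakly
    protected regions hydrogen-bond more with water).
    """
    more = [r.mean_count for r in reports if r.protection_class == "more"]
    less = [r.mean_count for r in reports if r.protection_class == "less"]
    if not more or not less:
        raise ValueError("need at least one segment in each protection class")
    mean_more = float(np.mean(more))
    mean_less = float(np.mean(less))
    n_above = int(sum(v > mean_more for v in less))
    return {
        "mean_more": mean_more,
        "mean_less": mean_less,
        "n_less_above_more_mean": n_above,
        "n_less_total": len(less),
    }


def read_segments(path) -> pd.DataFrame:
    """BED-like segment table: segment_id, start_residue, end_residue,
    protection_class (tab-separated, header allowed)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    expected = {"segment_id", "start_residue", "end_residue", "protection_class"}
    if not expected.issubset(df.columns):
        raise ValueError(f"segment table needs columns {sorted(expected)}")
    return df
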