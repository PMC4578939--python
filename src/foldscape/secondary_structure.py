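"""Secondary-structure assignment, propensities and transition events.

Assignment follows the Kabsch-Sander electrostatic hydrogen-bond model:

    E_hb = 0.084 * 332 * (1/r_ON + 1/r_CH - 1/r_OH - 1/r_CN)   [kcal/mol]

with a bond when E_hb < -0.5 kcal/mol; the amide hydrogen is reconstructed
geometrically when the structure carries none.  Helices come from pairs of
consecutive n-turns, strands from bridge patterns; the 8-state alphabet is
reduced to three classes (H, G, I -> H;  E, B -> E;  else C), which is the
granularity at which unfolding transitions are classified.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._geometry import dihedral
from .structure_io import Structure, Trajectory

__all__ = [
    "assign_secondary_structure",
    "assignment_series",
    "propensity",
    "classify_transition_events",
    "dihedral_series",
    "reference_assignment",
    "EVENT_CLASSES",
]

HB_ENERGY_CUTOFF = -0.5  # kcal/mol
HB_FACTOR = 0.084 * 332.0  # kcal/mol * A

EVENT_CLASSES = (
    "alpha_to_coil",
    "beta_to_coil",
    "coil_to_beta",
    "alpha_to_beta",
    "unchanged",
)

_EVENT_MAP = {
    ("H", "C"): "alpha_to_coil",
    ("E", "C"): "beta_to_coil",
    ("C", "E"): "coil_to_beta",
    ("H", "E"): "alpha_to_beta",
}


def _backbone_arrays(structure: Structure, coords: np.ndarray):
    """Per protein residue: chain id and backbone positions (nm -> A).

    Residues missing any of N, CA, C, O are flagged and end up as coil.
    """
    res = structure.protein_residues()
    n = len(res)
    pos = {name: np.full((n, 3), np.nan) for name in ("N", "CA", "C", "O", "H")}
    chain = []
    for k, r in enumerate(res):
        chain.append(r.chain_id)
        for a in structure.atoms:
            if a.residue_index != r.index:
                continue
            if a.name in ("N", "CA", "C", "O"):
                pos[a.name][k] = coords[a.index] * 10.0  # nm -> A
            elif a.name in ("H", "HN"):
                pos["H"][k] = coords[a.index] * 10.0
    ok = ~np.isnan(pos["N"]).any(1) & ~np.isnan(pos["CA"]).any(1) \
        & ~np.isnan(pos["C"]).any(1) & ~np.isnan(pos["O"]).any(1)
    return res, chain, pos, ok


def _reconstruct_amide_h(pos, chain, ok):
    """Place missing amide hydrogens 1.0 A from N, opposite the previous
    residue's C=O direction (the classical DSSP reconstruction)."""
    n = pos["N"].shape[0]
    for i in range(1, n):
        if not (ok[i] and ok[i - 1]) or chain[i] != chain[i - 1]:
            continue
        if not np.isnan(pos["H"][i]).any():
            continue
        co = pos["C"][i - 1] - pos["O"][i - 1]
        norm = np.linalg.norm(co)
        if norm > 0:
            pos["H"][i] = pos["N"][i] + co / norm


def _hbond_matrix(pos, chain, ok) -> np.ndarray:
    """HB[i, j] True iff CO(i) accepts an H-bond from NH(j)."""
    n = pos["N"].shape[0]
    hb = np.zeros((n, n), dtype=bool)
    ca = pos["CA"]
    for j in range(n):  # donor NH(j)
        if not ok[j] or np.isnan(pos["H"][j]).any():
            continue
        for i in range(n):  # acceptor CO(i)
            if i == j or not ok[i]:
                continue
            if chain[i] == chain[j] and abs(i - j) < 2:
                continue
            if np.linalg.norm(ca[i] - ca[j]) > 9.0:  # DSSP distance screen
                continue
            r_on = np.linalg.norm(pos["O"][i] - pos["N"][j])
            r_ch = np.linalg.norm(pos["C"][i] - pos["H"][j])
            r_oh = np.linalg.norm(pos["O"][i] - pos["H"][j])
            r_cn = np.linalg.norm(pos["C"][i] - pos["N"][j])
            if min(r_on, r_ch, r_oh, r_cn) < 0.5:
                energy = -9.9
            else:
                energy = HB_FACTOR * (1.0 / r_on + 1.0 / r_ch - 1.0 / r_oh - 1.0 / r_cn)
            hb[i, j] = energy < HB_ENERGY_CUTOFF
    return hb


def assign_secondary_structure(structure: Structure,
                               coords: np.ndarray | None = None) -> np.ndarray:
    """Per-residue 3-state labels ('H', 'E', 'C') for one frame.

    Helices (alpha, 3-10, pi) require two consecutive n-turns; strands are
    residues participating in parallel or antiparallel bridges.  Helix
    assignment takes priority over strand.  Chains shorter than three
    residues and residues with incomplete backbones are coil.
    """
    coords = structure.coords if coords is None else np.asarray(coords, float)
    res, chain, pos, ok = _backbone_arrays(structure, coords)
    n = len(res)
    labels = np.full(n, "C", dtype="<U1")
    if n == 0:
        return labels
    chain_sizes = {c: chain.count(c) for c in set(chain)}
    small = np.array([chain_sizes[c] < 3 for c in chain])
    _reconstruct_amide_h(pos, chain, ok)
    hb = _hbond_matrix(pos, chain, ok)

    same_chain = lambda i, j: chain[i] == chain[j]

    # n-turns: CO(i) ... NH(i+n)
    def turn(nn):
        t = np.zeros(n, dtype=bool)
        for i in range(n - nn):
            if same_chain(i, i + nn) and hb[i, i + nn]:
                t[i] = True
        return t

    helix = np.zeros(n, dtype=bool)
    for nn in (4, 3, 5):
        t = turn(nn)
        for i in range(1, n - nn):
            if t[i - 1] and t[i]:
                helix[i : i + nn] = True

    strand = np.zeros(n, dtype=bool)
    for i in range(n):
        for j in range(i + 1, n):
            if same_chain(i, j) and j - i < 3:
                continue
            anti = (hb[i, j] and hb[j, i]) or (
                0 <= i - 1 and j + 1 < n and 0 <= j - 1 and i + 1 < n
                and hb[i - 1, j + 1] and hb[j - 1, i + 1]
            )
            para = (
                0 <= i - 1 and i + 1 < n and hb[i - 1, j] and hb[j, i + 1]
            ) or (
                0 <= j - 1 and j + 1 < n and hb[j - 1, i] and hb[i, j + 1]
            )
            if anti or para:
                strand[i] = strand[j] = True

    labels[strand] = "E"
    labels[helix] = "H"  # helix wins over strand
    labels[~ok] = "C"
    labels[small] = "C"
    return labels


def assignment_series(trajectory: Trajectory) -> np.ndarray:
    """(n_frames, n_residues) label array."""
    return np.stack(
        [assign_secondary_structure(trajectory.topology, f) for f in trajectory.frames]
    )


def propensity(ensemble_labels: np.ndarray, native_labels) -> pd.DataFrame:
    """Per-residue class occupancies and native-normalized propensity.

    ``native_propensity`` is the fraction of frames a residue spends in its
    own native class.
    """
    ensemble_labels = np.atleast_2d(np.asarray(ensemble_labels))
    native_labels = np.asarray(list(native_labels))
    if ensemble_labels.shape[1] != native_labels.shape[0]:
        raise ValueError("label arrays are not aligned")
    p_h = (ensemble_labels == "H").mean(axis=0)
    p_e = (ensemble_labels == "E").mean(axis=0)
    p_c = (ensemble_labels == "C").mean(axis=0)
    native_prop = np.choose(
        np.searchsorted(np.array(["C", "E", "H"]), native_labels),
        [p_c, p_e, p_h],
    )
    return pd.DataFrame(
        {
            "residue": np.arange(native_labels.shape[0]),
            "native": native_labels,
            "p_H": p_h,
            "p_E": p_e,
            "p_C": p_c,
            "native_propensity": native_prop,
        }
    )


def classify_transition_events(native_labels, ensemble_labels) -> pd.DataFrame:
    """Per-residue transition event from native label vs modal ensemble label.

    The four event classes are helix->coil, strand->coil, coil->strand and
    helix->strand; everything else (including modal ties) is 'unchanged'.
    """
    native_labels = np.asarray(list(native_labels))
    ensemble_labels = np.atleast_2d(np.asarray(ensemble_labels))
    if ensemble_labels.shape[1] != native_labels.shape[0]:
        raise ValueError("label arrays are not aligned")
    events = []
    modal = []
    for r in range(native_labels.shape[0]):
        col = ensemble_labels[:, r]
        classes, counts = np.unique(col, return_counts=True)
        top = counts.max()
        winners = classes[counts == top]
        if len(winners) > 1:
            m = native_labels[r]  # tie -> conservative 'unchanged'
        else:
            m = winners[0]
        modal.append(m)
        events.append(_EVENT_MAP.get((native_labels[r], m), "unchanged"))
    return pd.DataFrame(
        {
            "residue": np.arange(native_labels.shape[0]),
            "native": native_labels,
            "modal": modal,
            "event": events,
        }
    )


def dihedral_series(trajectory: Trajectory, residue_index: int, angle: str) -> np.ndarray:
    """Backbone phi/psi torsion (degrees, IUPAC sign) per frame."""
    topo = trajectory.topology
    if angle == "phi":
        spec = [(residue_index - 1, "C"), (residue_index, "N"),
                (residue_index, "CA"), (residue_index, "C")]
    elif angle == "psi":
        spec = [(residue_index, "N"), (residue_index, "CA"),
                (residue_index, "C"), (residue_index + 1, "N")]
    else:
        raise ValueError(f"angle must be 'phi' or 'psi', got {angle!r}")
    idx = []
    for ri, name in spec:
        try:
            idx.append(topo.atom_index(ri, name))
        except KeyError:
            raise ValueError(
                f"{angle} of residue {residue_index} needs atom {name} of residue {ri}"
            ) from None
    return np.array(
        [dihedral(*(f[i] for i in idx)) for f in trajectory.frames]
    )


def reference_assignment(structure: Structure, coords: np.ndarray | None = None) -> np.ndarray:
    """Cross-check assignment from an established implementation (mdtraj's
    DSSP port), reduced to the same 3-state alphabet.  For validation only;
    the package's own assignment is :func:`assign_secondary_structure`.
    """
    import mdtraj as md

    coords = structure.coords if coords is None else np.asarray(coords, float)
    top = md.Topology()
    chains = {}
    residues = {}
    for r in structure.protein_residues():
        if r.chain_id not in chains:
            chains[r.chain_id] = top.add_chain()
        residues[r.index] = top.add_residue(r.name, chains[r.chain_id])
    keep = []
    for a in structure.atoms:
        if a.residue_index not in residues:
            continue
        el = md.element.get_by_symbol(a.element.capitalize())
        top.add_atom(a.name, el, residues[a.residue_index])
        keep.append(a.index)
    traj = md.Trajectory(coords[np.asarray(keep)][None], top)
    codes = md.compute_dssp(traj, simplified=True)[0]
    return np.array(["C" if c in ("NA", " ", "") else c for c in codes], dtype="<U1")
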