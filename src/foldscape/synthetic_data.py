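"""Synthetic structures and ensembles with planted ground truth.

Every generator is a pure function of its arguments (fixed seed => byte
identical output), and the oracle computations here share no code with the
analysis algorithms they validate:

* ideal poly-alanine secondary-structure templates (helix, strand,
  extended coil, antiparallel sheet) built from standard backbone
  geometry, used as assignment and H-bond oracles;
* two-state hopping trajectories with prescribed state populations and
  Gaussian coordinate noise, the phantom for free-energy maps;
* planar surface phantoms whose hydrophobic patch decomposition is known
  by construction and re-measured by an independent quadrature;
* unfolding ensembles with per-segment secondary-structure transition
  events planted as geometry;
* two-residue distance processes with exactly imposed sample moments for
  the commute-time matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._geometry import place_atom, rotation_matrix
from .structure_io import (
    Atom,
    ResidueInfo,
    Structure,
    Trajectory,
    assign_radii,
    classify_atom_polarity,
)

__all__ = [
    "SyntheticSpec",
    "make_ideal_helix",
    "make_extended_chain",
    "make_strand",
    "make_antiparallel_sheet",
    "make_two_state_trajectory",
    "make_patch_phantom",
    "numerical_patch_oracle",
    "make_unfolding_ensemble",
    "make_solvated_peptide",
    "make_distance_process",
]

# standard backbone geometry (angstrom / degrees)
B_N_CA, B_CA_C, B_C_N, B_C_O, B_CA_CB = 1.458, 1.525, 1.329, 1.231, 1.530
A_C_N_CA, A_N_CA_C, A_CA_C_N, A_CA_C_O = 121.7, 111.2, 116.2, 120.8
OMEGA = 180.0

HELIX_PHI, HELIX_PSI = -57.0, -47.0
STRAND_PHI, STRAND_PSI = -139.0, 135.0
EXTENDED_PHI, EXTENDED_PSI = 180.0, 180.0


@dataclass
class SyntheticSpec:
    """Study conditions for the statistical phantoms."""

    seed: int = 0
    n_residues: int = 20
    n_frames: int = 1000
    state_populations: tuple = (0.8, 0.2)
    coordinate_noise_sigma: float = 0.01  # nm
    planted_events: dict = field(default_factory=dict)  # segment id -> event
    temperature: float = 400.0  # K

    def __post_init__(self):
        if abs(sum(self.state_populations) - 1.0) > 1e-9:
            raise ValueError("state populations must sum to 1")


# ----------------------------------------------------------------------
# backbone construction
# ----------------------------------------------------------------------

def _backbone_chain(phi_psi: list, start=np.zeros(3)) -> dict:
    """NeRF poly-peptide backbone; returns arrays (angstrom) keyed by
    atom name.  phi of the first residue is ignored (no preceding C)."""
    n = len(phi_psi)
    N = np.zeros((n, 3))
    CA = np.zeros((n, 3))
    C = np.zeros((n, 3))
    O = np.zeros((n, 3))
    CB = np.zeros((n, 3))
    N[0] = start
    CA[0] = start + np.array([B_N_CA, 0.0, 0.0])
    ang = np.radians(180.0 - A_N_CA_C)
    C[0] = CA[0] + B_CA_C * np.array([np.cos(ang), np.sin(ang), 0.0])
    for i in range(n):
        phi, psi = phi_psi[i]
        if i > 0:
            N[i] = place_atom(N[i - 1], CA[i - 1], C[i - 1], B_C_N, A_CA_C_N,
                              phi_psi[i - 1][1])  # psi(i-1)
            CA[i] = place_atom(CA[i - 1], C[i - 1], N[i], B_N_CA, A_C_N_CA, OMEGA)
            C[i] = place_atom(C[i - 1], N[i], CA[i], B_CA_C, A_N_CA_C, phi)
        # carbonyl O: trans to the next N (psi + 180 about the same axis)
        O[i] = place_atom(N[i], CA[i], C[i], B_C_O, A_CA_C_O, psi + 180.0)
        # CB off the backbone plane at tetrahedral-ish geometry
        n1 = N[i] - CA[i]
        n2 = C[i] - CA[i]
        n1 /= np.linalg.norm(n1)
        n2 /= np.linalg.norm(n2)
        bis = n1 + n2
        bis /= np.linalg.norm(bis)
        perp = np.cross(n1, n2)
        perp /= np.linalg.norm(perp)
        CB[i] = CA[i] + B_CA_CB * (-bis * np.cos(np.radians(51.8))
                                   + perp * np.sin(np.radians(51.8)))
    return {"N": N, "CA": CA, "C": C, "O": O, "CB": CB}


def _chain_to_structure(backbones: list, chain_ids: list, res_name: str = "ALA",
                        with_cb: bool = True, res_names: list | None = None) -> Structure:
    """Assemble backbone dicts (angstrom) into a Structure (nm)."""
    atoms: list[Atom] = []
    residues: list[ResidueInfo] = []
    ridx = 0
    one = {"ALA": "A", "LEU": "L", "ILE": "I", "VAL": "V", "GLY": "G"}
    for bb, cid in zip(backbones, chain_ids):
        n = bb["N"].shape[0]
        for i in range(n):
            name3 = (res_names[ridx] if res_names else res_name)
            residues.append(
                ResidueInfo(index=ridx, name=name3, chain_id=cid,
                            one_letter=one.get(name3, "X"), author_seq_id=ridx + 1)
            )
            names = ["N", "CA", "C", "O"] + (["CB"] if with_cb and name3 != "GLY" else [])
            for an in names:
                el = an[0]
                atoms.append(
                    Atom(index=len(atoms), name=an, element=el, residue_index=ridx,
                         residue_name=name3, chain_id=cid,
                         position=bb[an][i] * 0.1, is_hydrogen=False)
                )
            ridx += 1
    st = Structure(atoms=atoms, residues=residues)
    for a in st.atoms:
        a.polarity = classify_atom_polarity(a, st)
    assign_radii(st, united=True)
    return st


def make_ideal_helix(n_residues: int, phi: float = HELIX_PHI,
                     psi: float = HELIX_PSI) -> Structure:
    """Ideal poly-alanine alpha-helix (heavy atoms N, CA, C, O, CB)."""
    if n_residues < 4:
        raise ValueError("a helix needs at least 4 residues")
    bb = _backbone_chain([(phi, psi)] * n_residues)
    return _chain_to_structure([bb], ["A"])


def make_extended_chain(n_residues: int) -> Structure:
    """Fully extended poly-alanine chain (no mainchain hydrogen bonds)."""
    bb = _backbone_chain([(EXTENDED_PHI, EXTENDED_PSI)] * n_residues)
    return _chain_to_structure([bb], ["A"])


def make_strand(n_residues: int) -> Structure:
    """Single beta-strand conformation (no partner, so assigned coil)."""
    bb = _backbone_chain([(STRAND_PHI, STRAND_PSI)] * n_residues)
    return _chain_to_structure([bb], ["A"])


def _strand_backbone(n: int) -> dict:
    return _backbone_chain([(STRAND_PHI, STRAND_PSI)] * n)


def make_antiparallel_sheet(n_per_strand: int = 6) -> Structure:
    """Two antiparallel beta-strands as separate chains.

    Both strands use the planar fully-extended template (which, unlike the
    twisted ideal strand, repeats by pure translation, so a rigid partner
    can register the whole hydrogen-bond ladder).  The partner is the
    first strand rotated 180 degrees in-plane (reversing its direction)
    and translated; the offset comes from a deterministic grid scan
    maximizing the number of inter-strand N...O pairs at hydrogen-bond
    distance (2.6-3.3 A) without backbone clashes.
    """
    bb1 = _backbone_chain([(EXTENDED_PHI, EXTENDED_PSI)] * n_per_strand)
    axis_pts = bb1["CA"]
    direction = axis_pts[-1] - axis_pts[0]
    direction /= np.linalg.norm(direction)
    normal = np.array([0.0, 0.0, 1.0])  # extended template is exactly planar
    rot = rotation_matrix(normal, 180.0)
    center = axis_pts.mean(0)
    base = {k: (v - center) @ rot.T + center for k, v in bb1.items()}
    lateral = np.cross(normal, direction)
    lateral /= np.linalg.norm(lateral)

    backbone1 = np.concatenate([bb1[k] for k in ("N", "CA", "C", "O")])
    backbone2 = np.concatenate([base[k] for k in ("N", "CA", "C", "O")])
    full1 = np.concatenate([bb1[k] for k in ("N", "CA", "C", "O", "CB")])
    full2 = np.concatenate([base[k] for k in ("N", "CA", "C", "O", "CB")])

    def score(shift):
        d = np.sqrt(((backbone1[:, None] - (backbone2 + shift)[None]) ** 2).sum(-1))
        if d.min() < 2.6:  # backbone steric clash
            return -1, 0.0
        b2o = base["O"] + shift
        b2n = base["N"] + shift
        cnt = 0
        for i in range(n_per_strand):
            for j in range(n_per_strand):
                for p, q in ((bb1["N"][i], b2o[j]), (bb1["O"][i], b2n[j])):
                    if 2.6 <= np.linalg.norm(p - q) <= 3.3:
                        cnt += 1
        dfull = np.sqrt(((full1[:, None] - (full2 + shift)[None]) ** 2).sum(-1))
        return cnt, float(dfull.min())

    best = None
    for dy in np.concatenate([np.arange(4.0, 6.01, 0.05), np.arange(-6.0, -3.99, 0.05)]):
        for dx in np.arange(-5.0, 5.01, 0.05):
            shift = dy * lateral + dx * direction
            cnt, clearance = score(shift)
            # most H-bonds first, then the least side-chain interference
            key = (-cnt, -round(clearance, 2), round(abs(float(dy)), 3),
                   round(float(dx), 3), float(np.sign(dy)))
            if best is None or key < best[0]:
                best = (key, shift)
    bb2 = {k: v + best[1] for k, v in base.items()}
    return _chain_to_structure([bb1, bb2], ["A", "B"])


# ----------------------------------------------------------------------
# two-state hopping trajectory
# ----------------------------------------------------------------------

def make_two_state_trajectory(spec: SyntheticSpec,
                              conformers: tuple | None = None) -> Trajectory:
    """Frames drawn i.i.d. from two reference conformers with the given
    populations plus isotropic Gaussian coordinate noise.

    Default conformers: a two-strand antiparallel sheet of
    ``spec.n_residues`` residues (folded: cross-strand side-chain contacts
    intact, rho = 1) and the same sheet with the strands pulled 4 nm apart
    (unfolded: rho = 0, large RMSD).
    """
    rng = np.random.default_rng(spec.seed)
    if conformers is None:
        folded = make_antiparallel_sheet(max(4, spec.n_residues // 2))
        apart = folded.coords.copy()
        chain_b = [a.index for a in folded.atoms if a.chain_id == "B"]
        apart[chain_b] += np.array([0.0, 0.0, 4.0])
        unfolded = folded.with_coords(apart)
        conformers = (folded, unfolded)
    ref = conformers[0]
    coord_sets = [c.coords for c in conformers]
    if len({c.shape for c in coord_sets}) != 1:
        raise ValueError("conformers must share an atom count")
    states = rng.choice(len(coord_sets), size=spec.n_frames, p=spec.state_populations)
    frames = np.stack([coord_sets[s] for s in states])
    if spec.coordinate_noise_sigma > 0:
        frames = frames + rng.normal(0.0, spec.coordinate_noise_sigma, frames.shape)
    return Trajectory(topology=ref, frames=frames, frame_interval=10.0,
                      temperature=spec.temperature,
                      label=f"two-state seed={spec.seed}")


# ----------------------------------------------------------------------
# patch phantom + independent numerical oracle
# ----------------------------------------------------------------------

def make_patch_phantom(layout: list | None = None, residue_name: str = "LEU"):
    """Planar surface phantom with an analytically known patch split.

    Default layout: two 4x4 grids of nonpolar carbon atoms separated by a
    wide gap carrying a stripe of polar oxygens, so exactly two contiguous
    hydrophobic patches exist.  Returns ``(structure, groups)`` where
    ``groups`` maps patch label -> atom indices (the construction truth).
    """
    if layout is None:
        layout = []
        spacing = 0.35  # nm: overlapping accessible spheres within a block
        for gx in range(4):
            for gy in range(4):
                layout.append((np.array([gx * spacing, gy * spacing, 0.0]),
                               "C", "left"))
        x_right = 3 * spacing + 1.4  # gap >> adjacency reach (~0.62 nm)
        for gx in range(4):
            for gy in range(4):
                layout.append((np.array([x_right + gx * spacing, gy * spacing, 0.0]),
                               "C", "right"))
        x_mid = 3 * spacing + 0.7
        for gy in range(4):
            layout.append((np.array([x_mid, gy * spacing, 0.0]), "O", "polar"))
    atoms, residues = [], []
    groups: dict[str, list[int]] = {}
    for k, (pos, element, group) in enumerate(layout):
        name3 = residue_name if element == "C" else "SER"
        residues.append(
            ResidueInfo(index=k, name=name3, chain_id="A",
                        one_letter={"LEU": "L", "SER": "S"}.get(name3, "X"),
                        author_seq_id=k + 1)
        )
        atom_name = "CB" if element == "C" else "OG"
        atoms.append(
            Atom(index=k, name=atom_name, element=element, residue_index=k,
                 residue_name=name3, chain_id="A", position=np.asarray(pos, float))
        )
        if element == "C":
            groups.setdefault(group, []).append(k)
    st = Structure(atoms=atoms, residues=residues)
    for a in st.atoms:
        a.polarity = classify_atom_polarity(a, st)
    assign_radii(st, united=True)
    return st, groups


def numerical_patch_oracle(structure: Structure, groups: dict,
                           probe_radius: float = 0.14,
                           polar_expansion: float = 0.14,
                           n_theta: int = 180) -> dict:
    """Patch areas (A^2) by independent latitude-longitude quadrature.

    For each nonpolar atom the accessible sphere is integrated on a
    theta-phi grid with sin(theta) solid-angle weights; a point is exposed
    iff outside every other atom's (polar-inflated) accessible sphere.
    Shares no code with the dot-surface engine under test.
    """
    pos = structure.coords
    radii = structure.radii
    polar = ~structure.nonpolar_mask
    occ = radii + probe_radius + np.where(polar, polar_expansion, 0.0)
    thetas = (np.arange(n_theta) + 0.5) * np.pi / n_theta
    n_phi = 2 * n_theta
    phis = (np.arange(n_phi) + 0.5) * 2 * np.pi / n_phi
    tt, pp = np.meshgrid(thetas, phis, indexing="ij")
    dirs = np.stack(
        [np.sin(tt) * np.cos(pp), np.sin(tt) * np.sin(pp), np.cos(tt)], axis=-1
    ).reshape(-1, 3)
    weights = (np.sin(tt) * (np.pi / n_theta) * (2 * np.pi / n_phi)).reshape(-1)
    areas = {}
    for label, members in groups.items():
        total = 0.0
        for i in members:
            r = radii[i] + probe_radius
            pts = pos[i] + r * dirs
            alive = np.ones(pts.shape[0], dtype=bool)
            for j in range(pos.shape[0]):
                if j == i:
                    continue
                d2 = ((pts - pos[j]) ** 2).sum(1)
                alive &= d2 > occ[j] ** 2
            total += r * r * weights[alive].sum()
        areas[label] = total * 100.0  # nm^2 -> A^2
    return areas


# ----------------------------------------------------------------------
# unfolding ensemble with planted transition events
# ----------------------------------------------------------------------

def _segment_geometry(kind: str, length: int) -> dict:
    """Backbone for one segment; 'beta' folds the span into a two-strand
    hairpin so strand residues have a bridge partner."""
    if kind == "helix":
        return _backbone_chain([(HELIX_PHI, HELIX_PSI)] * length)
    if kind == "coil":
        return _backbone_chain([(EXTENDED_PHI, EXTENDED_PSI)] * length)
    if kind == "beta":
        if length < 9:
            raise ValueError("a hairpin segment needs at least 9 residues")
        n_strand = (length - 3) // 2
        sheet = make_antiparallel_sheet(n_strand)
        coords_a = {k: [] for k in ("N", "CA", "C", "O", "CB")}
        per = {k: np.zeros((length, 3)) for k in ("N", "CA", "C", "O", "CB")}
        # strand 1 residues 0..n_strand-1, turn, strand 2 reversed to keep
        # a single chain direction
        atoms_of = {}
        for a in sheet.atoms:
            atoms_of.setdefault(a.residue_index, {})[a.name] = a.position * 10.0
        for i in range(n_strand):
            for k in per:
                per[k][i] = atoms_of[i][k]
        n_turn = length - 2 * n_strand
        # turn residues: linear interpolation between strand ends (kept
        # unbonded/coil-like on purpose)
        start = atoms_of[n_strand - 1]["C"]
        end = atoms_of[2 * n_strand - 1]["C"] + np.array([0.0, 0.0, 6.0])
        for t in range(n_turn):
            frac = (t + 1) / (n_turn + 1)
            base = start * (1 - frac) + end * frac + np.array([0.0, 0.0, 5.0])
            per["N"][n_strand + t] = base
            per["CA"][n_strand + t] = base + np.array([1.46, 0, 0])
            per["C"][n_strand + t] = base + np.array([2.2, 1.2, 0])
            per["O"][n_strand + t] = base + np.array([2.2, 2.4, 0])
            per["CB"][n_strand + t] = base + np.array([1.46, -1.2, 0.8])
        # strand 2: chain B of the sheet already runs spatially opposite to
        # strand 1 (it was built by an in-plane 180-degree rotation), so its
        # natural residue order keeps the hairpin antiparallel
        for s in range(n_strand):
            for k in per:
                per[k][n_strand + n_turn + s] = atoms_of[n_strand + s][k]
        return per
    raise ValueError(f"unknown segment kind {kind!r}")


_EVENT_KINDS = {
    "alpha_to_coil": ("helix", "coil"),
    "beta_to_coil": ("beta", "coil"),
    "coil_to_beta": ("coil", "beta"),
    "alpha_to_beta": ("helix", "beta"),
    "unchanged": (None, None),
}


@dataclass
class SegmentPlan:
    segment_id: str
    length: int
    native_kind: str  # helix | beta | coil
    event: str  # one of EVENT_CLASSES


def default_segment_plan() -> list:
    """One segment per event class plus unchanged controls of every kind."""
    return [
        SegmentPlan("seg_a2c", 12, "helix", "alpha_to_coil"),
        SegmentPlan("seg_b2c", 13, "beta", "beta_to_coil"),
        SegmentPlan("seg_c2b", 13, "coil", "coil_to_beta"),
        SegmentPlan("seg_a2b", 13, "helix", "alpha_to_beta"),
        SegmentPlan("seg_keep_h", 12, "helix", "unchanged"),
        SegmentPlan("seg_keep_c", 8, "coil", "unchanged"),
    ]


def _core_mask(kind: str, length: int) -> np.ndarray:
    """Residues of a segment whose label is pinned by the template
    (interiors of helices/strands; everything for coil)."""
    mask = np.zeros(length, dtype=bool)
    if kind == "helix":
        mask[2 : length - 2] = True
    elif kind == "coil":
        mask[:] = True
    elif kind == "beta":
        n_strand = (length - 3) // 2
        n_turn = length - 2 * n_strand
        mask[1 : n_strand - 1] = True
        mask[n_strand + n_turn + 1 : length - 1] = True
    return mask


def make_unfolding_ensemble(plan: list | None = None, n_frames: int = 20,
                            intermediate_fraction: float = 0.8,
                            seed: int = 0):
    """Ensemble in which designated segments are geometrically remodeled.

    Each segment has a native template and, when its planted event is not
    'unchanged', a remodeled template in the intermediate frames (helix or
    coil spans turn into hairpins, helices melt to extended coil, ...).
    Returns ``(trajectory, truth)`` where ``truth`` is a per-residue table
    with native/intermediate labels expected from the templates, the
    planted event, and a ``core`` flag marking residues whose label the
    template pins down (segment interiors).
    """
    if plan is None:
        plan = default_segment_plan()
    rng = np.random.default_rng(seed)

    def assemble(kinds):
        xs = 0.0
        per_seg = []
        for p, kind in zip(plan, kinds):
            bb = _segment_geometry(kind, p.length)
            span = bb["CA"][:, 0].max() - bb["CA"][:, 0].min()
            shift = np.array([xs - bb["CA"][:, 0].min(), 0.0, 0.0])
            per_seg.append({k: v + shift for k, v in bb.items()})
            xs += span + 18.0  # angstrom gap between segments
        merged = {k: np.concatenate([s[k] for s in per_seg]) for k in per_seg[0]}
        return merged

    native_kinds = [p.native_kind for p in plan]
    inter_kinds = []
    for p in plan:
        nk, tk = _EVENT_KINDS[p.event]
        if p.event == "unchanged":
            inter_kinds.append(p.native_kind)
        else:
            if nk != p.native_kind:
                raise ValueError(
                    f"segment {p.segment_id}: event {p.event} needs native kind {nk}"
                )
            inter_kinds.append(tk)

    native_bb = assemble(native_kinds)
    inter_bb = assemble(inter_kinds)
    native_st = _chain_to_structure([native_bb], ["A"])
    inter_st = _chain_to_structure([inter_bb], ["A"])

    n_inter = int(round(intermediate_fraction * n_frames))
    is_inter = np.zeros(n_frames, dtype=bool)
    order = rng.permutation(n_frames)
    is_inter[order[:n_inter]] = True
    frames = np.stack(
        [inter_st.coords if flag else native_st.coords for flag in is_inter]
    )
    traj = Trajectory(topology=native_st, frames=frames, frame_interval=10.0,
                      temperature=400.0, label=f"unfolding seed={seed}")

    label_of = {"helix": "H", "beta": "E", "coil": "C"}
    rows = []
    ridx = 0
    for p, nk, ik in zip(plan, native_kinds, inter_kinds):
        nat_core = _core_mask(nk, p.length)
        int_core = _core_mask(ik, p.length)
        for i in range(p.length):
            core = bool(nat_core[i] and int_core[i])
            rows.append(
                {
                    "residue": ridx,
                    "segment_id": p.segment_id,
                    "native_label": label_of[nk] if nat_core[i] else "C",
                    "intermediate_label": label_of[ik] if int_core[i] else "C",
                    "event": p.event if core else "unchanged",
                    "core": core,
                }
            )
            ridx += 1
    truth = pd.DataFrame(rows)
    return traj, truth


def make_solvated_peptide(n_residues: int = 3, n_waters: int = 50,
                          box_margin: float = 0.8, seed: int = 0) -> Structure:
    """Extended peptide surrounded by uniformly placed water oxygens.

    Waters are single-oxygen (heavy-atom representation), rejected closer
    than 0.25 nm to any previously placed atom, so hydrogen-bond counts
    against this fixture are checkable by plain pair enumeration.
    """
    peptide = make_extended_chain(n_residues)
    rng = np.random.default_rng(seed)
    coords = [a.position for a in peptide.atoms]
    lo = np.min(coords, axis=0) - box_margin
    hi = np.max(coords, axis=0) + box_margin
    atoms = list(peptide.atoms)
    residues = list(peptide.residues)
    placed = np.array(coords)
    n_placed = 0
    while n_placed < n_waters:
        pos = rng.uniform(lo, hi)
        if np.sqrt(((placed - pos) ** 2).sum(1)).min() < 0.25:
            continue
        ridx = len(residues)
        residues.append(
            ResidueInfo(index=ridx, name="HOH", chain_id="W", one_letter="X",
                        author_seq_id=ridx + 1, is_water=True)
        )
        atoms.append(
            Atom(index=len(atoms), name="O", element="O", residue_index=ridx,
                 residue_name="HOH", chain_id="W", position=pos, polarity="polar")
        )
        placed = np.vstack([placed, pos])
        n_placed += 1
    st = Structure(atoms=atoms, residues=residues)
    assign_radii(st, united=True)
    return st


# ----------------------------------------------------------------------
# imposed-moment distance process
# ----------------------------------------------------------------------

def make_distance_process(mean: float, variance: float, n_frames: int,
                          seed: int = 0) -> Trajectory:
    """Two C-alpha residues whose distance series has exactly the requested
    sample mean and (population) variance, in angstroms.

    The raw Gaussian series is standardized, so the moments are imposed
    identities rather than asymptotic properties.
    """
    if variance < 0:
        raise ValueError("variance must be non-negative")
    if n_frames < 2:
        raise ValueError("need at least two frames")
    rng = np.random.default_rng(seed)
    z = rng.normal(size=n_frames)
    sd = z.std()
    if variance == 0 or sd == 0:
        d = np.full(n_frames, mean)
    else:
        d = mean + np.sqrt(variance) * (z - z.mean()) / sd
    if np.any(d <= 0):
        raise ValueError("distance process crossed zero; increase mean or lower variance")
    atoms = []
    residues = []
    for k in range(2):
        residues.append(ResidueInfo(index=k, name="ALA", chain_id="A",
                                    one_letter="A", author_seq_id=k + 1))
        atoms.append(Atom(index=k, name="CA", element="C", residue_index=k,
                          residue_name="ALA", chain_id="A", position=np.zeros(3)))
    st = Structure(atoms=atoms, residues=residues)
    assign_radii(st, united=True)
    frames = np.zeros((n_frames, 2, 3))
    frames[:, 1, 0] = d * 0.1  # angstrom -> nm
    return Trajectory(topology=st, frames=frames, frame_interval=10.0,
                      temperature=300.0, label=f"distance-process seed={seed}")
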