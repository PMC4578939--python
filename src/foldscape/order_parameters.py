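"""Per-frame order parameters: RMSD, native-contact fractions, SASA, RMSF.

Two contact-based coordinates are distinguished the way unfolding studies
use them: ``rho`` is the fraction of native *side-chain* contacts retained
(0.55 nm minimum-distance criterion) and ``q`` the fraction of native
contacts over all heavy atoms.  Both are ratios against the native contact
list, so they live in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._dots import accessible_dots
from ._geometry import superpose
from .structure_io import BACKBONE_NAMES, Structure, Trajectory

__all__ = [
    "ContactSet",
    "native_contacts",
    "contact_fraction_series",
    "rho",
    "q_fraction",
    "rmsd",
    "rmsd_series",
    "sasa",
    "sasa_series",
    "rmsf",
    "compute_series",
    "write_series",
]

DEFAULT_CONTACT_CUTOFF = 0.55  # nm, minimum inter-atomic distance criterion
DEFAULT_MIN_SEP = 3


@dataclass(frozen=True)
class ContactSet:
    pairs: tuple  # ((i, j), ...) residue index pairs, i < j
    atom_scope: str  # 'sidechain' | 'heavy'
    cutoff: float  # nm
    min_sequence_separation: int

    def __post_init__(self):
        seen = set()
        for i, j in self.pairs:
            if i >= j:
                raise ValueError(f"contact pair ({i},{j}) must have i < j")
            if j - i < self.min_sequence_separation:
                raise ValueError(
                    f"pair ({i},{j}) violates min separation {self.min_sequence_separation}"
                )
            if (i, j) in seen:
                raise ValueError(f"duplicate contact pair ({i},{j})")
            seen.add((i, j))

    def __len__(self):
        return len(self.pairs)


def _scope_indices(structure: Structure, scope: str) -> dict[int, np.ndarray]:
    """Atom indices per protein residue for the requested scope."""
    if scope not in ("sidechain", "heavy"):
        raise ValueError(f"unknown atom scope {scope!r}")
    out: dict[int, np.ndarray] = {}
    for res in structure.protein_residues():
        idx = [
            a.index
            for a in structure.atoms
            if a.residue_index == res.index
            and not a.is_hydrogen
            and (scope == "heavy" or a.name not in BACKBONE_NAMES)
        ]
        out[res.index] = np.asarray(idx, dtype=int)
    return out


def native_contacts(structure: Structure, scope: str = "sidechain",
                    cutoff: float = DEFAULT_CONTACT_CUTOFF,
                    min_sep: int = DEFAULT_MIN_SEP) -> ContactSet:
    """Contacts of the native structure: pair (i, j) is native iff the
    minimum distance between the scoped atoms of residues i and j is
    <= cutoff.  Glycines contribute no side-chain atoms and are skipped.
    """
    scoped = _scope_indices(structure, scope)
    res_ids = sorted(scoped)
    if len(res_ids) < min_sep + 1:
        raise ValueError("structure too small for the requested sequence separation")
    coords = structure.coords
    pairs = []
    for a_pos, i in enumerate(res_ids):
        ai = scoped[i]
        if ai.size == 0:
            continue
        for j in res_ids[a_pos + 1:]:
            if j - i < min_sep:
                continue
            aj = scoped[j]
            if aj.size == 0:
                continue
            diff = coords[ai][:, None, :] - coords[aj][None, :, :]
            if float(np.sqrt((diff ** 2).sum(-1)).min()) <= cutoff:
                pairs.append((i, j))
    return ContactSet(pairs=tuple(pairs), atom_scope=scope, cutoff=cutoff,
                      min_sequence_separation=min_sep)


def contact_fraction_series(frames: np.ndarray, structure: Structure,
                            native: ContactSet) -> np.ndarray:
    """Fraction of native contacts retained, per frame."""
    if len(native) == 0:
        raise ValueError("empty native contact set: fraction undefined")
    frames = np.asarray(frames, dtype=float)
    if frames.ndim == 2:
        frames = frames[None]
    if frames.ndim != 3 or frames.shape[-1] != 3:
        raise ValueError("frames must be (n_frames, n_atoms, 3)")
    scoped = _scope_indices(structure, native.atom_scope)
    retained = np.zeros(frames.shape[0], dtype=int)
    for i, j in native.pairs:
        ai, aj = scoped[i], scoped[j]
        diff = frames[:, ai, None, :] - frames[:, None, aj, :]
        dmin = np.sqrt((diff ** 2).sum(-1)).min(axis=(1, 2))
        retained += dmin <= native.cutoff
    return retained / len(native)


def rho(frame: np.ndarray, structure: Structure, native: ContactSet) -> float:
    """Fraction of native side-chain contacts in one frame."""
    if native.atom_scope != "sidechain":
        raise ValueError("rho requires a side-chain contact set")
    return float(contact_fraction_series(frame[None], structure, native)[0])


def q_fraction(frame: np.ndarray, structure: Structure, native: ContactSet) -> float:
    """Fraction of native heavy-atom contacts in one frame."""
    if native.atom_scope != "heavy":
        raise ValueError("q requires a heavy-atom contact set")
    return float(contact_fraction_series(frame[None], structure, native)[0])


# ----------------------------------------------------------------------
# RMSD / RMSF
# ----------------------------------------------------------------------

def ca_indices(structure: Structure) -> np.ndarray:
    idx = [
        a.index for a in structure.atoms
        if a.name == "CA" and not a.is_hydrogen
        and not any(r.index == a.residue_index and (r.is_water or r.is_hetero)
                    for r in structure.residues)
    ]
    return np.asarray(idx, dtype=int)


def rmsd(frame: np.ndarray, reference: np.ndarray,
         selection: np.ndarray | None = None) -> float:
    """Optimal-superposition RMSD (nm) over the selected atoms (default: all)."""
    frame = np.asarray(frame, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if selection is not None:
        selection = np.asarray(selection, dtype=int)
        frame = frame[selection]
        reference = reference[selection]
    if frame.shape[0] < 3:
        raise ValueError("RMSD superposition needs at least 3 atoms")
    value, *_ = superpose(frame, reference)
    return value


def rmsd_series(frames: np.ndarray, reference: np.ndarray,
                selection: np.ndarray | None = None) -> np.ndarray:
    frames = np.asarray(frames, dtype=float)
    return np.array([rmsd(f, reference, selection) for f in frames])


def rmsf(frames: np.ndarray, structure: Structure,
         selection: np.ndarray | None = None, n_passes: int = 2) -> np.ndarray:
    """Per-residue C-alpha RMSF (nm) about the mean structure.

    Frames are iteratively superposed onto their mean (``n_passes`` rounds),
    then the fluctuation of each selected atom about its mean position is
    reported.
    """
    frames = np.asarray(frames, dtype=float)
    if frames.shape[0] < 2:
        raise ValueError("RMSF needs at least two frames")
    sel = ca_indices(structure) if selection is None else np.asarray(selection, int)
    sub = frames[:, sel, :]
    aligned = sub.copy()
    for _ in range(n_passes):
        mean = aligned.mean(axis=0)
        for k in range(aligned.shape[0]):
            _, rot, cm, cr = superpose(aligned[k], mean)
            aligned[k] = (aligned[k] - cm) @ rot + cr
    mean = aligned.mean(axis=0)
    return np.sqrt(((aligned - mean) ** 2).sum(-1).mean(axis=0))


# ----------------------------------------------------------------------
# SASA
# ----------------------------------------------------------------------

def sasa(structure: Structure, coords: np.ndarray | None = None,
         probe_radius: float = 0.14, dot_density: int = 960):
    """Dot-surface solvent-accessible area.

    Returns ``(total_nm2, per_atom_nm2)``; per-atom areas sum to the total.
    """
    positions = structure.coords if coords is None else np.asarray(coords, float)
    areas, _ = accessible_dots(positions, structure.radii, probe_radius, dot_density)
    return float(areas.sum()), areas


def sasa_series(frames: np.ndarray, structure: Structure,
                probe_radius: float = 0.14, dot_density: int = 960) -> np.ndarray:
    return np.array([sasa(structure, f, probe_radius, dot_density)[0] for f in frames])


# ----------------------------------------------------------------------
# bundled series
# ----------------------------------------------------------------------

def compute_series(trajectory: Trajectory, native: Structure,
                   native_sidechain: ContactSet | None = None,
                   native_heavy: ContactSet | None = None,
                   with_sasa: bool = False, dot_density: int = 960) -> pd.DataFrame:
    """Order-parameter table (one row per frame) against a native reference."""
    topo = trajectory.topology
    if native_sidechain is None:
        native_sidechain = native_contacts(native, "sidechain")
    if native_heavy is None:
        native_heavy = native_contacts(native, "heavy")
    sel = ca_indices(topo)
    df = pd.DataFrame(
        {
            "frame": np.arange(trajectory.n_frames),
            "time_ps": trajectory.times_ps,
            "rmsd_nm": rmsd_series(trajectory.frames, native.coords, sel),
            "rho": contact_fraction_series(trajectory.frames, topo, native_sidechain),
            "q": contact_fraction_series(trajectory.frames, topo, native_heavy),
        }
    )
    if with_sasa:
        df["sasa_nm2"] = sasa_series(trajectory.frames, topo, dot_density=dot_density)
    else:
        df["sasa_nm2"] = np.nan
    return df


def write_series(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")
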