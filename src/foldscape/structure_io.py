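"""Structures, trajectories and their file formats.

Coordinates are stored in nanometres throughout the package; PDB I/O
converts from/to angstroms at the boundary.  Residues are indexed 0-based
internally while the author (PDB) numbering is kept on each residue for
reporting.

PDB reading is backed by :mod:`gemmi`; binary trajectory formats (XTC/DCD)
are read through :mod:`mdtraj`.
"""

from __future__ import annotations

import io
import os
import tempfile
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import numpy as np
from Bio.SeqUtils import seq1

__all__ = [
    "Atom",
    "ResidueInfo",
    "Structure",
    "Trajectory",
    "ParseError",
    "AtomCountError",
    "read_structure",
    "read_trajectory",
    "write_pdb",
    "write_xyz",
    "read_xyz",
    "load_radii",
    "assign_radii",
    "classify_atom_polarity",
]

WATER_NAMES = {"WAT", "HOH", "SOL", "TIP3", "TIP3P", "SPC", "T3P"}

BACKBONE_NAMES = {"N", "CA", "C", "O", "OXT", "H", "H1", "H2", "H3", "HA", "HA2", "HA3", "HN"}

NONPOLAR_ELEMENTS = {"C", "S"}
POLAR_ELEMENTS = {"N", "O"}


class ParseError(ValueError):
    """Raised for unparseable structure input; carries the offending line."""

    def __init__(self, message: str, line_number: int | None = None, line: str | None = None):
        self.line_number = line_number
        self.line = line
        if line_number is not None:
            message = f"{message} (line {line_number}: {line!r})"
        super().__init__(message)


class AtomCountError(ValueError):
    """Frame/topology atom-count mismatch."""

    def __init__(self, expected: int, found: int, where: str = ""):
        self.expected = expected
        self.found = found
        suffix = f" in {where}" if where else ""
        super().__init__(f"expected {expected} atoms, found {found}{suffix}")


@dataclass
class Atom:
    index: int
    name: str
    element: str
    residue_index: int
    residue_name: str
    chain_id: str
    position: np.ndarray  # nm
    vdw_radius: float = float("nan")  # nm
    polarity: str = "polar"  # 'polar' | 'nonpolar'
    is_hydrogen: bool = False

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float)
        if not self.element:
            raise ValueError(f"atom {self.name} has an empty element symbol")


@dataclass(frozen=True)
class ResidueInfo:
    index: int  # 0-based internal index
    name: str  # 3-letter code
    chain_id: str
    one_letter: str
    author_seq_id: int
    is_water: bool = False
    is_hetero: bool = False


@dataclass
class Structure:
    """An ordered set of atoms with residue bookkeeping."""

    atoms: list[Atom]
    residues: list[ResidueInfo]
    title: str = ""

    def __post_init__(self):
        if not self.atoms:
            raise ValueError("a Structure needs at least one atom")
        known = {r.index for r in self.residues}
        for atom in self.atoms:
            if atom.residue_index not in known:
                raise ValueError(
                    f"atom {atom.index} ({atom.name}) references unknown residue "
                    f"{atom.residue_index}"
                )

    # -- derived views -------------------------------------------------
    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def n_residues(self) -> int:
        return len(self.residues)

    @property
    def coords(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms], dtype=float)

    @property
    def radii(self) -> np.ndarray:
        return np.array([a.vdw_radius for a in self.atoms], dtype=float)

    @property
    def nonpolar_mask(self) -> np.ndarray:
        return np.array([a.polarity == "nonpolar" for a in self.atoms], dtype=bool)

    def sequence(self, chain_id: str | None = None) -> str:
        return "".join(
            r.one_letter
            for r in self.residues
            if not r.is_water
            and not r.is_hetero
            and (chain_id is None or r.chain_id == chain_id)
        )

    def chains(self) -> list[str]:
        seen: list[str] = []
        for r in self.residues:
            if r.chain_id not in seen:
                seen.append(r.chain_id)
        return seen

    def residue_atom_indices(self, residue_index: int, names: set[str] | None = None,
                             heavy_only: bool = False) -> np.ndarray:
        idx = [
            a.index
            for a in self.atoms
            if a.residue_index == residue_index
            and (names is None or a.name in names)
            and not (heavy_only and a.is_hydrogen)
        ]
        return np.asarray(idx, dtype=int)

    def atom_index(self, residue_index: int, name: str) -> int:
        for a in self.atoms:
            if a.residue_index == residue_index and a.name == name:
                return a.index
        raise KeyError(f"residue {residue_index} has no atom named {name!r}")

    def protein_residues(self) -> list[ResidueInfo]:
        return [r for r in self.residues if not r.is_water and not r.is_hetero]

    def water_atom_indices(self) -> np.ndarray:
        waters = {r.index for r in self.residues if r.is_water}
        return np.asarray([a.index for a in self.atoms if a.residue_index in waters], dtype=int)

    def with_coords(self, coords: np.ndarray) -> "Structure":
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (self.n_atoms, 3):
            raise AtomCountError(self.n_atoms, coords.shape[0], "coordinate set")
        atoms = [replace(a, position=coords[i].copy()) for i, a in enumerate(self.atoms)]
        return Structure(atoms=atoms, residues=list(self.residues), title=self.title)


@dataclass
class Trajectory:
    """A topology plus an ordered stack of coordinate frames (nm)."""

    topology: Structure
    frames: np.ndarray  # (n_frames, n_atoms, 3)
    frame_interval: float = 10.0  # ps
    temperature: float = 300.0  # K
    label: str = ""

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise ValueError("frames must have shape (n_frames, n_atoms, 3)")
        if self.frames.shape[1] != self.topology.n_atoms:
            raise AtomCountError(self.topology.n_atoms, self.frames.shape[1], "trajectory frames")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")

    @property
    def n_frames(self) -> int:
        return int(self.frames.shape[0])

    @property
    def times_ps(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval


# ----------------------------------------------------------------------
# radii and polarity
# ----------------------------------------------------------------------

def load_radii(path: str | Path | None = None, united: bool = False) -> dict[str, float]:
    """Load a van der Waals radii table (two columns: pattern, radius in nm).

    The shipped default is the Bondi element set; ``united=True`` loads the
    united-atom variant used for heavy-atom-only (crystal) structures.
    """
    if path is None:
        name = "vdw_radii_united.tsv" if united else "vdw_radii.tsv"
        text = resources.files("foldscape.data").joinpath(name).read_text()
    else:
        text = Path(path).read_text()
    table: dict[str, float] = {}
    for lineno, line in enumerate(text.splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 2:
            raise ParseError("radii table rows need exactly two columns", lineno, line)
        table[parts[0].upper()] = float(parts[1])
    return table


def assign_radii(structure: Structure, table: dict[str, float] | None = None,
                 united: bool | None = None) -> Structure:
    """Assign per-atom vdW radii in place (and return the structure).

    ``united=None`` auto-selects the united-atom table when the structure
    carries no hydrogens.
    """
    if table is None:
        if united is None:
            united = not any(a.is_hydrogen for a in structure.atoms)
        table = load_radii(united=united)
    for atom in structure.atoms:
        key = atom.element.upper()
        if key not in table:
            raise KeyError(f"no vdW radius for element {atom.element!r} (atom {atom.name})")
        atom.vdw_radius = table[key]
    return structure


def classify_atom_polarity(atom: Atom, structure: Structure) -> str:
    """Polarity class used for hydrophobic-surface analysis.

    Carbon and sulfur are nonpolar; nitrogen and oxygen polar; a hydrogen
    inherits the class of its bonded heavy atom, with the bond inferred as
    the nearest heavy atom of the same residue.
    """
    el = atom.element.upper()
    if el in NONPOLAR_ELEMENTS:
        return "nonpolar"
    if el in POLAR_ELEMENTS:
        return "polar"
    if el == "H":
        heavies = [
            a for a in structure.atoms
            if a.residue_index == atom.residue_index and not a.is_hydrogen
        ]
        if not heavies:
            raise ValueError(f"hydrogen {atom.name} has no heavy atom to bond to")
        d = [np.linalg.norm(a.position - atom.position) for a in heavies]
        partner = heavies[int(np.argmin(d))]
        return classify_atom_polarity(partner, structure)
    raise ValueError(f"cannot classify polarity of element {el!r} (atom {atom.name})")


def _assign_polarity(structure: Structure) -> None:
    for atom in structure.atoms:
        try:
            atom.polarity = classify_atom_polarity(atom, structure)
        except ValueError:
            # ions / exotic elements: treated as polar, they never join a
            # hydrophobic patch
            atom.polarity = "polar"


# ----------------------------------------------------------------------
# PDB reading
# ----------------------------------------------------------------------

def _validate_pdb_text(text: str) -> None:
    n_atom_records = 0
    for lineno, line in enumerate(text.splitlines(), 1):
        if line.startswith(("ATOM", "HETATM")):
            n_atom_records += 1
            if len(line) < 54:
                raise ParseError("truncated coordinate record", lineno, line)
            for lo, hi in ((30, 38), (38, 46), (46, 54)):
                try:
                    float(line[lo:hi])
                except ValueError:
                    raise ParseError("non-numeric coordinate field", lineno, line) from None
    if n_atom_records == 0:
        raise ParseError("no ATOM/HETATM records found in input")


def _resolve_altlocs(residue: gemmi.Residue) -> list[gemmi.Atom]:
    """Keep one atom per name: highest occupancy, ties to altloc 'A'
    (smallest altloc identifier)."""
    by_name: dict[str, list[gemmi.Atom]] = {}
    for at in residue:
        by_name.setdefault(at.name, []).append(at)
    chosen = []
    for name in by_name:
        cands = by_name[name]
        cands.sort(key=lambda a: (-a.occ, a.altloc or "A"))
        chosen.append(cands[0])
    # keep original file order
    order = {at.name: i for i, at in enumerate(residue)}
    chosen.sort(key=lambda a: order[a.name])
    return chosen


def _structure_from_gemmi_model(model: gemmi.Model, title: str = "") -> Structure:
    atoms: list[Atom] = []
    residues: list[ResidueInfo] = []
    res_counter = 0
    for chain in model:
        for res in chain:
            is_water = res.name.upper() in WATER_NAMES
            is_het = (res.het_flag == "H") and not is_water
            one = "X"
            if not is_water and not is_het:
                try:
                    one = seq1(res.name.capitalize(), undef_code="X")
                except Exception:
                    one = "X"
            info = ResidueInfo(
                index=res_counter,
                name=res.name.upper(),
                chain_id=chain.name,
                one_letter=one if one.strip() else "X",
                author_seq_id=res.seqid.num,
                is_water=is_water,
                is_hetero=is_het,
            )
            residues.append(info)
            for at in _resolve_altlocs(res):
                el = at.element.name.upper() or at.name[0].upper()
                atoms.append(
                    Atom(
                        index=len(atoms),
                        name=at.name,
                        element=el,
                        residue_index=res_counter,
                        residue_name=res.name.upper(),
                        chain_id=chain.name,
                        position=np.array([at.pos.x, at.pos.y, at.pos.z]) * 0.1,  # A -> nm
                        is_hydrogen=(el == "H" or el == "D"),
                    )
                )
            res_counter += 1
    if not atoms:
        raise ParseError("no atoms after parsing")
    structure = Structure(atoms=atoms, residues=residues, title=title)
    _assign_polarity(structure)
    try:
        assign_radii(structure)
    except KeyError:
        pass  # exotic elements keep NaN radii; surface analyses will refuse them
    return structure


def _as_text(source) -> str:
    if hasattr(source, "read"):
        return source.read()
    text = str(source)
    if "\n" in text or text.startswith(("ATOM", "HETATM", "MODEL", "HEADER", "REMARK")):
        return text
    return Path(text).read_text()


def read_structure(source) -> Structure:
    """Parse a PDB file (path, text or stream) into a :class:`Structure`.

    Coordinates are converted to nm; waters and hetero groups are flagged;
    alternate locations resolve to the highest-occupancy conformer (ties to
    altloc 'A').  The first MODEL is used for multi-model input.
    """
    text = _as_text(source)
    _validate_pdb_text(text)
    st = gemmi.read_pdb_string(text)
    if len(st) == 0:
        raise ParseError("no models in PDB input")
    return _structure_from_gemmi_model(st[0], title=st.name)


def read_trajectory(topology: Structure, source, frame_interval: float = 10.0,
                    temperature: float = 300.0, label: str = "") -> Trajectory:
    """Read coordinate frames matching ``topology`` from one or more files.

    Supports multi-model PDB, plain XYZ and (via mdtraj) XTC/DCD.  Frames
    keep file order; an atom-count mismatch raises :class:`AtomCountError`.
    """
    paths: Sequence
    if isinstance(source, (str, Path)) or hasattr(source, "read"):
        paths = [source]
    else:
        paths = list(source)
    all_frames = []
    for src in paths:
        if hasattr(src, "read") or (isinstance(src, str) and "\n" in src):
            all_frames.append(_frames_from_pdb_text(_as_text(src), topology))
            continue
        path = Path(src)
        ext = path.suffix.lower()
        if ext in {".pdb", ".ent"}:
            all_frames.append(_frames_from_pdb_text(path.read_text(), topology))
        elif ext == ".xyz":
            all_frames.append(read_xyz(path, expected_atoms=topology.n_atoms))
        elif ext in {".xtc", ".dcd", ".trr"}:
            all_frames.append(_frames_from_binary(path, topology))
        else:
            raise ValueError(f"unsupported trajectory format: {ext!r}")
    frames = np.concatenate(all_frames, axis=0)
    return Trajectory(topology=topology, frames=frames, frame_interval=frame_interval,
                      temperature=temperature, label=label)


def _frames_from_pdb_text(text: str, topology: Structure) -> np.ndarray:
    _validate_pdb_text(text)
    st = gemmi.read_pdb_string(text)
    frames = []
    for model in st:
        coords = []
        for chain in model:
            for res in chain:
                for at in _resolve_altlocs(res):
                    coords.append([at.pos.x, at.pos.y, at.pos.z])
        arr = np.asarray(coords, dtype=float) * 0.1
        if arr.shape[0] != topology.n_atoms:
            raise AtomCountError(topology.n_atoms, arr.shape[0],
                                 f"model {model.num}")
        frames.append(arr)
    return np.stack(frames, axis=0)


def _frames_from_binary(path: Path, topology: Structure) -> np.ndarray:
    import mdtraj as md

    with tempfile.TemporaryDirectory() as tmp:
        top_path = os.path.join(tmp, "top.pdb")
        write_pdb(topology, top_path)
        try:
            traj = md.load(str(path), top=top_path)
        except Exception as exc:  # mdtraj raises plain exceptions on mismatch
            raise AtomCountError(topology.n_atoms, -1, f"{path.name}: {exc}") from exc
    if traj.n_atoms != topology.n_atoms:
        raise AtomCountError(topology.n_atoms, traj.n_atoms, path.name)
    return np.asarray(traj.xyz, dtype=float)  # mdtraj is already in nm


# ----------------------------------------------------------------------
# writing
# ----------------------------------------------------------------------

def _pdb_atom_line(serial: int, atom: Atom, res: ResidueInfo, pos_nm: np.ndarray) -> str:
    record = "HETATM" if (res.is_hetero or res.is_water) else "ATOM  "
    name = atom.name
    # PDB column convention: 1-3 char names start in column 14
    name_field = f" {name:<3s}" if len(name) < 4 else f"{name:<4s}"
    x, y, z = (float(v) * 10.0 for v in pos_nm)  # nm -> A
    return (
        f"{record}{serial:5d} {name_field} {res.name:<3s} {res.chain_id[:1] or 'A'}"
        f"{res.author_seq_id:4d}    {x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
        f"          {atom.element:>2s}"
    )


def write_pdb(structure: Structure, target, frames: np.ndarray | None = None) -> None:
    """Write a (multi-model) PDB file.

    ``frames`` omitted: single model from the structure's own coordinates.
    """
    res_by_index = {r.index: r for r in structure.residues}
    if frames is None:
        frames = structure.coords[None, :, :]
    frames = np.asarray(frames, dtype=float)
    if frames.shape[1] != structure.n_atoms:
        raise AtomCountError(structure.n_atoms, frames.shape[1], "write_pdb frames")
    multi = frames.shape[0] > 1
    own = isinstance(target, (str, Path))
    fh = open(target, "w") if own else target
    try:
        for m, frame in enumerate(frames, start=1):
            if multi:
                fh.write(f"MODEL     {m:4d}\n")
            for i, atom in enumerate(structure.atoms):
                res = res_by_index[atom.residue_index]
                fh.write(_pdb_atom_line(i + 1, atom, res, frame[i]) + "\n")
            fh.write("ENDMDL\n" if multi else "TER\n")
        fh.write("END\n")
    finally:
        if own:
            fh.close()


def write_xyz(structure: Structure, target, frames: np.ndarray | None = None) -> None:
    """Plain XYZ writer (angstrom, one block per frame) for fixtures."""
    if frames is None:
        frames = structure.coords[None, :, :]
    own = isinstance(target, (str, Path))
    fh = open(target, "w") if own else target
    try:
        for frame in np.asarray(frames, dtype=float):
            fh.write(f"{structure.n_atoms}\nfoldscape frame\n")
            for atom, pos in zip(structure.atoms, frame):
                x, y, z = pos * 10.0
                fh.write(f"{atom.element:<2s} {x:14.6f} {y:14.6f} {z:14.6f}\n")
    finally:
        if own:
            fh.close()


def read_xyz(source, expected_atoms: int | None = None) -> np.ndarray:
    """Read a multi-frame XYZ file into an (n_frames, n_atoms, 3) nm array."""
    text = _as_text(source)
    lines = text.splitlines()
    frames = []
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i].split()[0])
        except ValueError:
            raise ParseError("expected atom count", i + 1, lines[i]) from None
        block = lines[i + 2 : i + 2 + n]
        if len(block) < n:
            raise ParseError(f"truncated XYZ frame (wanted {n} atoms)", i + 1, lines[i])
        coords = []
        for j, ln in enumerate(block):
            parts = ln.split()
            if len(parts) < 4:
                raise ParseError("short XYZ atom line", i + 3 + j, ln)
            coords.append([float(parts[1]), float(parts[2]), float(parts[3])])
        arr = np.asarray(coords) * 0.1
        if expected_atoms is not None and arr.shape[0] != expected_atoms:
            raise AtomCountError(expected_atoms, arr.shape[0], "XYZ frame")
        frames.append(arr)
        i += 2 + n
    if not frames:
        raise ParseError("no frames in XYZ input")
    return np.stack(frames, axis=0)
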