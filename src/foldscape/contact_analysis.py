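"""Residue contact maps: native vs non-native contact bookkeeping.

Contacts are residue pairs within a distance cutoff (default 7 A) under
either a C-alpha or a minimum-heavy-atom metric.  Frequencies are the
fraction of ensemble frames in contact; each pair is classified against
the native structure's contacts at the same cutoff, so persistent
non-native pairs (interactions absent from the fold but stable in an
intermediate) can be pulled out directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .order_parameters import ca_indices
from .structure_io import Structure

__all__ = [
    "ContactMap",
    "residue_contact_map",
    "nonnative_pairs",
    "pair_distance_distribution",
]

A_PER_NM = 10.0
DEFAULT_CUTOFF_A = 7.0
DEFAULT_MIN_SEP = 3


@dataclass
class ContactMap:
    frequency: np.ndarray  # symmetric, in [0, 1]
    classification: np.ndarray  # 'native' | 'non_native' | 'absent'
    metric: str  # 'calpha' | 'min_heavy'
    cutoff: float  # A
    min_sep: int
    residue_ids: np.ndarray  # internal residue indices in matrix order


def _distance_matrix_series(frames: np.ndarray, structure: Structure, metric: str):
    """(n_frames, n_res, n_res) residue distance matrices in A."""
    res = structure.protein_residues()
    if metric == "calpha":
        idx = ca_indices(structure)
        if len(idx) != len(res):
            raise ValueError("C-alpha metric needs one CA per protein residue")
        sub = frames[:, idx, :]
        d = np.sqrt(((sub[:, :, None, :] - sub[:, None, :, :]) ** 2).sum(-1))
        return d * A_PER_NM, np.array([r.index for r in res])
    if metric == "min_heavy":
        groups = [
            structure.residue_atom_indices(r.index, heavy_only=True) for r in res
        ]
        n = len(res)
        out = np.zeros((frames.shape[0], n, n))
        for i in range(n):
            for j in range(i + 1, n):
                diff = frames[:, groups[i], None, :] - frames[:, None, groups[j], :]
                dmin = np.sqrt((diff ** 2).sum(-1)).min(axis=(1, 2))
                out[:, i, j] = out[:, j, i] = dmin
        return out * A_PER_NM, np.array([r.index for r in res])
    raise ValueError(f"unknown metric {metric!r}")


def residue_contact_map(frames: np.ndarray, structure: Structure,
                        native_coords: np.ndarray | None = None,
                        metric: str = "calpha",
                        cutoff: float = DEFAULT_CUTOFF_A,
                        min_sep: int = DEFAULT_MIN_SEP) -> ContactMap:
    """Contact frequencies of an ensemble, classified against the native map.

    ``native_coords`` defaults to the structure's own coordinates.  The
    diagonal band ``|i - j| < min_sep`` is excluded.
    """
    frames = np.asarray(frames, dtype=float)
    if frames.ndim == 2:
        frames = frames[None]
    if frames.shape[0] < 1:
        raise ValueError("need at least one frame")
    d_series, res_ids = _distance_matrix_series(frames, structure, metric)
    n = d_series.shape[1]
    band = np.abs(np.subtract.outer(np.arange(n), np.arange(n))) < min_sep
    freq = (d_series <= cutoff).mean(axis=0)
    freq[band] = 0.0

    native = structure.coords if native_coords is None else np.asarray(native_coords)
    d_native, _ = _distance_matrix_series(native[None], structure, metric)
    native_contact = d_native[0] <= cutoff
    native_contact[band] = False

    classification = np.full((n, n), "absent", dtype="<U10")
    classification[native_contact] = "native"
    classification[(freq > 0) & ~native_contact] = "non_native"
    return ContactMap(
        frequency=freq,
        classification=classification,
        metric=metric,
        cutoff=cutoff,
        min_sep=min_sep,
        residue_ids=res_ids,
    )


def nonnative_pairs(cmap: ContactMap, persistence_min: float = 0.5) -> pd.DataFrame:
    """Non-native pairs at or above a persistence threshold, by descending
    frequency (ties by residue pair for determinism)."""
    n = cmap.frequency.shape[0]
    rows = []
    for i in range(n):
        for j in range(i + 1, n):
            if cmap.classification[i, j] == "non_native" and \
                    cmap.frequency[i, j] >= persistence_min:
                rows.append(
                    {
                        "res_i": int(cmap.residue_ids[i]),
                        "res_j": int(cmap.residue_ids[j]),
                        "frequency": float(cmap.frequency[i, j]),
                    }
                )
    rows.sort(key=lambda r: (-r["frequency"], r["res_i"], r["res_j"]))
    return pd.DataFrame(rows, columns=["res_i", "res_j", "frequency"])


def pair_distance_distribution(frames: np.ndarray, structure: Structure,
                               residue_pair, bin_width: float = 0.5):
    """Normalized histogram of C-alpha distances (A) for one residue pair.

    Returns ``(bin_edges, density)`` with the histogram integrating to 1.
    """
    frames = np.asarray(frames, dtype=float)
    if frames.ndim == 2:
        frames = frames[None]
    i, j = residue_pair
    try:
        ai = structure.atom_index(i, "CA")
        aj = structure.atom_index(j, "CA")
    except KeyError as exc:
        raise ValueError(str(exc)) from None
    d = np.sqrt(((frames[:, ai] - frames[:, aj]) ** 2).sum(-1)) * A_PER_NM
    lo = np.floor(d.min() / bin_width) * bin_width
    hi = np.ceil(d.max() / bin_width) * bin_width
    if hi <= lo:
        hi = lo + bin_width
    edges = np.arange(lo, hi + bin_width / 2, bin_width)
    density, edges = np.histogram(d, bins=edges, density=True)
    return edges, density
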