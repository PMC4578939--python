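"""Two-dimensional free-energy maps over order-parameter pairs.

A map is a 2-D histogram of per-frame order parameters; the free energy of
cell *i* relative to the most probable cell is

    dA(i) = -R T ln(p_i / p_ref),      R = 8.314e-3 kJ/(mol K)

Unoccupied cells carry ``+inf`` (an explicit flag, never a sentinel
number).  Barriers between basins are the discrete minimax-path surrogate:
the smallest achievable maximum dA along any 8-connected path through
occupied cells.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

GAS_CONSTANT_KJ = 8.314e-3  # kJ / (mol K)

__all__ = [
    "FreeEnergyMap",
    "EnsembleSelection",
    "MeltingCurve",
    "build_map",
    "select_reference_cell",
    "extract_ensemble",
    "basin_barrier",
    "melting_curve",
    "fit_tm",
    "write_map",
    "plot_map",
]


@dataclass(frozen=True)
class Axis:
    name: str
    min: float
    max: float
    n_bins: int


@dataclass
class FreeEnergyMap:
    axis_x: Axis
    axis_y: Axis
    counts: np.ndarray  # (nx, ny) ints
    probability: np.ndarray
    delta_a: np.ndarray  # kJ/mol, +inf where unoccupied
    temperature: float  # K
    reference_cell: tuple

    @property
    def occupied(self) -> np.ndarray:
        return self.counts > 0


@dataclass
class EnsembleSelection:
    window_x: tuple
    window_y: tuple
    frame_indices: np.ndarray
    source_label: str = ""

    def __len__(self):
        return len(self.frame_indices)


@dataclass
class MeltingCurve:
    temperatures: np.ndarray  # K, strictly increasing
    fraction_unfolded: np.ndarray  # in [0, 1]
    unfolded_window: tuple = (0.3, 0.9)  # nm
    tm: float | None = None


def select_reference_cell(counts: np.ndarray) -> tuple:
    """Most-occupied cell; ties broken toward the lexicographically
    smallest (row, col) index."""
    counts = np.asarray(counts)
    if counts.size == 0 or counts.max() <= 0:
        raise ValueError("no occupied cells")
    flat = int(np.argmax(counts))  # argmax is first-in-C-order == lexicographic
    return np.unravel_index(flat, counts.shape)


def build_map(x_series, y_series, temperature: float, n_bins: int = 20,
              ranges=None, axis_names=("x", "y")) -> FreeEnergyMap:
    """Histogram two order-parameter series on an ``n_bins`` x ``n_bins``
    grid and convert occupancy to free energy.

    Bin ranges default to [min, max] of each series; points exactly on the
    maximum edge fall in the last bin (numpy histogram convention).
    """
    x = np.asarray(x_series, dtype=float)
    y = np.asarray(y_series, dtype=float)
    if x.size == 0 or x.shape != y.shape:
        raise ValueError("series must be non-empty and of equal length")
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    if ranges is None:
        ranges = ((x.min(), x.max()), (y.min(), y.max()))
    counts, xe, ye = np.histogram2d(x, y, bins=n_bins, range=ranges)
    counts = counts.astype(int)
    prob = counts / counts.sum()
    ref = select_reference_cell(counts)
    with np.errstate(divide="ignore"):
        delta_a = np.where(
            counts > 0,
            -GAS_CONSTANT_KJ * temperature * np.log(
                np.where(counts > 0, prob, 1.0) / prob[ref]
            ),
            np.inf,
        )
    return FreeEnergyMap(
        axis_x=Axis(axis_names[0], float(xe[0]), float(xe[-1]), n_bins),
        axis_y=Axis(axis_names[1], float(ye[0]), float(ye[-1]), n_bins),
        counts=counts,
        probability=prob,
        delta_a=delta_a,
        temperature=float(temperature),
        reference_cell=tuple(int(v) for v in ref),
    )


def extract_ensemble(x_series, y_series, window_x, window_y,
                     source_label: str = "") -> EnsembleSelection:
    """Frames with x and y inside the closed windows (inclusive bounds)."""
    x = np.asarray(x_series, dtype=float)
    y = np.asarray(y_series, dtype=float)
    for lo, hi in (window_x, window_y):
        if lo > hi:
            raise ValueError(f"window ({lo}, {hi}) has min > max")
    mask = (
        (x >= window_x[0]) & (x <= window_x[1])
        & (y >= window_y[0]) & (y <= window_y[1])
    )
    return EnsembleSelection(
        window_x=tuple(window_x), window_y=tuple(window_y),
        frame_indices=np.flatnonzero(mask), source_label=source_label,
    )


_NEIGHBORS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def basin_barrier(fes: FreeEnergyMap, cell_a: tuple, cell_b: tuple) -> float:
    """Minimax-path barrier between two occupied cells (kJ/mol).

    Over all 8-connected paths through occupied cells, take the minimum of
    the path maximum of dA, then subtract dA(cell_a).  Unreachable basins
    give ``inf``.
    """
    cell_a = tuple(cell_a)
    cell_b = tuple(cell_b)
    for c in (cell_a, cell_b):
        if not fes.occupied[c]:
            raise ValueError(f"cell {c} is unoccupied")
    if cell_a == cell_b:
        return 0.0
    # grow the occupied-cell set in order of increasing dA (Kruskal-style);
    # the threshold at which a and b join is the minimax path maximum.
    cells = [tuple(map(int, c)) for c in np.argwhere(fes.occupied)]
    cells.sort(key=lambda c: fes.delta_a[c])
    parent: dict = {}

    def find(c):
        while parent[c] != c:
            parent[c] = parent[parent[c]]
            c = parent[c]
        return c

    added = set()
    for cell in cells:
        parent[cell] = cell
        added.add(cell)
        for di, dj in _NEIGHBORS:
            nb = (cell[0] + di, cell[1] + dj)
            if nb in added:
                ra, rb = find(cell), find(nb)
                if ra != rb:
                    parent[ra] = rb
        if cell_a in added and cell_b in added and find(cell_a) == find(cell_b):
            return float(fes.delta_a[cell] - fes.delta_a[cell_a])
    return float("inf")


def melting_curve(rmsd_by_temperature: dict, unfolded_window=(0.3, 0.9)) -> MeltingCurve:
    """Fraction of frames whose RMSD lies inside the unfolded window,
    per temperature (the REMD melting-curve construction)."""
    if len(rmsd_by_temperature) < 2:
        raise ValueError("need at least two temperatures")
    temps = np.array(sorted(rmsd_by_temperature), dtype=float)
    fracs = []
    lo, hi = unfolded_window
    for t in temps:
        series = np.asarray(rmsd_by_temperature[t], dtype=float)
        if series.size == 0:
            raise ValueError(f"temperature {t} K has no frames")
        fracs.append(float(((series >= lo) & (series <= hi)).mean()))
    return MeltingCurve(temperatures=temps, fraction_unfolded=np.array(fracs),
                        unfolded_window=tuple(unfolded_window))


def _logistic(t, tm, width):
    return 1.0 / (1.0 + np.exp((tm - t) / width))


def fit_tm(curve: MeltingCurve) -> float:
    """Melting temperature: midpoint of a least-squares logistic fit to the
    0-1 (min-max) normalized unfolded fraction."""
    t = curve.temperatures
    f = curve.fraction_unfolded.astype(float)
    span = f.max() - f.min()
    if span <= 0:
        raise ValueError("melting curve is flat; no transition to fit")
    norm = (f - f.min()) / span
    if not (np.any(norm < 0.5) and np.any(norm > 0.5)):
        raise ValueError("normalized curve never crosses 0.5; Tm undefined")
    t0 = float(t[int(np.argmin(np.abs(norm - 0.5)))])
    w0 = max((t.max() - t.min()) / 10.0, 1e-3)
    popt, _ = curve_fit(_logistic, t, norm, p0=(t0, w0), maxfev=10000)
    tm = float(popt[0])
    if not (t.min() - 10.0 <= tm <= t.max() + 10.0):
        raise ValueError(f"fitted Tm {tm:.1f} K lies far outside the data range")
    curve.tm = tm
    return tm


def plot_map(fes: FreeEnergyMap, path, cmap: str = "viridis") -> None:
    """Filled-contour image of the free-energy map (kJ/mol color bar)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    finite = np.where(np.isfinite(fes.delta_a), fes.delta_a, np.nan)
    xs = np.linspace(fes.axis_x.min, fes.axis_x.max, fes.axis_x.n_bins)
    ys = np.linspace(fes.axis_y.min, fes.axis_y.max, fes.axis_y.n_bins)
    fig, ax = plt.subplots(figsize=(5, 4))
    im = ax.contourf(xs, ys, finite.T, levels=12, cmap=cmap)
    fig.colorbar(im, ax=ax, label=r"$\Delta A$ (kJ/mol)")
    ax.set_xlabel(fes.axis_x.name)
    ax.set_ylabel(fes.axis_y.name)
    ax.set_title(f"T = {fes.temperature:.0f} K")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def write_map(fes: FreeEnergyMap, tsv_path, json_path=None) -> None:
    """TSV matrix of dA plus JSON metadata (axes, temperature, reference)."""
    import json

    with open(tsv_path, "w") as fh:
        for row in fes.delta_a:
            fh.write("\t".join("inf" if not np.isfinite(v) else f"{v:.6f}" for v in row))
            fh.write("\n")
    if json_path is not None:
        meta = {
            "axis_x": vars(fes.axis_x) | {},
            "axis_y": vars(fes.axis_y) | {},
            "temperature_K": fes.temperature,
            "reference_cell": list(fes.reference_cell),
            "gas_constant_kJ_per_mol_K": GAS_CONSTANT_KJ,
        }
        with open(json_path, "w") as fh:
            json.dump(meta, fh, indent=2, sort_keys=True)
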