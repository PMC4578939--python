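"""Residue communication networks from inter-residue distance dynamics.

Commute time between residues i and j is the time-variance of their
C-alpha distance,

    CT(i, j) = < (d_ij - <d_ij>)^2 >,

low values meaning the pair moves as one rigid unit and hence
"communicates" efficiently.  Communication pathways are chains of residues
in which every adjacent pair shares a persistent non-bonded interaction
and every member pair has a commute time below a threshold (0.1 on the
max-normalized matrix by default).  Node degree over neighbor plus
interaction edges is the communication efficiency used to rank hubs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .order_parameters import ca_indices
from .structure_io import Structure, Trajectory

__all__ = [
    "CommuteTimeMatrix",
    "CommunicationNetwork",
    "neighbor_matrix",
    "interaction_matrix",
    "commute_time_matrix",
    "grow_pathways",
    "build_network",
    "communication_efficiency",
    "export_graph",
    "import_graph",
]

A_PER_NM = 10.0
NEIGHBOR_CUTOFF_A = 3.6  # time-averaged minimum heavy-atom distance
INTERACTION_CUTOFF_A = 3.9  # instantaneous non-bonded heavy-atom contact
INTERACTION_PERSISTENCE = 0.5
CT_THRESHOLD = 0.1  # on the max-normalized commute-time matrix


@dataclass
class CommuteTimeMatrix:
    values: np.ndarray  # A^2 (raw) or unitless (normalized)
    normalized: bool
    residue_ids: np.ndarray

    @property
    def n(self) -> int:
        return self.values.shape[0]


@dataclass
class CommunicationNetwork:
    graph: nx.Graph  # nodes = residue ids; edges typed via 'kind'
    pathways: list  # ordered residue chains
    ct: CommuteTimeMatrix
    thresholds: dict = field(default_factory=dict)


def _heavy_groups(structure: Structure):
    res = structure.protein_residues()
    return res, [structure.residue_atom_indices(r.index, heavy_only=True) for r in res]


def _min_distance_series(frames: np.ndarray, groups) -> np.ndarray:
    """(n_frames, n_res, n_res) minimum heavy-atom distances in A."""
    n = len(groups)
    out = np.zeros((frames.shape[0], n, n))
    for i in range(n):
        for j in range(i + 1, n):
            diff = frames[:, groups[i], None, :] - frames[:, None, groups[j], :]
            dmin = np.sqrt((diff ** 2).sum(-1)).min(axis=(1, 2))
            out[:, i, j] = out[:, j, i] = dmin
    return out * A_PER_NM


def neighbor_matrix(trajectory: Trajectory,
                    cutoff: float = NEIGHBOR_CUTOFF_A) -> np.ndarray:
    """True where the time-averaged minimum inter-residue heavy-atom
    distance is below the neighbor threshold."""
    structure = trajectory.topology
    _, groups = _heavy_groups(structure)
    mean_d = _min_distance_series(trajectory.frames, groups).mean(axis=0)
    out = mean_d < cutoff
    np.fill_diagonal(out, False)
    return out


def interaction_matrix(trajectory: Trajectory,
                       cutoff: float = INTERACTION_CUTOFF_A,
                       frame_fraction: float = INTERACTION_PERSISTENCE,
                       min_sep: int = 2) -> np.ndarray:
    """True where a non-bonded heavy-atom contact (<= cutoff, |i-j| >=
    min_sep) is present in at least ``frame_fraction`` of the frames."""
    structure = trajectory.topology
    _, groups = _heavy_groups(structure)
    d = _min_distance_series(trajectory.frames, groups)
    persist = (d <= cutoff).mean(axis=0)
    n = persist.shape[0]
    band = np.abs(np.subtract.outer(np.arange(n), np.arange(n))) < min_sep
    out = (persist >= frame_fraction) & ~band
    return out


def commute_time_matrix(trajectory: Trajectory, normalize: bool = True) -> CommuteTimeMatrix:
    """Population variance of every C-alpha pair distance over the frames."""
    if trajectory.n_frames < 2:
        raise ValueError("commute time needs at least two frames")
    structure = trajectory.topology
    idx = ca_indices(structure)
    sub = trajectory.frames[:, idx, :]
    d = np.sqrt(((sub[:, :, None, :] - sub[:, None, :, :]) ** 2).sum(-1)) * A_PER_NM
    ct = d.var(axis=0)  # population variance per pair
    np.fill_diagonal(ct, 0.0)
    ct = (ct + ct.T) / 2.0  # enforce exact symmetry against rounding
    normalized = False
    if normalize:
        peak = ct.max()
        if peak > 0:
            ct = ct / peak
        normalized = True
    res_ids = np.array([r.index for r in structure.protein_residues()])
    return CommuteTimeMatrix(values=ct, normalized=normalized, residue_ids=res_ids)


def grow_pathways(ct: CommuteTimeMatrix, interactions: np.ndarray,
                  ct_threshold: float = CT_THRESHOLD,
                  min_length: int = 3) -> list:
    """Greedy communication-pathway growth.

    Seed with the interacting pair of minimal CT; repeatedly append the
    residue (lowest index on ties) that interacts with at least one member
    and has CT <= threshold to *every* member; exhausted members leave the
    pool and the next seed starts.  Chains shorter than ``min_length`` are
    discarded.  Every adjacent pair in a reported pathway shares an
    interaction edge and all internal CT values respect the threshold.
    """
    n = ct.n
    pool = set(range(n))
    pathways = []
    while True:
        best = None
        for i in sorted(pool):
            for j in sorted(pool):
                if j <= i or not interactions[i, j]:
                    continue
                if ct.values[i, j] > ct_threshold:
                    continue
                key = (ct.values[i, j], i, j)
                if best is None or key < best:
                    best = key
        if best is None:
            break
        _, i, j = best
        members = [i, j]
        while True:
            candidates = []
            for k in sorted(pool - set(members)):
                if not any(interactions[k, m] for m in members):
                    continue
                if all(ct.values[k, m] <= ct_threshold for m in members):
                    candidates.append(k)
            if not candidates:
                break
            members.append(candidates[0])  # deterministic: lowest index
        pool -= set(members)
        if len(members) >= min_length:
            pathways.append([int(ct.residue_ids[m]) for m in members])
    return pathways


def build_network(trajectory: Trajectory,
                  ct_threshold: float = CT_THRESHOLD,
                  neighbor_cutoff: float = NEIGHBOR_CUTOFF_A,
                  interaction_cutoff: float = INTERACTION_CUTOFF_A,
                  frame_fraction: float = INTERACTION_PERSISTENCE,
                  normalize_ct: bool = True) -> CommunicationNetwork:
    """Assemble the full communication network of one ensemble."""
    nb = neighbor_matrix(trajectory, neighbor_cutoff)
    inter = interaction_matrix(trajectory, interaction_cutoff, frame_fraction)
    ct = commute_time_matrix(trajectory, normalize=normalize_ct)
    paths = grow_pathways(ct, inter, ct_threshold)
    g = nx.Graph()
    ids = ct.residue_ids
    path_members = {r for p in paths for r in p}
    for k, rid in enumerate(ids):
        g.add_node(int(rid), in_pathway=bool(int(rid) in path_members))
    pos = {int(rid): k for k, rid in enumerate(ids)}
    for a in range(len(ids)):
        for b in range(a + 1, len(ids)):
            if nb[a, b] or inter[a, b]:
                kind = "interaction" if inter[a, b] else "neighbor"
                g.add_edge(int(ids[a]), int(ids[b]), kind=kind,
                           ct=float(ct.values[a, b]))
    for p in paths:
        for u, v in zip(p, p[1:]):
            if g.has_edge(u, v):
                g[u][v]["kind"] = "pathway"
    for node in g.nodes:
        g.nodes[node]["degree"] = g.degree[node]
    return CommunicationNetwork(
        graph=g,
        pathways=paths,
        ct=ct,
        thresholds={
            "ct_threshold": ct_threshold,
            "neighbor_cutoff_A": neighbor_cutoff,
            "interaction_cutoff_A": interaction_cutoff,
            "frame_fraction": frame_fraction,
            "ct_normalized": normalize_ct,
        },
    )


def communication_efficiency(network: CommunicationNetwork) -> dict:
    """Node degree over neighbor + interaction edges, per residue."""
    return {node: int(network.graph.degree[node]) for node in network.graph.nodes}


def export_graph(network: CommunicationNetwork, path, fmt: str = "graphml") -> None:
    """Write the network as GraphML or GEXF for external graph tools."""
    if fmt == "graphml":
        nx.write_graphml(network.graph, path)
    elif fmt == "gexf":
        nx.write_gexf(network.graph, path)
    else:
        raise ValueError(f"unsupported graph format {fmt!r} (use 'graphml' or 'gexf')")


def import_graph(path, fmt: str = "graphml") -> nx.Graph:
    if fmt == "graphml":
        g = nx.read_graphml(path)
    elif fmt == "gexf":
        g = nx.read_gexf(path)
    else:
        raise ValueError(f"unsupported graph format {fmt!r} (use 'graphml' or 'gexf')")
    return nx.relabel_nodes(g, {n: int(n) for n in g.nodes})
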