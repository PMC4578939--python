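"""Commute-time matrices, communication pathways and graph export."""

import itertools

import numpy as np
import pytest

from foldscape import residue_network as rn
from foldscape import synthetic_data as syn
from foldscape.structure_io import Atom, ResidueInfo, Structure, Trajectory


def ca_only_structure(n):
    atoms, residues = [], []
    for k in range(n):
        residues.append(ResidueInfo(k, "ALA", "A", "A", k + 1))
        atoms.append(Atom(k, "CA", "C", k, "ALA", "A", [0.4 * k, 0.0, 0.0],
                          vdw_radius=0.187))
    return Structure(atoms=atoms, residues=residues)


def trajectory_from_distance(d_series):
    """Two-residue trajectory with a prescribed distance series (A)."""
    st = ca_only_structure(2)
    frames = np.zeros((len(d_series), 2, 3))
    frames[:, 1, 0] = np.asarray(d_series) / 10.0
    return Trajectory(topology=st, frames=frames)


class TestCommuteTime:
    def test_rigid_trajectory_all_zero(self, sheet6):
        frames = np.tile(sheet6.coords, (4, 1, 1))
        ct = rn.commute_time_matrix(Trajectory(topology=sheet6, frames=frames),
                                    normalize=False)
        assert np.allclose(ct.values, 0.0)

    def test_alternating_five_seven_gives_one(self):
        traj = trajectory_from_distance([5.0, 7.0] * 5)
        ct = rn.commute_time_matrix(traj, normalize=False)
        assert ct.values[0, 1] == pytest.approx(1.0)

    def test_symmetric_zero_diagonal(self, rng):
        st = ca_only_structure(5)
        frames = st.coords[None] + rng.normal(0, 0.05, (30, 5, 3))
        ct = rn.commute_time_matrix(Trajectory(topology=st, frames=frames),
                                    normalize=False)
        assert np.allclose(ct.values, ct.values.T)
        assert np.allclose(np.diag(ct.values), 0.0)
        assert (ct.values >= 0).all()

    def test_matches_direct_variance_oracle(self, rng):
        st = ca_only_structure(4)
        frames = st.coords[None] + rng.normal(0, 0.1, (50, 4, 3))
        ct = rn.commute_time_matrix(Trajectory(topology=st, frames=frames),
                                    normalize=False)
        for i, j in itertools.combinations(range(4), 2):
            d = np.linalg.norm(frames[:, i] - frames[:, j], axis=1) * 10
            assert ct.values[i, j] == pytest.approx(d.var(), rel=1e-9)

    def test_imposed_moment_process_exact(self):
        traj = syn.make_distance_process(mean=8.0, variance=1.5, n_frames=200, seed=5)
        ct = rn.commute_time_matrix(traj, normalize=False)
        assert ct.values[0, 1] == pytest.approx(1.5, abs=1e-10)
        zero = syn.make_distance_process(8.0, 0.0, 50, seed=5)
        ct0 = rn.commute_time_matrix(zero, normalize=False)
        assert ct0.values[0, 1] == 0.0

    def test_single_frame_rejected(self, sheet6):
        with pytest.raises(ValueError):
            rn.commute_time_matrix(Trajectory(topology=sheet6,
                                              frames=sheet6.coords[None]))

    def test_noise_does_not_shrink_ct(self, rng):
        st = ca_only_structure(4)
        base = st.coords[None] + rng.normal(0, 0.02, (200, 4, 3))
        noisy = base + rng.normal(0, 0.05, base.shape)
        ct_base = rn.commute_time_matrix(Trajectory(topology=st, frames=base),
                                         normalize=False)
        ct_noisy = rn.commute_time_matrix(Trajectory(topology=st, frames=noisy),
                                          normalize=False)
        off = ~np.eye(4, dtype=bool)
        assert ct_noisy.values[off].mean() > ct_base.values[off].mean()


class TestNeighborAndInteraction:
    def test_covalent_neighbors_true_distant_false(self, sheet6):
        frames = np.tile(sheet6.coords, (3, 1, 1))
        nb = rn.neighbor_matrix(Trajectory(topology=sheet6, frames=frames))
        assert nb[0, 1]
        far = sheet6.coords.copy()
        far[[a.index for a in sheet6.atoms if a.residue_index == 5]] += 3.0
        nb2 = rn.neighbor_matrix(
            Trajectory(topology=sheet6, frames=np.tile(far, (3, 1, 1)))
        )
        assert not nb2[0, 5]

    def test_neighbor_matches_direct_averaging(self, sheet6, rng):
        frames = sheet6.coords[None] + rng.normal(0, 0.02, (5, sheet6.n_atoms, 3))
        nb = rn.neighbor_matrix(Trajectory(topology=sheet6, frames=frames))
        groups = [sheet6.residue_atom_indices(r.index, heavy_only=True)
                  for r in sheet6.protein_residues()]
        for i, j in itertools.combinations(range(len(groups)), 2):
            dmin = np.mean([
                np.sqrt(((f[groups[i]][:, None] - f[groups[j]][None]) ** 2)
                        .sum(-1)).min()
                for f in frames
            ]) * 10
            assert nb[i, j] == (dmin < 3.6)

    def test_interaction_persistence_threshold(self, sheet6):
        near = sheet6.coords
        far = near.copy()
        far[[a.index for a in sheet6.atoms if a.chain_id == "B"]] += 5.0
        always = rn.interaction_matrix(
            Trajectory(topology=sheet6, frames=np.tile(near, (5, 1, 1)))
        )
        cross_pairs = [(i, j) for i in range(6) for j in range(6, 12) if always[i, j]]
        assert cross_pairs  # the sheet has persistent cross-strand contacts
        # present in 2 of 5 frames: below the 50 % rule
        inter = rn.interaction_matrix(
            Trajectory(topology=sheet6, frames=np.stack([near, near, far, far, far]))
        )
        assert not any(inter[i, j] for i, j in cross_pairs)
        # 3 of 5 frames: at or above
        inter = rn.interaction_matrix(
            Trajectory(topology=sheet6, frames=np.stack([near, near, near, far, far]))
        )
        assert all(inter[i, j] for i, j in cross_pairs)


class TestPathways:
    def _ct(self, values, ids=None):
        values = np.asarray(values, float)
        return rn.CommuteTimeMatrix(values=values, normalized=True,
                                    residue_ids=np.arange(values.shape[0])
                                    if ids is None else np.asarray(ids))

    def test_three_mutual_zero_ct_one_pathway(self):
        inter = np.ones((3, 3), bool) & ~np.eye(3, dtype=bool)
        ct = self._ct(np.zeros((3, 3)))
        assert rn.grow_pathways(ct, inter, 0.1) == [[0, 1, 2]]

    def test_high_ct_member_excluded(self):
        inter = np.ones((3, 3), bool) & ~np.eye(3, dtype=bool)
        vals = np.zeros((3, 3))
        vals[2, :2] = vals[:2, 2] = 0.5
        ct = self._ct(vals)
        assert rn.grow_pathways(ct, inter, 0.1) == []  # remaining pair < 3 long

    def test_growth_conditions_hold_and_no_feasible_extension_remains(self, rng):
        n = 5
        vals = rng.uniform(0, 0.3, (n, n))
        vals = (vals + vals.T) / 2
        np.fill_diagonal(vals, 0.0)
        inter = rng.uniform(size=(n, n)) < 0.7
        inter = inter | inter.T
        np.fill_diagonal(inter, False)
        ct = self._ct(vals)
        paths = rn.grow_pathways(ct, inter, ct_threshold=0.15)
        # re-check the reported growth conditions independently
        for path in paths:
            for member in path:
                assert any(inter[member, other] for other in path if other != member)
            for a, b in itertools.combinations(path, 2):
                assert vals[a, b] <= 0.15
        # maximality: no pool residue could still join the first pathway
        if paths:
            used = {r for p in paths for r in p}
            rest = set(range(n)) - used
            first = paths[0]
            for k in rest:
                joins = any(inter[k, m] for m in first)
                fits = all(vals[k, m] <= 0.15 for m in first)
                assert not (joins and fits)

    def test_empty_interaction_graph_empty_result(self):
        ct = self._ct(np.zeros((4, 4)))
        assert rn.grow_pathways(ct, np.zeros((4, 4), bool)) == []


@pytest.fixture(scope="module")
def two_domain():
    """Two rigid 3-residue clusters with inter-domain breathing."""
    rng = np.random.default_rng(9)
    st = ca_only_structure(6)
    base = st.coords
    frames = np.tile(base, (60, 1, 1))
    # domain B (residues 3-5) translates coherently frame to frame
    frames[:, 3:, 0] += rng.normal(0, 0.15, 60)[:, None]
    frames += rng.normal(0, 0.005, frames.shape)
    return Trajectory(topology=st, frames=frames)


class TestNetworkAndExport:
    def test_intra_domain_ct_below_inter_domain(self, two_domain):
        ct = rn.commute_time_matrix(two_domain, normalize=False)
        intra = [ct.values[i, j] for i, j in itertools.combinations(range(3), 2)]
        intra += [ct.values[i, j] for i, j in itertools.combinations(range(3, 6), 2)]
        inter = [ct.values[i, j] for i in range(3) for j in range(3, 6)]
        assert max(intra) < min(inter)

    def test_degree_sequence_handshake(self, two_domain):
        net = rn.build_network(two_domain)
        degrees = rn.communication_efficiency(net)
        assert sum(degrees.values()) == 2 * net.graph.number_of_edges()

    def test_pathway_edges_are_interaction_edges(self, two_domain):
        net = rn.build_network(two_domain)
        for path in net.pathways:
            for u, v in zip(path, path[1:]):
                assert net.graph.has_edge(u, v)

    @pytest.mark.parametrize("fmt,suffix", [("graphml", ".graphml"), ("gexf", ".gexf")])
    def test_export_import_round_trip(self, two_domain, tmp_path, fmt, suffix):
        net = rn.build_network(two_domain)
        path = tmp_path / f"net{suffix}"
        rn.export_graph(net, path, fmt)
        back = rn.import_graph(path, fmt)
        assert back.number_of_nodes() == net.graph.number_of_nodes()
        assert back.number_of_edges() == net.graph.number_of_edges()
        for node, data in net.graph.nodes(data=True):
            assert back.nodes[node]["degree"] == data["degree"]

    def test_unsupported_format_rejected(self, two_domain, tmp_path):
        net = rn.build_network(two_domain)
        with pytest.raises(ValueError):
            rn.export_graph(net, tmp_path / "x.bin", "pickle")

    def test_empty_network_exports_valid_file(self, tmp_path):
        import networkx as nx

        empty = rn.CommunicationNetwork(
            graph=nx.Graph(), pathways=[],
            ct=rn.CommuteTimeMatrix(np.zeros((0, 0)), True, np.array([])),
        )
        path = tmp_path / "empty.graphml"
        rn.export_graph(empty, path, "graphml")
        assert rn.import_graph(path).number_of_edges() == 0
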