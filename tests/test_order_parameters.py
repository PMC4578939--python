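"""Order parameters: contacts, rho/Q, RMSD, SASA, RMSF against oracles."""

import itertools

import numpy as np
import pytest

from foldscape import order_parameters as op
from foldscape import synthetic_data as syn
from foldscape._geometry import rotation_matrix
from foldscape.structure_io import Atom, ResidueInfo, Structure


def toy_structure(cb_positions, cutoff_names=None):
    """Four residues with a single CB 'side chain' each, CA stacked nearby."""
    atoms, residues = [], []
    for k, pos in enumerate(cb_positions):
        residues.append(ResidueInfo(k, "ALA", "A", "A", k + 1))
        atoms.append(Atom(len(atoms), "CA", "C", k, "ALA", "A",
                          np.asarray(pos) + [0.0, 0.0, 0.3]))
        atoms.append(Atom(len(atoms), "CB", "C", k, "ALA", "A", np.asarray(pos)))
    st = Structure(atoms=atoms, residues=residues)
    for a in st.atoms:
        a.vdw_radius = 0.17
    return st


class TestNativeContacts:
    def test_below_cutoff_present_above_absent(self):
        near = toy_structure([[0, 0, 0], [0.2, 0, 0], [0.35, 0, 0], [0.50, 0, 0]])
        cs = op.native_contacts(near, "sidechain", cutoff=0.55, min_sep=3)
        assert (0, 3) in cs.pairs  # 0.50 nm apart
        far = toy_structure([[0, 0, 0], [0.2, 0, 0], [0.35, 0, 0], [0.60, 0, 0]])
        cs = op.native_contacts(far, "sidechain", cutoff=0.55, min_sep=3)
        assert (0, 3) not in cs.pairs

    def test_matches_brute_force_all_pairs(self, rng):
        pos = rng.uniform(0, 1.2, (6, 3))
        st = toy_structure(pos)
        cs = op.native_contacts(st, "sidechain", cutoff=0.55, min_sep=2)
        expected = {
            (i, j)
            for i, j in itertools.combinations(range(6), 2)
            if j - i >= 2 and np.linalg.norm(pos[i] - pos[j]) <= 0.55
        }
        assert set(cs.pairs) == expected

    def test_glycine_contributes_no_sidechain_atoms(self):
        st = toy_structure([[0, 0, 0], [0.2, 0, 0], [0.35, 0, 0], [0.5, 0, 0]])
        # residue 0 becomes glycine: drop its CB
        atoms = [a for a in st.atoms if not (a.residue_index == 0 and a.name == "CB")]
        for k, a in enumerate(atoms):
            a.index = k
        st2 = Structure(atoms=atoms, residues=list(st.residues))
        cs = op.native_contacts(st2, "sidechain", cutoff=0.55, min_sep=3)
        assert all(0 not in pair for pair in cs.pairs)


class TestFractions:
    def test_native_frame_gives_one_and_displaced_zero(self, sheet6):
        cs = op.native_contacts(sheet6, "sidechain")
        assert op.rho(sheet6.coords, sheet6, cs) == 1.0
        blown = sheet6.coords * 10.0
        assert op.rho(blown, sheet6, cs) == 0.0

    def test_partial_fraction_matches_hand_count(self):
        st = toy_structure([[0, 0, 0], [0.3, 0, 0], [0.6, 0, 0], [0.5, 0.2, 0]])
        cs = op.native_contacts(st, "sidechain", cutoff=0.55, min_sep=2)
        assert len(cs) >= 2
        # displace the last residue far away; recount by brute force
        frame = st.coords.copy()
        moved = [a.index for a in st.atoms if a.residue_index == 3]
        frame[moved] += 5.0
        cb = {a.residue_index: a.index for a in st.atoms if a.name == "CB"}
        expected = np.mean(
            [np.linalg.norm(frame[cb[i]] - frame[cb[j]]) <= 0.55 for i, j in cs.pairs]
        )
        assert op.rho(frame, st, cs) == pytest.approx(expected)

    def test_q_requires_heavy_scope_and_rho_sidechain(self, sheet6):
        heavy = op.native_contacts(sheet6, "heavy")
        side = op.native_contacts(sheet6, "sidechain")
        with pytest.raises(ValueError):
            op.rho(sheet6.coords, sheet6, heavy)
        with pytest.raises(ValueError):
            op.q_fraction(sheet6.coords, sheet6, side)
        assert op.q_fraction(sheet6.coords, sheet6, heavy) == 1.0

    def test_empty_native_set_is_an_error(self, sheet6):
        import dataclasses

        empty = op.ContactSet(pairs=(), atom_scope="sidechain", cutoff=0.55,
                              min_sequence_separation=3)
        with pytest.raises(ValueError):
            op.rho(sheet6.coords, sheet6, empty)

    def test_monotone_under_isotropic_expansion(self, sheet6):
        cs = op.native_contacts(sheet6, "heavy")
        coords = sheet6.coords
        center = coords.mean(0)
        values = [
            op.q_fraction(center + s * (coords - center), sheet6, cs)
            for s in (1.0, 1.5, 2.0, 3.0)
        ]
        assert all(a >= b for a, b in zip(values, values[1:]))


class TestRmsd:
    def test_identity_and_rigid_motion_invariance(self, helix12):
        c = helix12.coords
        assert op.rmsd(c, c) == pytest.approx(0.0, abs=1e-12)
        rot = rotation_matrix([1, 1, 0], 63.0)
        moved = c @ rot.T + np.array([0.5, -0.2, 0.9])
        assert op.rmsd(moved, c) == pytest.approx(0.0, abs=1e-9)
        assert op.rmsd(moved, c) == pytest.approx(op.rmsd(c, moved), abs=1e-12)

    def test_matches_coarse_rotation_grid_oracle(self, rng):
        a = rng.normal(size=(4, 3))
        b = a + rng.normal(0, 0.1, (4, 3))
        fast = op.rmsd(a, b)
        # oracle: exhaustive coarse rotation grid, then local refinement
        ac = a - a.mean(0)
        bc = b - b.mean(0)

        def grid_best(center, span, step):
            best = (np.inf, center)
            for alpha in np.arange(center[0] - span, center[0] + span + 1e-9, step):
                for beta in np.arange(center[1] - span, center[1] + span + 1e-9, step):
                    for gamma in np.arange(center[2] - span, center[2] + span + 1e-9,
                                           step):
                        r = (rotation_matrix([0, 0, 1], alpha)
                             @ rotation_matrix([0, 1, 0], beta)
                             @ rotation_matrix([0, 0, 1], gamma))
                        d = ac @ r.T - bc
                        val = np.sqrt((d * d).sum() / 4)
                        if val < best[0]:
                            best = (val, (alpha, beta, gamma))
            return best

        best, center = grid_best((180.0, 90.0, 180.0), 180.0, 12.0)
        for span, step in ((12.0, 2.0), (2.0, 0.25)):
            best, center = grid_best(center, span, step)
        assert fast <= best + 1e-9  # grid search can never beat the optimum
        assert fast == pytest.approx(best, abs=2e-3)

    def test_too_few_atoms_raise(self):
        with pytest.raises(ValueError):
            op.rmsd(np.zeros((2, 3)), np.zeros((2, 3)))


class TestSasa:
    def _single_atom(self, radius=0.17):
        a = Atom(0, "CB", "C", 0, "ALA", "A", np.zeros(3), vdw_radius=radius,
                 polarity="nonpolar")
        return Structure(atoms=[a], residues=[ResidueInfo(0, "ALA", "A", "A", 1)])

    def test_isolated_atom_closed_form(self):
        st = self._single_atom(0.17)
        total, per_atom = op.sasa(st, probe_radius=0.14, dot_density=960)
        expect = 4 * np.pi * 0.31 ** 2
        assert total == pytest.approx(expect, rel=0.02)
        assert per_atom.sum() == pytest.approx(total)

    def test_fully_overlapping_pair_equals_one_sphere(self):
        atoms = [
            Atom(0, "C1", "C", 0, "ALA", "A", np.zeros(3), vdw_radius=0.17),
            Atom(1, "C2", "C", 0, "ALA", "A", np.zeros(3) + 1e-9, vdw_radius=0.17),
        ]
        st = Structure(atoms=atoms, residues=[ResidueInfo(0, "ALA", "A", "A", 1)])
        total, _ = op.sasa(st, probe_radius=0.14, dot_density=960)
        assert total == pytest.approx(4 * np.pi * 0.31 ** 2, rel=0.02)

    def test_partial_overlap_matches_spherical_cap_formula(self):
        d = 0.4
        r = 0.17 + 0.14
        atoms = [
            Atom(0, "C1", "C", 0, "ALA", "A", np.zeros(3), vdw_radius=0.17),
            Atom(1, "C2", "C", 0, "ALA", "A", [d, 0, 0], vdw_radius=0.17),
        ]
        st = Structure(atoms=atoms, residues=[ResidueInfo(0, "ALA", "A", "A", 1)])
        total, per_atom = op.sasa(st, probe_radius=0.14, dot_density=960)
        # equal spheres: each loses a cap of height h = r - d/2
        h = r - d / 2
        expect_per_atom = 4 * np.pi * r ** 2 - 2 * np.pi * r * h
        assert per_atom[0] == pytest.approx(expect_per_atom, rel=0.02)
        assert total == pytest.approx(2 * expect_per_atom, rel=0.02)

    def test_low_dot_density_rejected(self):
        st = self._single_atom()
        with pytest.raises(ValueError):
            op.sasa(st, dot_density=16)

    def test_per_atom_non_negative_and_sum_to_total(self, sheet6):
        total, per_atom = op.sasa(sheet6, dot_density=128)
        assert (per_atom >= 0).all()
        assert per_atom.sum() == pytest.approx(total)


class TestRmsf:
    def test_static_trajectory_is_zero(self, helix10):
        frames = np.stack([helix10.coords] * 5)
        assert np.allclose(op.rmsf(frames, helix10), 0.0)

    def test_single_oscillating_residue_closed_form(self, helix10):
        frames = np.stack([helix10.coords] * 2)
        ca = op.ca_indices(helix10)
        # displace all atoms rigidly is removed by superposition; move one CA
        frames[0, ca[4], 0] += 0.1
        frames[1, ca[4], 0] -= 0.1
        out = op.rmsf(frames, helix10, n_passes=0)
        assert out[4] == pytest.approx(0.1, rel=1e-6)
        others = np.delete(out, 4)
        assert np.allclose(others, 0.0, atol=1e-9)

    def test_matches_direct_variance_oracle(self, helix10, rng):
        frames = helix10.coords[None] + rng.normal(0, 0.02, (30, helix10.n_atoms, 3))
        ca = op.ca_indices(helix10)
        out = op.rmsf(frames, helix10, n_passes=0)
        sub = frames[:, ca, :]
        direct = np.sqrt(((sub - sub.mean(0)) ** 2).sum(-1).mean(0))
        np.testing.assert_allclose(out, direct, rtol=1e-9)

    def test_single_frame_rejected(self, helix10):
        with pytest.raises(ValueError):
            op.rmsf(helix10.coords[None], helix10)
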