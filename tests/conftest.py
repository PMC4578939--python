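"""Shared fixtures: idealized templates and planted-truth ensembles.

Everything is generated programmatically; expensive constructions are
session-scoped so the whole suite builds them once.
"""

import numpy as np
import pytest

from foldscape import synthetic_data as syn


@pytest.fixture(scope="session")
def helix12():
    return syn.make_ideal_helix(12)


@pytest.fixture(scope="session")
def helix10():
    return syn.make_ideal_helix(10)


@pytest.fixture(scope="session")
def extended10():
    return syn.make_extended_chain(10)


@pytest.fixture(scope="session")
def sheet6():
    return syn.make_antiparallel_sheet(6)


@pytest.fixture(scope="session")
def phantom():
    return syn.make_patch_phantom()


@pytest.fixture(scope="session")
def unfolding_ensemble():
    return syn.make_unfolding_ensemble(n_frames=10, seed=0)


@pytest.fixture(scope="session")
def solvated():
    return syn.make_solvated_peptide(n_residues=3, n_waters=50, seed=3)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


TWO_ATOM_PDB = """\
ATOM      1  N   ALA A   1      11.104   6.134  -6.504  1.00  0.00           N
ATOM      2  CA  ALA A   1      11.639   6.071  -5.147  1.00  0.00           C
END
"""


@pytest.fixture()
def two_atom_pdb():
    return TWO_ATOM_PDB
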