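import numpy as np
import pytest

from pairpot.fixtures import FixtureSpec, make_chain, make_training_set
from pairpot.structure_io import Atom, Chain, Residue


@pytest.fixture(scope="session")
def ala10():
    """10-residue all-alanine chain (helix fold)."""
    return make_chain(FixtureSpec(10, "ALA", "helix", seed=1))


@pytest.fixture(scope="session")
def gly10():
    return make_chain(FixtureSpec(10, "GLY", "helix", seed=1))


@pytest.fixture(scope="session")
def mixed_chain():
    """24-residue random-sequence compact chain."""
    return make_chain(FixtureSpec(24, "random", "mixed", seed=11))


@pytest.fixture(scope="session")
def small_training_set():
    """20 short chains for fast training tests."""
    return make_training_set(20, FixtureSpec(30, "random", "mixed"), seed=5)


def build_residue(res_type, seq_index, atom_coords):
    """Residue from {atom_name: (x, y, z)}."""
    atoms = [Atom(name, name[0], np.array(xyz, dtype=float))
             for name, xyz in atom_coords.items()]
    return Residue(res_type, seq_index, atoms)


def ca_only_chain(positions, res_type="ALA", seq_indices=None):
    """Chain of CA-only residues at the given coordinates.

    Default sequence numbering is 1, 4, 7, ... so every pair passes the
    separation filter.
    """
    if seq_indices is None:
        seq_indices = [1 + 3 * i for i in range(len(positions))]
    residues = [build_residue(res_type, idx, {"CA": p})
                for idx, p in zip(seq_indices, positions)]
    return Chain("A", residues)
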