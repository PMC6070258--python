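"""Shared fixtures: small structures and planted synthetic trajectories."""

import numpy as np
import pytest

from mdscope import synthetic as syn


@pytest.fixture(scope="session")
def gaussian_small():
    """Small planted-mode Gaussian trajectory for fast unit tests."""
    return syn.gen_gaussian_traj(n_residues=30, n_frames=4000, seed=101)


@pytest.fixture(scope="session")
def hinge():
    """Two-arm hinge trajectory with a 20-degree planted oscillation."""
    return syn.gen_two_domain_hinge(n_frames=1500, seed=202)


@pytest.fixture(scope="session")
def double_well_pair():
    """Free/bound double-well runs sharing one planted mode basis."""
    free = syn.gen_double_well(n_frames=30000, occupancy=0.8, seed=303, mode_seed=9)
    bound = syn.gen_double_well(n_frames=30000, occupancy=0.2, seed=304, mode_seed=9)
    return free, bound


@pytest.fixture(scope="session")
def hbond_fixture():
    return syn.gen_hbond_fixture(seed=5)


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def tiny_structure():
    """3-residue peptide-like structure with hydrogens for selection tests."""
    from mdscope.io import Structure

    names = ["N", "CA", "C", "H", "N", "CA", "C", "H", "N", "CA", "C", "H", "HB1", "HB2"]
    elements = [n[0] for n in names]
    resids = [1, 1, 1, 1, 2, 2, 2, 2, 3, 3, 3, 3, 3, 3]
    n = len(names)
    rng = np.random.default_rng(7)
    return Structure(
        atom_serial=np.arange(1, n + 1),
        atom_name=np.array(names),
        residue_name=np.array(["ALA"] * n),
        residue_id=np.array(resids),
        chain_id=np.array(["A"] * n),
        coords=rng.normal(0, 3, (n, 3)),
        bfactor=np.linspace(10, 20, n),
        element=np.array(elements),
    )
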