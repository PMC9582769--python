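import numpy as np
import pytest

from dnadock import assign_forcefield, toy_dna, toy_protein
from dnadock.structure import Structure


@pytest.fixture(scope="session")
def tables():
    from dnadock.forcefield import load_parameter_tables
    return load_parameter_tables()


@pytest.fixture(scope="session")
def helix6():
    return assign_forcefield(toy_protein(6))


@pytest.fixture(scope="session")
def duplex8():
    return assign_forcefield(toy_dna("ACGTACGT"))


@pytest.fixture(scope="session")
def duplex22():
    return assign_forcefield(toy_dna("ACGTACGTACGTACGTACGTAC"))


def random_annotated(n_atoms: int, seed: int, moltype: str = "protein",
                     box: float = 15.0, center=(0.0, 0.0, 0.0)) -> Structure:
    """Random annotated structure for energy-oracle tests (arbitrary but
    valid charges/radii, single chain)."""
    rng = np.random.default_rng(seed)
    coords = rng.uniform(-box / 2, box / 2, (n_atoms, 3)) + np.asarray(center)
    s = Structure(names=["C"] * n_atoms, resnames=["ALA"] * n_atoms,
                  chains=["X"] * n_atoms,
                  resseqs=np.arange(1, n_atoms + 1),
                  coords=coords, elements=["C"] * n_atoms, moltype=moltype)
    s.charges = rng.uniform(-0.9, 0.9, n_atoms)
    s.vdw_rstar = rng.uniform(1.5, 2.1, n_atoms)
    s.vdw_eps = rng.uniform(0.05, 0.25, n_atoms)
    s.asp = rng.uniform(-0.05, 0.05, n_atoms)
    s.atom_types = ["CT"] * n_atoms
    return s
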