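import numpy as np
import pytest

from cetptunnel.synthetic import BarrelSpec, make_barrel, make_ligand_trajectory, make_rod_ligand


@pytest.fixture(scope="session")
def ile_barrel():
    """Short all-ILE barrel with a 3.3-Å inner radius and its axial path."""
    spec = BarrelSpec(axis_length=10.0, inner_radius=3.3, atoms_per_ring=16,
                      ring_residues=("ILE",))
    structure, path = make_barrel(spec)
    return spec, structure, path


@pytest.fixture(scope="session")
def narrow_barrel():
    """All-ILE barrel tight enough for a 2.4-Å contact criterion to fire.

    Inner radius 1.0 Å with 0.8-Å atoms puts wall-atom centers 1.8 Å from
    the axis, inside the contact cutoff of an axial ligand.
    """
    spec = BarrelSpec(axis_length=12.0, inner_radius=1.0, atom_vdw_radius=0.8,
                      atoms_per_ring=12, ring_residues=("ILE",))
    structure, path = make_barrel(spec)
    return spec, structure, path


@pytest.fixture(scope="session")
def narrow_trajectory(narrow_barrel):
    """Axial rod-ligand trajectory through the narrow barrel."""
    _, _, path = narrow_barrel
    ligand = make_rod_ligand(length=4.0, n_atoms=4, vdw_radius=0.8)
    return make_ligand_trajectory(path, ligand, lambda s: np.array([0.0, 0.0, 1.0]))
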