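import numpy as np
import pytest

from synthonic.crystal_io import (Atom, CrystalStructure, Molecule,
                                  SymmetryOp, UnitCell)
from synthonic.synthetic_data import (make_chain_fixture, make_hbonded_fixture,
                                      make_random_fixture, table2_cells)


@pytest.fixture(scope="session")
def chain_bundle():
    return make_chain_fixture()


@pytest.fixture(scope="session")
def hbond_bundle():
    return make_hbonded_fixture(seed=3)


@pytest.fixture(scope="session")
def random_bundles():
    return [make_random_fixture(seed) for seed in range(1, 6)]


@pytest.fixture(scope="session")
def form_cells():
    return table2_cells()


def cell_only_structure(form_cell, frac=(0.13, 0.21, 0.17)):
    """One-atom structure carrying a reference cell, for crystallography ops."""
    from synthonic.crystal_io import _BUILTIN_SPACEGROUPS
    ops = [SymmetryOp.from_xyz(t)
           for t in _BUILTIN_SPACEGROUPS[form_cell.space_group]]
    mol = Molecule(atoms=[Atom("C", "C1", np.array(frac))], bonds=[],
                   cell=form_cell.cell)
    return CrystalStructure(cell=form_cell.cell, symmetry_ops=ops,
                            molecules=[mol], space_group=form_cell.space_group)


def simple_p1(cell_lengths, atoms_spec, bonds=()):
    """P1 structure from explicit Cartesian atom positions.

    ``atoms_spec``: list of (element, label, cartesian xyz, charge).
    """
    cell = UnitCell(*cell_lengths)
    atoms = [Atom(el, lab, cell.to_fractional(np.asarray(xyz, float)),
                  charge=q)
             for el, lab, xyz, q in atoms_spec]
    mol = Molecule(atoms=atoms, bonds=list(bonds), cell=cell)
    return CrystalStructure(cell=cell, symmetry_ops=[SymmetryOp.from_xyz("x,y,z")],
                            molecules=[mol], space_group="P1")
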