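"""Unit tests for CIF parsing, symmetry expansion and molecule perception."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from synthonic.crystal_io import (Atom, CifParseError, CrystalStructure,
                                  Molecule, NotMolecularCrystalError,
                                  SymmetryOp, UnitCell,
                                  UnsupportedSymmetryError,
                                  add_hydroxyl_hydrogen, expand_cluster,
                                  perceive_molecules, read_charge_file,
                                  read_cif, write_charge_file, write_cif)
from conftest import simple_p1

FORM_I_CIF = """data_form_i_cell
_symmetry_space_group_name_H-M 'P21'
_cell_length_a 13.344
_cell_length_b 5.2150
_cell_length_c 26.693
_cell_angle_alpha 90
_cell_angle_beta 103.456
_cell_angle_gamma 90
loop_
_atom_site_label
_atom_site_type_symbol
_atom_site_fract_x
_atom_site_fract_y
_atom_site_fract_z
C1 C 0.10 0.20 0.30
"""


class TestUnitCell:
    def test_monoclinic_volume_matches_closed_form(self):
        cell = UnitCell(13.344, 5.2150, 26.693, 90.0, 103.456, 90.0)
        closed = (13.344 * 5.2150 * 26.693
                  * np.sin(np.radians(103.456)))
        assert cell.volume == pytest.approx(closed, abs=1e-9)
        assert cell.volume == pytest.approx(1806.55, abs=0.5)

    def test_orthorhombic_volume(self):
        cell = UnitCell(9.831, 18.485, 20.261)
        assert cell.volume == pytest.approx(9.831 * 18.485 * 20.261, abs=1e-9)
        assert cell.volume == pytest.approx(3681.95, abs=0.5)

    def test_metric_tensor_symmetric_positive_definite(self):
        cell = UnitCell(13.344, 5.2150, 26.693, 90.0, 103.456, 90.0)
        g = cell.metric_tensor
        assert np.allclose(g, g.T)
        assert np.all(np.linalg.eigvalsh(g) > 0)

    @pytest.mark.parametrize("bad", [dict(a=-1, b=5, c=5),
                                     dict(a=5, b=5, c=5, beta=185.0)])
    def test_invalid_cells_rejected(self, bad):
        with pytest.raises(ValueError):
            UnitCell(**{"a": 5, "b": 5, "c": 5, **bad})

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(st.tuples(*[st.floats(4.0, 30.0) for _ in range(3)]),
           st.tuples(*[st.floats(70.0, 110.0) for _ in range(3)]),
           st.tuples(*[st.floats(-2.0, 3.0) for _ in range(3)]))
    def test_frac_cart_roundtrip(self, lengths, angles, point):
        cell = UnitCell(*lengths, *angles)
        frac = np.array(point)
        back = cell.to_fractional(cell.to_cartesian(frac))
        assert np.allclose(back, frac, atol=1e-10)


class TestReadCif:
    def test_cell_and_symmetry_from_symbol(self, tmp_path):
        path = tmp_path / "form_i.cif"
        path.write_text(FORM_I_CIF)
        s = read_cif(path)
        assert s.cell.volume == pytest.approx(1806.55, abs=0.5)
        assert len(s.symmetry_ops) == 2          # P2_1 from the built-in table
        assert s.z == 2

    def test_cubic_p1_single_atom(self, tmp_path):
        cif = ("data_x\n_symmetry_space_group_name_H-M 'P1'\n"
               "_cell_length_a 10\n_cell_length_b 10\n_cell_length_c 10\n"
               "_cell_angle_alpha 90\n_cell_angle_beta 90\n_cell_angle_gamma 90\n"
               "loop_\n_atom_site_label\n_atom_site_fract_x\n_atom_site_fract_y\n"
               "_atom_site_fract_z\nC1 0.5 0.5 0.5\n")
        path = tmp_path / "cube.cif"
        path.write_text(cif)
        s = perceive_molecules(read_cif(path))
        assert s.cell.volume == pytest.approx(1000.0)
        assert s.z == 1 and s.z_prime == 1

    def test_p212121_generates_four_images(self, tmp_path, hbond_bundle):
        path = tmp_path / "hb.cif"
        hbond_bundle.write(path)
        s = read_cif(path)
        assert len(s.symmetry_ops) == 4
        assert len(s.unit_cell_molecules()) == 4

    def test_missing_cell_names_block(self, tmp_path):
        path = tmp_path / "bad.cif"
        path.write_text("data_x\nloop_\n_atom_site_label\nC1\n")
        with pytest.raises(CifParseError, match="_cell_length_a"):
            read_cif(path)

    def test_missing_atoms_names_block(self, tmp_path):
        path = tmp_path / "bad.cif"
        path.write_text("data_x\n_cell_length_a 10\n_cell_length_b 10\n"
                        "_cell_length_c 10\n_cell_angle_alpha 90\n"
                        "_cell_angle_beta 90\n_cell_angle_gamma 90\n"
                        "_symmetry_space_group_name_H-M 'P1'\n")
        with pytest.raises(CifParseError, match="atom-site"):
            read_cif(path)

    def test_unknown_spacegroup_without_operators(self, tmp_path):
        path = tmp_path / "bad.cif"
        path.write_text(FORM_I_CIF.replace("'P21'", "'Fdd2'"))
        with pytest.raises(UnsupportedSymmetryError, match="Fdd2"):
            read_cif(path)


class TestPerception:
    def test_bonded_pair_becomes_one_molecule(self):
        s = simple_p1((10, 10, 10), [("C", "C1", (5, 5, 5), 0.0),
                                     ("H", "H1", (6, 5, 5), 0.0)])
        out = perceive_molecules(s)
        assert out.z_prime == 1
        assert len(out.molecules[0].atoms) == 2
        assert out.molecules[0].bonds == [(0, 1)]

    def test_waterlike_bonds_are_intramolecular_only(self):
        # O-H at 0.96 Å bonds; intermolecular O···O at 2.8 Å does not
        s = simple_p1((2.8, 12, 12), [("O", "O1", (0, 0, 0), 0.0),
                                      ("H", "H1", (0.55, 0.79, 0), 0.0)])
        out = perceive_molecules(s)
        assert out.z_prime == 1
        assert out.molecules[0].bonds == [(0, 1)]

    def test_molecule_straddling_cell_edge_made_whole(self):
        # diatomic split across the a boundary: x = 0.95 and 0.05
        cell = UnitCell(10, 10, 10)
        atoms = [Atom("C", "C1", np.array([0.95, 0.5, 0.5])),
                 Atom("N", "N1", np.array([0.05, 0.5, 0.5]))]
        s = CrystalStructure(cell=cell,
                             symmetry_ops=[SymmetryOp.from_xyz("x,y,z")],
                             molecules=[Molecule(atoms=atoms, bonds=[],
                                                 cell=cell)])
        out = perceive_molecules(s)
        mol = out.molecules[0]
        assert len(mol.atoms) == 2 and mol.bonds == [(0, 1)]
        d = np.linalg.norm(np.diff(mol.cart_coords, axis=0))
        assert d == pytest.approx(1.0, abs=1e-9)  # whole, not 9 Å apart

    def test_periodic_covalent_network_rejected(self):
        # atoms 1.5 Å apart tiling a 3 Å axis: an infinite chain
        s = simple_p1((3.0, 12, 12), [("C", "C1", (0, 0, 0), 0.0),
                                      ("C", "C2", (1.5, 0, 0), 0.0)])
        with pytest.raises(NotMolecularCrystalError):
            perceive_molecules(s)


class TestExpandCluster:
    def test_chain_neighbour_counts(self, chain_bundle):
        s = chain_bundle.structure
        assert len(expand_cluster(s, 6.0)) == 2     # ±b only
        assert len(expand_cluster(s, 11.0)) == 4    # ±b, ±2b

    def test_counts_match_supercell_enumeration(self, random_bundles):
        s = random_bundles[0].structure
        radius = 15.0
        cluster = expand_cluster(s, radius)
        # O(N^3) brute-force supercell count
        c0 = s.molecules[0].centroid
        frac0 = s.molecules[0].frac_coords.mean(axis=0)
        count = 0
        for ta in range(-4, 5):
            for tb in range(-4, 5):
                for tc in range(-4, 5):
                    if (ta, tb, tc) == (0, 0, 0):
                        continue
                    cen = s.cell.to_cartesian(frac0 + [ta, tb, tc])
                    if np.linalg.norm(cen - c0) <= radius:
                        count += 1
        assert len(cluster) == count

    def test_membership_invariant_under_lattice_image_choice(self, hbond_bundle):
        s = hbond_bundle.structure
        base = sorted(round(np.linalg.norm(m.centroid
                                           - s.molecules[0].centroid), 6)
                      for m in expand_cluster(s, 10.0))
        shifted = CrystalStructure(
            cell=s.cell, symmetry_ops=s.symmetry_ops,
            molecules=[s.molecules[0].transformed(
                SymmetryOp.from_xyz("x,y,z"), (1, -1, 1))],
            space_group=s.space_group)
        moved = sorted(round(np.linalg.norm(m.centroid
                                            - shifted.molecules[0].centroid), 6)
                       for m in expand_cluster(shifted, 10.0))
        assert base == moved

    def test_tiny_radius_gives_empty_list(self, chain_bundle):
        assert expand_cluster(chain_bundle.structure, 2.0) == []


class TestUtilities:
    def test_add_hydroxyl_hydrogen_placement(self):
        s = simple_p1((10, 10, 10), [("O", "O1", (5, 5, 5), 0.0)])
        mol = add_hydroxyl_hydrogen(s.molecules[0], "O1", direction=(0, 0, 1))
        assert len(mol.atoms) == 2
        d = np.linalg.norm(mol.cart_coords[1] - mol.cart_coords[0])
        assert d == pytest.approx(0.97, abs=1e-9)
        with pytest.raises(ValueError, match="O9"):
            add_hydroxyl_hydrogen(s.molecules[0], "O9")

    def test_charge_file_roundtrip(self, tmp_path, hbond_bundle):
        mol = hbond_bundle.structure.molecules[0]
        path = tmp_path / "charges.txt"
        write_charge_file(mol, path)
        charges = read_charge_file(path)
        assert charges == {a.label: pytest.approx(a.charge, abs=1e-6)
                           for a in mol.atoms}

    def test_cif_roundtrip_preserves_structure(self, tmp_path, hbond_bundle):
        path = tmp_path / "round.cif"
        write_cif(hbond_bundle.structure, path, include_charges=True)
        back = read_cif(path)
        orig = hbond_bundle.structure
        assert back.cell.a == pytest.approx(orig.cell.a, abs=1e-5)
        got = back.molecules[0]
        want = orig.molecules[0]
        assert [a.element for a in got.atoms] == [a.element for a in want.atoms]
        assert np.allclose(got.frac_coords, want.frac_coords, atol=1e-7)
        assert np.allclose(got.charges, want.charges, atol=1e-5)
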