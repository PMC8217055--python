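"""Lattice-energy sums, convergence shells, synthons, fragments, H-bonds."""

import numpy as np
import pytest

from synthonic.crystal_io import CrystalStructure, SymmetryOp, expand_cluster
from synthonic.lattice_analysis import (convergence_profile,
                                        fragment_partition, hbond_inventory,
                                        identify_synthons, lattice_energy,
                                        pair_records)
from synthonic.synthetic_data import supercell_oracle

from conftest import simple_p1


class TestLatticeEnergy:
    def test_chain_equals_pair_energy(self, chain_bundle):
        res = lattice_energy(chain_bundle.structure, chain_bundle.forcefield,
                             radius=6.0)
        assert res.e_cr == pytest.approx(-10.0, abs=1e-12)

    def test_matches_supercell_oracle_on_seeded_fixtures(self, random_bundles):
        for bundle in random_bundles:
            res = lattice_energy(bundle.structure, bundle.forcefield,
                                 radius=15.0)
            oracle = supercell_oracle(bundle.structure, bundle.forcefield,
                                      n=5, radius=15.0)
            assert res.e_cr == pytest.approx(oracle, abs=1e-8)

    def test_matches_oracle_on_hbonded_screw_fixture(self, hbond_bundle):
        res = lattice_energy(hbond_bundle.structure, hbond_bundle.forcefield,
                             radius=12.0)
        oracle = supercell_oracle(hbond_bundle.structure,
                                  hbond_bundle.forcefield, n=3, radius=12.0)
        assert res.e_cr == pytest.approx(oracle, abs=1e-8)

    def test_doubling_charges_quadruples_coulomb(self, hbond_bundle):
        import copy
        s = hbond_bundle.structure
        base = lattice_energy(s, hbond_bundle.forcefield, radius=10.0)
        doubled = copy.deepcopy(s)
        for atom in doubled.molecules[0].atoms:
            atom.charge *= 2.0
        res = lattice_energy(doubled, hbond_bundle.forcefield, radius=10.0)
        assert res.breakdown.e_coulomb == pytest.approx(
            4.0 * base.breakdown.e_coulomb, rel=1e-12)

    def test_translation_invariance(self, hbond_bundle):
        s = hbond_bundle.structure
        base = lattice_energy(s, hbond_bundle.forcefield, radius=10.0)
        # a lattice translation moves the molecule to an equivalent origin
        # relative to the screw axes, so E_cr must be unchanged
        lattice_shifted = CrystalStructure(
            cell=s.cell, symmetry_ops=s.symmetry_ops,
            molecules=[s.molecules[0].transformed(
                SymmetryOp.from_xyz("x,y,z"), (2, -1, 1))],
            space_group=s.space_group)
        res = lattice_energy(lattice_shifted, hbond_bundle.forcefield,
                             radius=10.0)
        assert res.e_cr == pytest.approx(base.e_cr, abs=1e-9)

    def test_unconverged_sum_warns(self, chain_bundle):
        with pytest.warns(UserWarning, match="not converged"):
            lattice_energy(chain_bundle.structure, chain_bundle.forcefield,
                           radius=6.0)

    def test_tiny_radius_rejected(self, chain_bundle):
        with pytest.raises(ValueError):
            lattice_energy(chain_bundle.structure, radius=3.0)


class TestConvergenceProfile:
    def test_chain_energy_all_in_first_shell(self, chain_bundle):
        prof = convergence_profile(chain_bundle.structure,
                                   chain_bundle.forcefield, radius=8.0,
                                   shell_edges=(0.0, 9.0))
        assert prof.shell_percent[0] == pytest.approx(100.0, abs=1e-6)
        assert prof.convergence_radius <= 6.0

    def test_shell_percentages_telescope(self, hbond_bundle):
        prof = convergence_profile(hbond_bundle.structure,
                                   hbond_bundle.forcefield, radius=20.0,
                                   shell_edges=(0, 9, 14, 20))
        assert prof.shell_percent.sum() == pytest.approx(100.0, abs=1e-6)
        assert prof.cumulative[-1] == pytest.approx(
            prof.shell_energies.sum(), abs=1e-9)

    def test_cumulative_final_equals_lattice_energy(self, hbond_bundle):
        prof = convergence_profile(hbond_bundle.structure,
                                   hbond_bundle.forcefield, radius=15.0)
        res = lattice_energy(hbond_bundle.structure, hbond_bundle.forcefield,
                             radius=15.0)
        assert prof.e_final == pytest.approx(res.e_cr, abs=1e-10)

    def test_molecule_counts_match_enumeration(self, random_bundles):
        s = random_bundles[2].structure
        prof = convergence_profile(s, random_bundles[2].forcefield,
                                   radius=15.0, shell_edges=(0, 9, 15))
        c0 = s.molecules[0].centroid
        frac0 = s.molecules[0].frac_coords.mean(axis=0)
        counts = [0, 0]
        for t in np.ndindex(9, 9, 9):
            t = np.array(t) - 4
            if not np.any(t):
                continue
            d = np.linalg.norm(s.cell.to_cartesian(frac0 + t) - c0)
            if d <= 9.0:
                counts[0] += 1
            elif d <= 15.0:
                counts[1] += 1
        assert prof.shell_molecule_counts.tolist() == counts


class TestSynthons:
    def test_chain_single_translation_synthon(self, chain_bundle):
        synthons = identify_synthons(chain_bundle.structure,
                                     chain_bundle.forcefield, radius=6.0)
        assert len(synthons) == 1
        s = synthons[0]
        assert s.label == "A" and s.multiplicity == 2
        assert s.interaction_type == "vdW"
        assert s.symmetry_class == "translation"

    def test_hbonded_fixture_ranks_hbond_first(self, hbond_bundle):
        synthons = identify_synthons(hbond_bundle.structure,
                                     hbond_bundle.forcefield, radius=12.0)
        a = synthons[0]
        assert a.label == "A"
        assert a.interaction_type == "H-Bond"
        assert a.symmetry_class == "screw"
        assert abs(a.breakdown.e_total) >= abs(synthons[-1].breakdown.e_total)

    def test_multiplicity_weighted_sum_is_twice_ecr(self, random_bundles,
                                                    hbond_bundle):
        for bundle, radius in [(b, 15.0) for b in random_bundles] + \
                [(hbond_bundle, 12.0)]:
            res = lattice_energy(bundle.structure, bundle.forcefield,
                                 radius=radius)
            synthons = identify_synthons(bundle.structure, bundle.forcefield,
                                         radius=radius)
            total = sum(s.multiplicity * s.breakdown.e_total for s in synthons)
            assert total == pytest.approx(2.0 * res.e_cr, abs=1e-8)

    def test_members_cover_pair_list_exactly_once(self, hbond_bundle):
        records = pair_records(hbond_bundle.structure,
                               hbond_bundle.forcefield, 12.0)
        synthons = identify_synthons(hbond_bundle.structure,
                                     hbond_bundle.forcefield, radius=12.0,
                                     records=records)
        members = [m for s in synthons for m in s.members]
        assert len(members) == len(records)
        assert {id(m) for m in members} == {id(r) for r in records}


class TestFragmentPartition:
    def test_single_fragment_carries_everything(self, hbond_bundle):
        s = hbond_bundle.structure
        fmap = {a.label: "all" for a in s.molecules[0].atoms}
        part = fragment_partition(s, fmap, hbond_bundle.forcefield, radius=10.0)
        assert part.percentages["all"] == pytest.approx(100.0, abs=1e-9)

    def test_fragments_conserve_lattice_energy(self, hbond_bundle):
        s = hbond_bundle.structure
        fmap = {"O1": "hydroxyl", "H1": "hydroxyl", "C1": "backbone",
                "C2": "carbonyl", "O2": "carbonyl"}
        part = fragment_partition(s, fmap, hbond_bundle.forcefield, radius=10.0)
        res = lattice_energy(s, hbond_bundle.forcefield, radius=10.0)
        assert sum(part.energies.values()) == pytest.approx(res.e_cr, abs=1e-6)
        assert sum(part.percentages.values()) == pytest.approx(100.0, abs=1e-6)

    def test_matches_per_atom_oracle(self, random_bundles):
        """Independent per-atom accumulation over explicit neighbour loops."""
        bundle = random_bundles[0]
        s = bundle.structure
        labels = [a.label for a in s.molecules[0].atoms]
        fmap = {lab: ("left" if i < 2 else "right")
                for i, lab in enumerate(labels)}
        part = fragment_partition(s, fmap, bundle.forcefield, radius=12.0)
        from synthonic.energy_model import atom_pair_terms
        acc = {"left": 0.0, "right": 0.0}
        for nb in expand_cluster(s, 12.0):
            for i, j, kind, e in atom_pair_terms(s.molecules[0], nb,
                                                 bundle.forcefield):
                acc[fmap[labels[i]]] += e / 4.0
                acc[fmap[labels[j]]] += e / 4.0
        for key in acc:
            assert part.energies[key] == pytest.approx(acc[key], abs=1e-10)

    def test_unmapped_atom_reported(self, hbond_bundle):
        with pytest.raises(KeyError, match="O2"):
            fragment_partition(hbond_bundle.structure, {
                "O1": "a", "H1": "a", "C1": "a", "C2": "a"},
                hbond_bundle.forcefield, radius=8.0)


class TestHBondInventory:
    def test_collinear_chain_geometry(self):
        # O-H along +a; acceptor is the O image one cell over: a = 2.97
        s = simple_p1((2.97, 14, 14), [("O", "O1", (0, 0, 0), -0.4),
                                       ("H", "H1", (0.97, 0, 0), 0.4)],
                      bonds=[(0, 1)])
        inv = hbond_inventory(s, radius=5.0)
        assert len(inv) == 1
        hb = inv[0]
        assert hb.r_ha == pytest.approx(2.0, abs=1e-9)
        assert hb.r_da == pytest.approx(2.97, abs=1e-9)
        assert hb.theta == pytest.approx(180.0, abs=1e-6)
        assert hb.multiplicity == 2
        assert hb.q_diff == pytest.approx(0.8)
        assert hb.r_da > hb.r_ha

    def test_low_angle_contact_excluded(self):
        # perpendicular-ish translation image gives theta < 90: not an H-bond
        s = simple_p1((12, 2.0, 12), [("O", "O1", (0, 0, 0), -0.4),
                                      ("H", "H1", (0.97, 0, 0), 0.4)],
                      bonds=[(0, 1)])
        assert hbond_inventory(s, radius=4.0) == []

    def test_screw_fixture_unique_bond_multiplicity(self, hbond_bundle):
        inv = hbond_inventory(hbond_bundle.structure, hbond_bundle.forcefield,
                              radius=10.0)
        assert len(inv) == hbond_bundle.expected["unique_hbonds"]
        hb = inv[0]
        assert hb.multiplicity == hbond_bundle.expected["hbond_multiplicity"]
        assert hb.r_ha == pytest.approx(hbond_bundle.expected["r_ha"], abs=1e-6)
        assert hb.theta == pytest.approx(hbond_bundle.expected["theta"],
                                         abs=1e-4)
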