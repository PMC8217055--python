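"""Deterministic toy crystal fixtures and brute-force oracles.

Every pipeline stage is testable on fully specified synthetic structures:
small rigid organic-like molecules placed in P1, P2₁ or P2₁2₁2₁ cells with
known nearest-neighbour topology, hydrogen-bond donor/acceptor pairs and
mixed partial charges, plus "cell-only" fixtures carrying the published
ritonavir unit-cell constants.  Fixtures are deterministic given their
seed, and the :func:`supercell_oracle` recomputes lattice energies by a
direct triple-loop supercell enumeration with no neighbour lists.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

from .crystal_io import (Atom, CrystalStructure, Molecule, SymmetryOp,
                         UnitCell, write_cif)
from .energy_model import (ForceField, VdwParams, coulomb_energy,
                           find_hbond_triplets, hbond_energy, vdw_energy)

__all__ = [
    "FixtureBundle", "FormCell", "make_chain_fixture", "make_random_fixture",
    "make_hbonded_fixture", "table2_cells", "supercell_oracle",
    "fixture_manifest",
]

_P1_OPS = ["x,y,z"]
_P21_OPS = ["x,y,z", "-x,y+1/2,-z"]
_P212121_OPS = ["x,y,z", "-x+1/2,-y,z+1/2", "x+1/2,-y+1/2,-z",
                "-x,y+1/2,-z+1/2"]


@dataclass
class FixtureBundle:
    """A generated structure together with the force field that defines it."""

    structure: CrystalStructure
    forcefield: ForceField
    label: str
    seed: int | None = None
    expected: dict = field(default_factory=dict)

    def write(self, cif_path, manifest_path=None) -> None:
        write_cif(self.structure, cif_path, name=self.label,
                  include_charges=True)
        if manifest_path is not None:
            with open(manifest_path, "w") as fh:
                json.dump(fixture_manifest(self), fh, indent=2)


@dataclass(frozen=True)
class FormCell:
    """Cell-only fixture: unit-cell constants with space group and Z."""

    cell: UnitCell
    space_group: str
    z: int
    label: str


def _ops(triplets):
    return [SymmetryOp.from_xyz(t) for t in triplets]


# --------------------------------------------------------------------------
# chain fixture: a single dominant translation synthon
# --------------------------------------------------------------------------

def make_chain_fixture(spacing: float = 5.215, pair_energy: float = -10.0,
                       lateral: tuple = (12.0, 12.8)) -> FixtureBundle:
    """P1 crystal whose dominant interaction is a ±b translation pair.

    One-atom molecules sit on a lattice with repeat ``spacing`` along b and
    looser lateral repeats; the LJ parameters are chosen so the
    nearest-neighbour pair energy is exactly ``pair_energy`` (the well
    depth) at the chain repeat.  Within a summation radius that captures
    only the ±b neighbours, E_cr = pair_energy by construction.
    """
    if spacing <= 2.0:
        raise ValueError(f"molecules overlap at spacing {spacing:.2f} Å")
    if pair_energy >= 0:
        raise ValueError("pair energy must be attractive (negative)")
    cell = UnitCell(lateral[0], spacing, lateral[1])
    atom = Atom(element="C", label="C1", frac=np.array([0.25, 0.0, 0.25]),
                charge=0.0)
    mol = Molecule(atoms=[atom], bonds=[], cell=cell)
    structure = CrystalStructure(cell=cell, symmetry_ops=_ops(_P1_OPS),
                                 molecules=[mol], space_group="P1")
    ff = ForceField(vdw=VdwParams(table={"C": (abs(pair_energy), spacing)}))
    return FixtureBundle(structure=structure, forcefield=ff, label="chain",
                         expected={"e_cr_at_radius_6": pair_energy,
                                   "chain_axis": "b",
                                   "synthon_multiplicity": 2})


# --------------------------------------------------------------------------
# random P1 fixture: mixed-charge oracle workloads
# --------------------------------------------------------------------------

def make_random_fixture(seed: int, n_atoms: int = 4) -> FixtureBundle:
    """Seeded P1 fixture with a random small molecule and mixed charges.

    A chain molecule of C/N/O atoms with ~1.45 Å bonds is placed in a
    random 8-9.5 Å orthorhombic cell; partial charges are drawn uniformly
    and recentred to zero net charge.  Placement is redrawn until all
    intermolecular image contacts exceed 2.6 Å.
    """
    rng = np.random.default_rng(seed)
    elements = ["C", "N", "O"]
    for attempt in range(60):
        cell = UnitCell(*(8.0 + 1.5 * rng.random(3)))
        pos = [np.zeros(3)]
        for _ in range(n_atoms - 1):
            step = rng.normal(size=3)
            step = 1.45 * step / np.linalg.norm(step)
            pos.append(pos[-1] + step)
        pos = np.array(pos)
        pos -= pos.mean(axis=0)
        # reject self-clashes in the random walk
        d = np.linalg.norm(pos[:, None] - pos[None, :], axis=-1)
        d[np.diag_indices(n_atoms)] = np.inf
        if d.min() < 1.2:
            continue
        centre = cell.to_cartesian([0.5, 0.5, 0.5])
        frac = cell.to_fractional(pos + centre)
        charges = rng.uniform(-0.3, 0.3, n_atoms)
        charges -= charges.mean()
        atoms = [Atom(element=elements[i % 3], label=f"X{i + 1}",
                      frac=frac[i], charge=charges[i])
                 for i in range(n_atoms)]
        bonds = [(i, i + 1) for i in range(n_atoms - 1)]
        mol = Molecule(atoms=atoms, bonds=bonds, cell=cell)
        structure = CrystalStructure(cell=cell, symmetry_ops=_ops(_P1_OPS),
                                     molecules=[mol], space_group="P1")
        # closest intermolecular image contact
        delta = frac[:, None, :] - frac[None, :, :]
        ok = True
        for shift in np.ndindex(3, 3, 3):
            t = np.array(shift) - 1
            if not np.any(t):
                continue
            dd = np.linalg.norm(cell.to_cartesian(delta + t), axis=-1)
            if dd.min() < 2.6:
                ok = False
                break
        if ok:
            return FixtureBundle(structure=structure, forcefield=ForceField(),
                                 label=f"random-{seed}", seed=seed)
    raise RuntimeError("could not place a clash-free random fixture")


# --------------------------------------------------------------------------
# hydrogen-bonded P2₁2₁2₁ fixture
# --------------------------------------------------------------------------

def make_hbonded_fixture(seed: int = 0) -> FixtureBundle:
    """P2₁2₁2₁ crystal with exactly one symmetry-unique O-H···O=C bond.

    The molecule carries one hydroxyl donor (O1-H1) and one carbonyl-like
    acceptor (C2=O2).  The geometry is built so the donor proton points at
    the acceptor of the 2₁-screw image along a, with r(H···A) drawn in
    [1.9, 2.4] Å and θ(D-H···A) in [150°, 180°]; the a repeat is solved so
    the intramolecular O1→O2 span closes with ordinary covalent bonds.
    """
    rng = np.random.default_rng(seed)
    r_ha = float(rng.uniform(1.9, 2.4))
    theta = float(rng.uniform(150.0, 179.0))
    b = 12.5 + float(rng.uniform(-0.3, 0.3))
    c = 13.5 + float(rng.uniform(-0.3, 0.3))

    # acceptor O2 in the central molecule (Cartesian, orthorhombic frame)
    y_q = b / 4.0 + 0.5
    q = np.array([2.0, y_q, 0.30])
    u_ha = np.array([1.0, 0.15, -0.10])
    u_ha /= np.linalg.norm(u_ha)
    w = np.cross(u_ha, [0.0, 0.0, 1.0])
    w /= np.linalg.norm(w)
    th = math.radians(theta)
    d_hat = math.cos(th) * u_ha + math.sin(th) * w

    # screw image of q under (x+1/2, -y+1/2, -z): depends on a only in x
    l_span = 3.80                      # target O1···O2 intramolecular span
    v_rest = (np.array([0.0, b / 2.0 - 2.0 * y_q, -2.0 * q[2]])
              - r_ha * u_ha + 0.97 * d_hat)
    yz2 = v_rest[1] ** 2 + v_rest[2] ** 2
    a = 2.0 * (math.sqrt(l_span**2 - yz2) - v_rest[0])
    cell = UnitCell(a, b, c)

    a_img = np.array([q[0] + a / 2.0, b / 2.0 - q[1], -q[2]])
    h1 = a_img - r_ha * u_ha
    o1 = h1 + 0.97 * d_hat
    span = q - o1
    perp = np.cross(span, [0.0, 0.0, 1.0])
    perp /= np.linalg.norm(perp)
    c1 = o1 + span / 3.0 + 0.30 * perp
    c2 = o1 + 2.0 * span / 3.0 - 0.30 * perp
    if np.linalg.norm(h1 - c1) < 1.6:   # keep the proton off the carbon
        c1 = o1 + span / 3.0 - 0.30 * perp
        c2 = o1 + 2.0 * span / 3.0 + 0.30 * perp

    cart = {"O1": o1, "H1": h1, "C1": c1, "C2": c2, "O2": q}
    charges = {"O1": -0.38, "H1": 0.30, "C1": 0.05, "C2": 0.35, "O2": -0.32}
    atoms = [Atom(element=lab[0], label=lab, frac=cell.to_fractional(p),
                  charge=charges[lab]) for lab, p in cart.items()]
    bonds = [(0, 1), (0, 2), (2, 3), (3, 4)]   # O1-H1, O1-C1, C1-C2, C2-O2
    mol = Molecule(atoms=atoms, bonds=bonds, cell=cell)
    structure = CrystalStructure(cell=cell, symmetry_ops=_ops(_P212121_OPS),
                                 molecules=[mol], space_group="P212121")
    structure.validate()
    return FixtureBundle(structure=structure, forcefield=ForceField(),
                         label=f"hbonded-{seed}", seed=seed,
                         expected={"r_ha": r_ha, "theta": theta,
                                   "unique_hbonds": 1,
                                   "hbond_multiplicity": 2})


# --------------------------------------------------------------------------
# cell-only reference fixtures
# --------------------------------------------------------------------------

def table2_cells() -> tuple:
    """The two ritonavir unit cells (cells only, no atoms).

    Form I: monoclinic P2₁, Z = 2; form II: orthorhombic P2₁2₁2₁, Z = 4.
    Used for closed-form d-spacing and surface-energy arithmetic.
    """
    form_i = FormCell(cell=UnitCell(13.344, 5.2150, 26.693,
                                    90.0, 103.456, 90.0),
                      space_group="P21", z=2, label="form I")
    form_ii = FormCell(cell=UnitCell(9.831, 18.485, 20.261, 90.0, 90.0, 90.0),
                       space_group="P212121", z=4, label="form II")
    return form_i, form_ii


# --------------------------------------------------------------------------
# brute-force supercell oracle
# --------------------------------------------------------------------------

def supercell_oracle(structure: CrystalStructure,
                     ff: ForceField | None = None, n: int = 5,
                     radius: float = 30.0, central_index: int = 0) -> float:
    """½ × direct double-loop lattice sum over an n×n×n supercell (kcal/mol).

    Enumerates every symmetry image in the block without neighbour lists,
    recomputes each pair energy with explicit per-atom loops over the
    scalar potentials, and keeps pairs with centroid separation within
    ``radius``.  Independent of the cluster-expansion code path.
    """
    if n < 3 or n % 2 == 0:
        raise ValueError("n must be odd and >= 3")
    ff = ff or ForceField()
    cell = structure.cell
    half = n // 2
    central = structure.molecules[central_index]
    c_cart = central.cart_coords
    c_centroid = c_cart.mean(axis=0)
    c_q = central.charges
    total = 0.0
    for mi, mol in enumerate(structure.molecules):
        for op in structure.symmetry_ops:
            for ta in range(-half, half + 1):
                for tb in range(-half, half + 1):
                    for tc in range(-half, half + 1):
                        t = np.array([ta, tb, tc], dtype=float)
                        frac = (mol.frac_coords @ op.rotation.T
                                + op.translation + t)
                        cart = cell.to_cartesian(frac)
                        centroid = cart.mean(axis=0)
                        d = np.linalg.norm(centroid - c_centroid)
                        if d < 1e-6 or d > radius:
                            continue
                        other = Molecule(
                            atoms=[Atom(element=at.element, label=at.label,
                                        frac=f, charge=at.charge)
                                   for at, f in zip(mol.atoms, frac)],
                            bonds=list(mol.bonds), cell=cell)
                        total += _direct_pair_energy(central, other, ff)
    return 0.5 * total


def _direct_pair_energy(mol_a, mol_b, ff: ForceField) -> float:
    """Plain double loop over atoms; H-bond replacement applied explicitly."""
    ra, rb = mol_a.cart_coords, mol_b.cart_coords
    qa, qb = mol_a.charges, mol_b.charges
    suppressed = set()
    e = 0.0
    for side, d_idx, h_idx, a_idx, r_ha, r_da, theta in \
            find_hbond_triplets(mol_a, mol_b, ff.hbond):
        if side == 0:
            suppressed.update({(h_idx, a_idx), (d_idx, a_idx)})
        else:
            suppressed.update({(a_idx, h_idx), (a_idx, d_idx)})
        e += hbond_energy(r_da, theta, ff.hbond)
    for i in range(len(mol_a.atoms)):
        for j in range(len(mol_b.atoms)):
            r = float(np.linalg.norm(ra[i] - rb[j]))
            if (i, j) not in suppressed:
                d0, r0 = ff.vdw.combine(mol_a.atoms[i].element,
                                        mol_b.atoms[j].element)
                e += vdw_energy(r, d0, r0)
            if qa[i] and qb[j]:
                e += coulomb_energy(r, qa[i], qb[j], ff.coulomb_constant)
    return e


def fixture_manifest(bundle: FixtureBundle) -> dict:
    s = bundle.structure
    return {
        "label": bundle.label,
        "seed": bundle.seed,
        "space_group": s.space_group,
        "z": s.z,
        "z_prime": s.z_prime,
        "cell": [s.cell.a, s.cell.b, s.cell.c,
                 s.cell.alpha, s.cell.beta, s.cell.gamma],
        "n_atoms": sum(len(m.atoms) for m in s.molecules),
        "expected": bundle.expected,
    }
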