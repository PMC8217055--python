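"""Atom–atom intermolecular energy model.

Dreiding-style force field for rigid-molecule lattice sums:

* van der Waals: Lennard-Jones 12-6, ``D0[(R0/r)^12 - 2(R0/r)^6]`` with
  geometric-mean well depths and arithmetic-mean equilibrium distances;
* hydrogen bond: 12-10 term ``D_hb[5(R_hb/r_DA)^12 - 6(R_hb/r_DA)^10] cos^4(θ)``
  applied to detected D-H···A triplets (the LJ terms between the three atoms
  involved are suppressed, per the Dreiding convention);
* electrostatics: vacuum Coulomb with the 332.0637 kcal·Å/(mol·e²) constant,
  summed directly (no Ewald — convergence is handled by the summation radius).

Partial charges come either from an external file or from the
Gasteiger–Marsili partial-equalization (PEOE) scheme implemented here.
All energies are kcal/mol, distances Å, charges electron units.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .crystal_io import Molecule

__all__ = [
    "VdwParams", "HBondParams", "ForceField", "ChargeSet", "EnergyBreakdown",
    "OverlapError", "vdw_energy", "hbond_energy", "coulomb_energy",
    "gasteiger_charges", "pair_interaction", "atom_pair_terms",
    "find_hbond_triplets", "DREIDING_VDW",
]

COULOMB_CONSTANT = 332.0637  # kcal·Å/(mol·e²)

# Dreiding-flavour per-element LJ parameters: element -> (D0 kcal/mol, R0 Å)
DREIDING_VDW = {
    "H": (0.0152, 3.195),
    "B": (0.0950, 4.020),
    "C": (0.0951, 3.8983),
    "N": (0.0774, 3.6621),
    "O": (0.0957, 3.4046),
    "F": (0.0725, 3.4720),
    "P": (0.3200, 4.1500),
    "S": (0.3440, 4.0300),
    "Cl": (0.2833, 3.9503),
    "Br": (0.3700, 3.9500),
    "I": (0.5100, 4.1500),
}

HBOND_ELEMENTS = frozenset({"O", "N", "S"})


class OverlapError(ValueError):
    """Atoms unphysically close — the rigid-molecule model does not apply."""


@dataclass
class VdwParams:
    """Per-element LJ 12-6 parameters with Lorentz-Berthelot-style combining."""

    table: dict = field(default_factory=lambda: dict(DREIDING_VDW))
    combining_rule: str = "geometric-D0/arithmetic-R0"

    def combine(self, element_i: str, element_j: str) -> tuple:
        try:
            d0i, r0i = self.table[element_i]
            d0j, r0j = self.table[element_j]
        except KeyError as exc:
            raise KeyError(f"no vdW parameters for element {exc}") from exc
        return math.sqrt(d0i * d0j), 0.5 * (r0i + r0j)


@dataclass
class HBondParams:
    """12-10 hydrogen-bond well plus detection thresholds."""

    d_hb: float = 9.5          # kcal/mol
    r_hb: float = 2.75         # Å, equilibrium donor···acceptor distance
    angular_exponent: int = 4
    r_ha_cutoff: float = 3.0   # Å, H···A activation distance
    theta_min: float = 90.0    # degrees, D-H···A activation angle


@dataclass
class ForceField:
    vdw: VdwParams = field(default_factory=VdwParams)
    hbond: HBondParams = field(default_factory=HBondParams)
    coulomb_constant: float = COULOMB_CONSTANT


@dataclass
class ChargeSet:
    """Per-atom partial charges (e) with provenance."""

    charges: np.ndarray
    provenance: str = "gasteiger"

    def __post_init__(self):
        self.charges = np.asarray(self.charges, dtype=float)

    def total(self) -> float:
        return float(self.charges.sum())


@dataclass
class EnergyBreakdown:
    e_vdw: float = 0.0
    e_hbond: float = 0.0
    e_coulomb: float = 0.0

    @property
    def e_total(self) -> float:
        return self.e_vdw + self.e_hbond + self.e_coulomb

    def __add__(self, other: "EnergyBreakdown") -> "EnergyBreakdown":
        return EnergyBreakdown(self.e_vdw + other.e_vdw,
                               self.e_hbond + other.e_hbond,
                               self.e_coulomb + other.e_coulomb)

    def __mul__(self, factor: float) -> "EnergyBreakdown":
        return EnergyBreakdown(self.e_vdw * factor, self.e_hbond * factor,
                               self.e_coulomb * factor)

    __rmul__ = __mul__

    def as_dict(self) -> dict:
        return {"vdw": self.e_vdw, "hbond": self.e_hbond,
                "coulomb": self.e_coulomb, "total": self.e_total}


# --------------------------------------------------------------------------
# pair potentials
# --------------------------------------------------------------------------

def vdw_energy(r: float, d0: float, r0: float) -> float:
    """LJ 12-6 well: ``-d0`` at ``r = r0``, → 0⁻ at long range."""
    if r < 0.1:
        raise OverlapError(f"interatomic distance {r:.3f} Å below 0.1 Å")
    x6 = (r0 / r) ** 6
    return d0 * (x6 * x6 - 2.0 * x6)


def hbond_energy(r_da: float, theta_dha: float,
                 params: HBondParams | None = None) -> float:
    """12-10 hydrogen-bond term with a cos⁴ angular modulation.

    ``-d_hb`` exactly at ``r_DA = r_hb`` and θ = 180°; zero for θ ≤ 90°.
    """
    params = params or HBondParams()
    if r_da <= 0:
        raise ValueError("donor-acceptor distance must be positive")
    if theta_dha <= 90.0:
        return 0.0
    x = params.r_hb / r_da
    radial = params.d_hb * (5.0 * x**12 - 6.0 * x**10)
    return radial * math.cos(math.radians(theta_dha)) ** params.angular_exponent


def coulomb_energy(r: float, q1: float, q2: float,
                   constant: float = COULOMB_CONSTANT) -> float:
    """Vacuum point-charge interaction in kcal/mol."""
    if r <= 0:
        raise ValueError("distance must be positive")
    return constant * q1 * q2 / r


# --------------------------------------------------------------------------
# Gasteiger-Marsili PEOE charges
# --------------------------------------------------------------------------

# (a, b, c) orbital-electronegativity polynomials, chi(q) = a + b q + c q².
_PEOE_PARAMS = {
    ("H", "any"): (7.17, 6.24, -0.56),
    ("C", "sp3"): (7.98, 9.18, 1.88),
    ("C", "sp2"): (8.79, 9.32, 1.51),
    ("C", "sp"): (10.39, 9.45, 0.73),
    ("N", "sp3"): (11.54, 10.82, 1.36),
    ("N", "sp2"): (12.87, 11.15, 0.85),
    ("N", "sp"): (15.68, 11.70, -0.27),
    ("O", "sp3"): (14.18, 12.92, 1.39),
    ("O", "sp2"): (17.07, 13.79, 0.47),
    ("S", "sp3"): (10.14, 9.13, 1.38),
    ("F", "sp3"): (14.66, 13.85, 2.31),
    ("Cl", "sp3"): (11.00, 9.69, 1.35),
    ("Br", "sp3"): (10.08, 8.47, 1.16),
    ("I", "sp3"): (9.90, 7.96, 0.96),
}


def _hybridisation(element: str, degree: int) -> str:
    if element == "H":
        return "any"
    if element == "C":
        return {4: "sp3", 3: "sp2"}.get(degree, "sp")
    if element == "N":
        return "sp3" if degree >= 3 else ("sp2" if degree == 2 else "sp")
    if element == "O":
        return "sp3" if degree >= 2 else "sp2"
    return "sp3"


def gasteiger_charges(molecule: Molecule, iterations: int = 24,
                      tolerance: float = 1e-5) -> ChargeSet:
    """Gasteiger-Marsili partial-equalization charges.

    Iterative charge transfer across each bond, damped by ``(1/2)^k`` at
    iteration ``k``; converged when the largest per-iteration transfer drops
    below ``tolerance`` (e).  The divisor is the cation electronegativity of
    the electron-donating (less electronegative) atom, with the special H⁺
    value 20.02.
    """
    n = len(molecule.atoms)
    degrees = [len(molecule.neighbour_indices(i)) for i in range(n)]
    params = []
    for atom, deg in zip(molecule.atoms, degrees):
        key = (atom.element, _hybridisation(atom.element, deg))
        if key not in _PEOE_PARAMS:
            raise KeyError(f"no PEOE electronegativity parameters for "
                           f"element {atom.element!r} ({key[1]})")
        params.append(_PEOE_PARAMS[key])
    a = np.array([p[0] for p in params])
    b = np.array([p[1] for p in params])
    c = np.array([p[2] for p in params])
    chi_plus = np.where(np.array([at.element for at in molecule.atoms]) == "H",
                        20.02, a + b + c)

    q = np.zeros(n)
    for k in range(1, iterations + 1):
        chi = a + b * q + c * q * q
        damping = 0.5 ** k
        dq = np.zeros(n)
        max_transfer = 0.0
        for i, j in molecule.bonds:
            if chi[i] == chi[j]:
                continue
            lo, hi = (i, j) if chi[i] < chi[j] else (j, i)
            transfer = (chi[hi] - chi[lo]) / chi_plus[lo] * damping
            dq[lo] += transfer
            dq[hi] -= transfer
            max_transfer = max(max_transfer, abs(transfer))
        q += dq
        if max_transfer < tolerance:
            break
    return ChargeSet(charges=q, provenance="gasteiger")


# --------------------------------------------------------------------------
# intermolecular pair interaction
# --------------------------------------------------------------------------

def find_hbond_triplets(mol_a: Molecule, mol_b: Molecule,
                        params: HBondParams | None = None) -> list:
    """Active D-H···A triplets between two molecules.

    Donors are O/N/S with a covalently bound H; acceptors are O/N/S.  A
    triplet is active when r(H···A) < cutoff and θ(D-H···A) > θ_min.
    Returned tuples are ``(donor_mol, d_idx, h_idx, a_idx, r_ha, r_da, theta)``
    where ``donor_mol`` is 0 if the donor sits in ``mol_a`` else 1.
    """
    params = params or HBondParams()
    triplets = []
    pair = [(0, mol_a, mol_b), (1, mol_b, mol_a)]
    for side, donor_mol, acceptor_mol in pair:
        dcoords, acoords = donor_mol.cart_coords, acceptor_mol.cart_coords
        for h_idx, h_atom in enumerate(donor_mol.atoms):
            if h_atom.element != "H":
                continue
            for d_idx in donor_mol.neighbour_indices(h_idx):
                if donor_mol.atoms[d_idx].element not in HBOND_ELEMENTS:
                    continue
                for a_idx, a_atom in enumerate(acceptor_mol.atoms):
                    if a_atom.element not in HBOND_ELEMENTS:
                        continue
                    r_ha = float(np.linalg.norm(acoords[a_idx] - dcoords[h_idx]))
                    if r_ha >= params.r_ha_cutoff:
                        continue
                    v1 = dcoords[d_idx] - dcoords[h_idx]
                    v2 = acoords[a_idx] - dcoords[h_idx]
                    cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
                    theta = math.degrees(math.acos(np.clip(cosang, -1.0, 1.0)))
                    if theta <= params.theta_min:
                        continue
                    r_da = float(np.linalg.norm(acoords[a_idx] - dcoords[d_idx]))
                    triplets.append((side, d_idx, h_idx, a_idx, r_ha, r_da, theta))
    return triplets


def atom_pair_terms(mol_a: Molecule, mol_b: Molecule,
                    ff: ForceField | None = None) -> list:
    """Per-term energy decomposition of one intermolecular pair interaction.

    Yields ``(i, j, kind, energy)`` with ``i`` an atom index in ``mol_a``,
    ``j`` in ``mol_b`` and ``kind`` one of ``vdw | coulomb | hbond``.  For an
    active hydrogen-bond triplet the LJ terms of the (H, A) and (D, A) pairs
    are replaced by a single 12-10 hbond term attributed to the (H, A) pair
    (donor-side index is the H when the donor is in ``mol_a``, the A
    otherwise).  Coulomb terms are kept for all pairs.
    """
    ff = ff or ForceField()
    ra, rb = mol_a.cart_coords, mol_b.cart_coords
    qa, qb = mol_a.charges, mol_b.charges
    delta = ra[:, None, :] - rb[None, :, :]
    dist = np.linalg.norm(delta, axis=-1)
    if dist.min() < 0.5:
        i, j = np.unravel_index(np.argmin(dist), dist.shape)
        raise OverlapError(
            f"atoms {mol_a.atoms[i].label}/{mol_b.atoms[j].label} only "
            f"{dist.min():.3f} Å apart — molecules overlap")

    triplets = find_hbond_triplets(mol_a, mol_b, ff.hbond)
    suppressed = set()
    terms = []
    for side, d_idx, h_idx, a_idx, r_ha, r_da, theta in triplets:
        if side == 0:
            suppressed.add((h_idx, a_idx))
            suppressed.add((d_idx, a_idx))
            key = (h_idx, a_idx)
        else:
            suppressed.add((a_idx, h_idx))
            suppressed.add((a_idx, d_idx))
            key = (a_idx, h_idx)
        terms.append((key[0], key[1], "hbond",
                      hbond_energy(r_da, theta, ff.hbond)))

    for i in range(len(mol_a.atoms)):
        for j in range(len(mol_b.atoms)):
            r = dist[i, j]
            if (i, j) not in suppressed:
                d0, r0 = ff.vdw.combine(mol_a.atoms[i].element,
                                        mol_b.atoms[j].element)
                terms.append((i, j, "vdw", vdw_energy(r, d0, r0)))
            if qa[i] != 0.0 and qb[j] != 0.0:
                terms.append((i, j, "coulomb",
                              coulomb_energy(r, qa[i], qb[j],
                                             ff.coulomb_constant)))
    return terms


def pair_interaction(mol_a: Molecule, mol_b: Molecule,
                     ff: ForceField | None = None) -> EnergyBreakdown:
    """Total intermolecular interaction energy with component breakdown."""
    breakdown = EnergyBreakdown()
    for _, _, kind, energy in atom_pair_terms(mol_a, mol_b, ff):
        if kind == "vdw":
            breakdown.e_vdw += energy
        elif kind == "hbond":
            breakdown.e_hbond += energy
        else:
            breakdown.e_coulomb += energy
    return breakdown
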