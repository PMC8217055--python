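"""Lattice-energy summation, convergence profiling, synthon analysis.

The lattice energy E_cr of a molecular crystal is computed as a direct
atom-atom sum over all whole molecules whose centroid lies within a
summation radius of a central molecule, with the handshake ½ convention
(each pair interaction shared between two molecules):

    E_cr = ½ Σ_k E_pair(central, neighbour_k)

For Z' > 1 the value is the arithmetic mean over the Z' central molecules;
per-central values are retained.  Symmetry-equivalent pair interactions are
grouped into *synthons*, labelled A, B, C, … by descending interaction
strength, and the lattice energy can be partitioned onto user-defined
molecular fragments by splitting every atom-atom term half to each atom.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .crystal_io import CrystalStructure, Molecule, expand_cluster
from .energy_model import (EnergyBreakdown, ForceField, atom_pair_terms,
                           find_hbond_triplets, pair_interaction)

__all__ = [
    "PairRecord", "LatticeEnergyResult", "ConvergenceProfile", "Synthon",
    "FragmentPartition", "HBondGeometry", "pair_records", "lattice_energy",
    "convergence_profile", "identify_synthons", "fragment_partition",
    "hbond_inventory",
]

DEFAULT_RADIUS = 30.0
DEFAULT_SHELL_EDGES = (0.0, 9.0, 19.0, 22.0, 30.0)
CONVERGENCE_TOL = 0.01     # relative, over a 2 Å window
HBOND_TAG_THRESHOLD = 0.5  # kcal/mol of |E_hbond| to call a synthon "H-Bond"


@dataclass
class PairRecord:
    """One central-molecule/neighbour interaction."""

    neighbour: Molecule
    distance: float                 # centroid separation, Å
    breakdown: EnergyBreakdown
    central_index: int = 0

    @property
    def op_index(self) -> int:
        return self.neighbour.ident[1]

    @property
    def tvec(self) -> tuple:
        return self.neighbour.ident[2]


@dataclass
class LatticeEnergyResult:
    e_cr: float                     # kcal/mol, per molecule
    breakdown: EnergyBreakdown
    radius: float
    per_central: list = field(default_factory=list)   # (index, e_cr) per Z'
    converged: bool = True

    def as_dict(self) -> dict:
        return {"e_cr": self.e_cr, "radius": self.radius,
                "converged": self.converged, **{f"e_{k}": v for k, v in
                self.breakdown.as_dict().items() if k != "total"}}


@dataclass
class ConvergenceProfile:
    radii: np.ndarray               # Å grid
    cumulative: np.ndarray          # E(r), kcal/mol
    cumulative_coulomb: np.ndarray
    shell_edges: tuple
    shell_energies: np.ndarray      # kcal/mol per (lo, hi] bin
    shell_percent: np.ndarray       # % of E(r_max) per bin
    shell_molecule_counts: np.ndarray
    convergence_radius: float | None

    @property
    def e_final(self) -> float:
        return float(self.cumulative[-1])


@dataclass
class Synthon:
    label: str
    multiplicity: int
    breakdown: EnergyBreakdown
    distance: float
    symmetry_class: str             # translation | screw | other
    interaction_type: str           # "H-Bond" | "vdW"
    members: list = field(default_factory=list)   # PairRecords

    def percent_of_lattice(self, e_cr: float, handshake: bool = True) -> float:
        """Contribution as % of the lattice energy.

        With ``handshake=True`` the denominator is 2|E_cr| (so that all
        synthons together account for exactly 100%); with ``False`` it is
        |E_cr|, the convention some published tables appear to use.  Both are
        provided because the two conventions differ by a factor of two and
        printed tables are not always internally consistent.
        """
        denom = 2.0 * abs(e_cr) if handshake else abs(e_cr)
        return 100.0 * abs(self.multiplicity * self.breakdown.e_total) / denom


@dataclass
class FragmentPartition:
    energies: dict                  # fragment tag -> kcal/mol
    e_cr: float

    @property
    def percentages(self) -> dict:
        return {k: 100.0 * v / self.e_cr for k, v in self.energies.items()}


@dataclass
class HBondGeometry:
    donor_label: str
    hydrogen_label: str
    acceptor_label: str
    q_d: float
    q_a: float
    r_ha: float
    r_da: float
    theta: float
    multiplicity: int = 1

    @property
    def q_diff(self) -> float:
        """Donor-acceptor polarization difference, q_D − q_A."""
        return self.q_d - self.q_a


# --------------------------------------------------------------------------
# pair enumeration and lattice energy
# --------------------------------------------------------------------------

def pair_records(structure: CrystalStructure, ff: ForceField | None = None,
                 radius: float = DEFAULT_RADIUS,
                 central_index: int = 0) -> list:
    """All pair interactions of one central molecule within ``radius``."""
    ff = ff or ForceField()
    central = structure.molecules[central_index]
    c0 = central.centroid
    records = []
    for neighbour in expand_cluster(structure, radius, central_index):
        d = float(np.linalg.norm(neighbour.centroid - c0))
        records.append(PairRecord(neighbour=neighbour, distance=d,
                                  breakdown=pair_interaction(central, neighbour, ff),
                                  central_index=central_index))
    return records


def lattice_energy(structure: CrystalStructure, ff: ForceField | None = None,
                   radius: float = DEFAULT_RADIUS,
                   convergence_window: float = 2.0,
                   convergence_tol: float = CONVERGENCE_TOL) -> LatticeEnergyResult:
    """Direct-sum lattice energy with the handshake ½ convention.

    Warns (without failing) when the sum has not converged at ``radius``:
    |E(r) − E(r − window)| / |E(r)| above ``convergence_tol``.
    """
    if radius < 5.0:
        raise ValueError("summation radius below 5 Å is not meaningful")
    ff = ff or ForceField()
    per_central = []
    total = EnergyBreakdown()
    converged = True
    for ci in range(structure.z_prime):
        records = pair_records(structure, ff, radius, central_index=ci)
        breakdown = EnergyBreakdown()
        for rec in records:
            breakdown = breakdown + rec.breakdown
        breakdown = 0.5 * breakdown
        per_central.append((ci, breakdown.e_total))
        total = total + breakdown
        inner = 0.5 * sum(r.breakdown.e_total for r in records
                          if r.distance <= radius - convergence_window)
        if abs(breakdown.e_total) > 0 and \
                abs(breakdown.e_total - inner) > convergence_tol * abs(breakdown.e_total):
            converged = False
    total = total * (1.0 / structure.z_prime)
    if not converged:
        warnings.warn(f"lattice sum not converged at {radius:.1f} Å "
                      f"(relative change over the last {convergence_window:.0f} Å "
                      f"window exceeds {convergence_tol:.1%})")
    return LatticeEnergyResult(e_cr=total.e_total, breakdown=total,
                               radius=radius, per_central=per_central,
                               converged=converged)


def convergence_profile(structure: CrystalStructure,
                        ff: ForceField | None = None,
                        radius: float = DEFAULT_RADIUS, step: float = 1.0,
                        shell_edges: tuple = DEFAULT_SHELL_EDGES,
                        tolerance: float = CONVERGENCE_TOL) -> ConvergenceProfile:
    """Cumulative lattice energy vs summation radius plus shell decomposition.

    The convergence radius is the smallest grid radius r with
    |E(r) − E(r_max)| / |E(r_max)| < ``tolerance``.
    """
    ff = ff or ForceField()
    radii = np.arange(step, radius + step / 2, step)
    n_r = len(radii)
    cumulative = np.zeros(n_r)
    cumulative_q = np.zeros(n_r)
    edges = np.asarray(shell_edges, dtype=float)
    shell_e = np.zeros(len(edges) - 1)
    shell_n = np.zeros(len(edges) - 1)

    for ci in range(structure.z_prime):
        records = pair_records(structure, ff, radius, central_index=ci)
        dists = np.array([r.distance for r in records])
        totals = np.array([r.breakdown.e_total for r in records])
        coul = np.array([r.breakdown.e_coulomb for r in records])
        for k, r in enumerate(radii):
            mask = dists <= r
            cumulative[k] += 0.5 * totals[mask].sum()
            cumulative_q[k] += 0.5 * coul[mask].sum()
        for b in range(len(edges) - 1):
            mask = (dists > edges[b]) & (dists <= edges[b + 1])
            shell_e[b] += 0.5 * totals[mask].sum()
            shell_n[b] += int(mask.sum())

    zp = structure.z_prime
    cumulative /= zp
    cumulative_q /= zp
    shell_e /= zp
    shell_n /= zp
    e_final = cumulative[-1]
    shell_pct = (100.0 * shell_e / e_final if e_final != 0
                 else np.zeros_like(shell_e))
    conv_r = None
    if e_final != 0:
        ok = np.abs(cumulative - e_final) / abs(e_final) < tolerance
        idx = np.argmax(ok)
        if ok[idx]:
            conv_r = float(radii[idx])
    return ConvergenceProfile(radii=radii, cumulative=cumulative,
                              cumulative_coulomb=cumulative_q,
                              shell_edges=tuple(edges),
                              shell_energies=shell_e, shell_percent=shell_pct,
                              shell_molecule_counts=shell_n,
                              convergence_radius=conv_r)


# --------------------------------------------------------------------------
# synthons
# --------------------------------------------------------------------------

def identify_synthons(structure: CrystalStructure,
                      ff: ForceField | None = None,
                      radius: float = DEFAULT_RADIUS,
                      energy_tol: float = 0.01, distance_tol: float = 0.01,
                      central_index: int = 0,
                      hbond_threshold: float = HBOND_TAG_THRESHOLD,
                      records: list | None = None) -> list:
    """Group symmetry-equivalent pair interactions into labelled synthons.

    Two pair interactions belong to the same synthon when their total
    energies agree within ``energy_tol`` kcal/mol and their centroid
    distances within ``distance_tol`` Å.  Synthons are labelled A, B, C, …
    by descending |E_total| and tagged "H-Bond" when the hydrogen-bond
    component exceeds ``hbond_threshold``.  Each synthon's breakdown is the
    mean over its members, so Σ multiplicity × E_total over all synthons
    recovers 2 E_cr exactly.
    """
    if records is None:
        records = pair_records(structure, ff, radius, central_index)
    remaining = sorted(records,
                       key=lambda r: (-abs(r.breakdown.e_total), r.distance,
                                      r.op_index, r.tvec))
    groups = []
    for rec in remaining:
        for grp in groups:
            ref = grp[0]
            if (abs(rec.breakdown.e_total - ref.breakdown.e_total) <= energy_tol
                    and abs(rec.distance - ref.distance) <= distance_tol):
                grp.append(rec)
                break
        else:
            groups.append([rec])

    groups.sort(key=lambda g: (-abs(g[0].breakdown.e_total), g[0].distance))
    synthons = []
    for rank, grp in enumerate(groups):
        ref = grp[0]
        mean = EnergyBreakdown()
        for rec in grp:
            mean = mean + rec.breakdown
        mean = mean * (1.0 / len(grp))
        ops = structure.symmetry_ops
        classes = {ops[r.op_index].symmetry_class() if r.op_index < len(ops)
                   else "other" for r in grp}
        if "translation" in classes and len(classes) == 1:
            sym_class = "translation"
        elif "screw" in classes:
            sym_class = "screw"
        else:
            sym_class = "other"
        label = chr(ord("A") + rank) if rank < 26 else f"S{rank}"
        itype = ("H-Bond" if abs(mean.e_hbond) > hbond_threshold
                 else "vdW")
        synthons.append(Synthon(label=label, multiplicity=len(grp),
                                breakdown=mean, distance=ref.distance,
                                symmetry_class=sym_class,
                                interaction_type=itype, members=grp))
    return synthons


# --------------------------------------------------------------------------
# fragment partition
# --------------------------------------------------------------------------

def fragment_partition(structure: CrystalStructure, fragment_map: dict,
                       ff: ForceField | None = None,
                       radius: float = DEFAULT_RADIUS) -> FragmentPartition:
    """Partition E_cr onto molecular fragments.

    ``fragment_map`` maps atom labels to fragment tags (every atom must be
    mapped).  Every atom-atom energy term is split half to the fragment of
    each participating atom; the hydrogen-bond term is carried by the (H, A)
    pair.  Fragment energies sum exactly to E_cr.
    """
    ff = ff or ForceField()
    for mol in structure.molecules:
        unmapped = [a.label for a in mol.atoms if a.label not in fragment_map]
        if unmapped:
            raise KeyError(f"atoms without fragment assignment: {unmapped}")

    energies: dict = {}
    zp = structure.z_prime
    e_cr = 0.0
    for ci in range(zp):
        central = structure.molecules[ci]
        for neighbour in expand_cluster(structure, radius, ci):
            for i, j, kind, e in atom_pair_terms(central, neighbour, ff):
                fa = fragment_map[central.atoms[i].label]
                fb = fragment_map[neighbour.atoms[j].label]
                energies[fa] = energies.get(fa, 0.0) + e / (4.0 * zp)
                energies[fb] = energies.get(fb, 0.0) + e / (4.0 * zp)
                e_cr += e / (2.0 * zp)
    return FragmentPartition(energies=energies, e_cr=e_cr)


# --------------------------------------------------------------------------
# hydrogen-bond inventory
# --------------------------------------------------------------------------

def hbond_inventory(structure: CrystalStructure,
                    ff: ForceField | None = None,
                    radius: float = DEFAULT_RADIUS,
                    central_index: int = 0,
                    geometry_tol: float = 0.01) -> list:
    """Symmetry-unique D-H···A triplets around the central molecule.

    Both directions are inventoried (central as donor and as acceptor);
    triplets with identical site labels and geometry (within
    ``geometry_tol``) are merged with their multiplicity counted.
    """
    ff = ff or ForceField()
    central = structure.molecules[central_index]
    found = []
    for neighbour in expand_cluster(structure, radius, central_index):
        for side, d_idx, h_idx, a_idx, r_ha, r_da, theta in \
                find_hbond_triplets(central, neighbour, ff.hbond):
            donor_mol = central if side == 0 else neighbour
            acceptor_mol = neighbour if side == 0 else central
            d_atom = donor_mol.atoms[d_idx]
            h_atom = donor_mol.atoms[h_idx]
            a_atom = acceptor_mol.atoms[a_idx]
            # q_D is the donor *proton* charge (the polarized site), q_A the
            # acceptor heavy-atom charge
            found.append(HBondGeometry(
                donor_label=d_atom.label, hydrogen_label=h_atom.label,
                acceptor_label=a_atom.label,
                q_d=0.0 if h_atom.charge is None else h_atom.charge,
                q_a=0.0 if a_atom.charge is None else a_atom.charge,
                r_ha=r_ha, r_da=r_da, theta=theta))

    unique = []
    for hb in found:
        for u in unique:
            if (u.donor_label == hb.donor_label
                    and u.hydrogen_label == hb.hydrogen_label
                    and u.acceptor_label == hb.acceptor_label
                    and abs(u.r_ha - hb.r_ha) <= geometry_tol
                    and abs(u.r_da - hb.r_da) <= geometry_tol
                    and abs(u.theta - hb.theta) <= 1.0):
                u.multiplicity += 1
                break
        else:
            unique.append(hb)
    unique.sort(key=lambda h: (h.r_ha, h.donor_label, h.acceptor_label))
    return unique
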