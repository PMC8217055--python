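"""Face-specific surface properties of a molecular crystal.

* anisotropy factor ξ_hkl = E_sl/E_cr — the fraction of a molecule's
  lattice coordination satisfied within the growth slice ("synthon
  saturation"), reported as a percentage;
* surface energy γ_hkl = Z |E_att| d_hkl / (2 V_cell N_A), converted to
  mJ/m², with a component-wise breakdown (vdW / H-bond / electrostatic)
  obtained by applying the formula to the attachment-energy components;
* particle surface energy: the facet-area-weighted mean of γ_hkl over the
  predicted habit;
* rugosity: RMS height variation of the asymmetric-unit atoms about the
  mean height along the face normal — a surface smoothness metric.

Attachment energies are negative for cohesive crystals; γ uses their
magnitude so surface energies come out positive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .crystal_io import CrystalStructure
from .energy_model import EnergyBreakdown
from .morphology import plane_normal

__all__ = [
    "AVOGADRO", "KCAL_TO_J", "SurfaceReport", "anisotropy_factor",
    "surface_energy", "surface_energy_breakdown", "particle_surface_energy",
    "rugosity", "build_surface_report",
]

AVOGADRO = 6.02214076e23
KCAL_TO_J = 4184.0


def anisotropy_factor(e_att: float, e_cr: float) -> float:
    """Synthon saturation ξ = E_sl/E_cr = (E_cr − E_att)/E_cr, in percent."""
    if e_cr >= 0:
        raise ValueError("E_cr must be negative (cohesive crystal)")
    if abs(e_att) > abs(e_cr):
        warnings.warn(f"|E_att| = {abs(e_att):.2f} exceeds |E_cr| = "
                      f"{abs(e_cr):.2f}: non-physical slice partition")
    return 100.0 * (e_cr - e_att) / e_cr


def surface_energy(z: int, e_att: float, d_hkl: float, v_cell: float) -> float:
    """γ_hkl in mJ/m² from Z, attachment energy (kcal/mol), d (Å), V (Å³)."""
    e_joule = abs(e_att) * KCAL_TO_J / AVOGADRO        # J per molecule
    gamma = z * e_joule * (d_hkl * 1e-10) / (2.0 * v_cell * 1e-30)
    return gamma * 1e3                                  # J/m² -> mJ/m²


def surface_energy_breakdown(z: int, e_att: EnergyBreakdown, d_hkl: float,
                             v_cell: float) -> dict:
    """Component-wise γ; signs of the components are kept (a repulsive
    component reduces the total)."""
    sign = -1.0 if e_att.e_total < 0 else 1.0
    comps = {}
    for key, value in (("vdw", e_att.e_vdw), ("hbond", e_att.e_hbond),
                       ("electrostatic", e_att.e_coulomb)):
        comps[key] = sign * value * KCAL_TO_J / AVOGADRO * z \
            * (d_hkl * 1e-10) / (2.0 * v_cell * 1e-30) * 1e3
    comps["total"] = surface_energy(z, e_att.e_total, d_hkl, v_cell)
    return comps


def particle_surface_energy(faces: list) -> float:
    """Area-weighted whole-crystal surface energy Σ γ_hkl · SA_hkl (mJ/m²).

    ``faces`` carry fractional areas already aggregated over each form's
    multiplicity; the printed areas are used as given, without
    renormalisation.
    """
    total_area = 0.0
    gamma = 0.0
    for f in faces:
        sa = f.area_fraction if f.area_fraction is not None else 0.0
        if sa < 0:
            raise ValueError(f"negative fractional area on {f.label}")
        g = f.gamma.get("total") if f.gamma else None
        if g is None:
            raise ValueError(f"face {f.label} has no surface energy")
        gamma += g * sa
        total_area += sa
    if not 0.98 <= total_area <= 1.02:
        warnings.warn(f"fractional areas sum to {total_area:.3f}, "
                      "outside [0.98, 1.02]")
    return gamma


def rugosity(structure: CrystalStructure, hkl, central_index: int = 0) -> float:
    """RMS variation of atomic heights about their mean along the (hkl) normal."""
    mol = structure.molecules[central_index]
    if not mol.atoms:
        raise ValueError("empty asymmetric unit")
    n = plane_normal(structure.cell, hkl)
    heights = mol.cart_coords @ n
    return float(np.sqrt(np.mean((heights - heights.mean()) ** 2)))


@dataclass
class SurfaceReport:
    faces: list
    e_cr: float
    z: int
    v_cell: float
    gamma_particle: float = 0.0
    rugosities: dict = field(default_factory=dict)

    def rows(self) -> list:
        out = []
        for f in self.faces:
            out.append({
                "face": f.label, "d_hkl": f.d, "multiplicity": f.multiplicity,
                "area_pct": None if f.area_fraction is None
                else 100.0 * f.area_fraction,
                "e_att": f.e_att.e_total if f.e_att else None,
                "xi_pct": anisotropy_factor(f.e_att.e_total, self.e_cr)
                if f.e_att else None,
                **{f"gamma_{k}": v for k, v in f.gamma.items()},
                "rugosity": self.rugosities.get(f.hkl),
            })
        return out


def build_surface_report(structure: CrystalStructure, faces: list,
                         e_cr: float) -> SurfaceReport:
    """Fill γ components, ξ and rugosity for every face and aggregate."""
    z = structure.z
    v = structure.cell.volume
    for f in faces:
        f.gamma = surface_energy_breakdown(z, f.e_att, f.d, v)
    report = SurfaceReport(faces=faces, e_cr=e_cr, z=z, v_cell=v)
    report.rugosities = {f.hkl: rugosity(structure, f.hkl) for f in faces}
    if all(f.area_fraction is not None for f in faces):
        report.gamma_particle = particle_surface_energy(faces)
    return report
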