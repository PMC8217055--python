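"""Conformer torsion fingerprints and deformation-energy bookkeeping.

Conformational polymorphs pack different conformers of the same molecule;
the packing advantage of one polymorph is partially offset by the
single-point energy penalty of its deformed conformer.  Single-point
energies are external inputs (quantum-chemistry results supplied as plain
numbers with a provenance tag) — no electronic-structure calculation
happens here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .crystal_io import Molecule

__all__ = [
    "TorsionDefinition", "DeformationEnergy", "torsion_angle",
    "classify_torsion", "deformation_energy",
    "conformation_adjusted_difference",
]

CIS_TRANS_THRESHOLD = 90.0  # degrees


@dataclass(frozen=True)
class TorsionDefinition:
    """A named torsion (e.g. τ_A) over four bonded atom labels."""

    name: str
    atom_labels: tuple
    cis_threshold: float = CIS_TRANS_THRESHOLD

    def __post_init__(self):
        if len(set(self.atom_labels)) != 4:
            raise ValueError("a torsion needs four distinct atoms")


@dataclass(frozen=True)
class DeformationEnergy:
    """ΔE_conf between two conformers with a provenance echo."""

    value: float            # kcal/mol, E_a − E_b
    provenance: str = ""


def torsion_angle(molecule: Molecule, atom_labels) -> float:
    """Signed dihedral (IUPAC convention) in degrees, in (−180, 180].

    The four atoms must form a bonded chain a-b-c-d; the sign is that of
    the rotation of a→b seen along b→c towards c→d.
    """
    idx = []
    for lab in atom_labels:
        match = [i for i, a in enumerate(molecule.atoms) if a.label == lab]
        if not match:
            raise ValueError(f"no atom labelled {lab!r}")
        idx.append(match[0])
    bonds = {tuple(sorted(b)) for b in molecule.bonds}
    for u, v in zip(idx[:-1], idx[1:]):
        if tuple(sorted((u, v))) not in bonds:
            raise ValueError(
                f"atoms {atom_labels} are not a bonded chain: missing bond "
                f"{molecule.atoms[u].label}-{molecule.atoms[v].label}")
    p = molecule.cart_coords[idx]
    b0, b2 = p[0] - p[1], p[3] - p[2]
    b1 = p[2] - p[1]
    b1 = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1) * b1
    w = b2 - np.dot(b2, b1) * b1
    if np.linalg.norm(v) < 1e-10 or np.linalg.norm(w) < 1e-10:
        raise ValueError("undefined torsion: three collinear atoms")
    x = np.dot(v, w)
    y = np.dot(np.cross(b1, v), w)
    angle = math.degrees(math.atan2(y, x))
    if angle <= -180.0:
        angle += 360.0
    return angle


def classify_torsion(angle: float,
                     threshold: float = CIS_TRANS_THRESHOLD) -> str:
    """cis when |angle| < threshold, else trans."""
    return "cis" if abs(angle) < threshold else "trans"


def deformation_energy(e_a: float, e_b: float,
                       provenance: str = "") -> DeformationEnergy:
    """ΔE_conf = E_a − E_b (kcal/mol); both on the same level of theory.

    Exactly antisymmetric under argument swap.
    """
    return DeformationEnergy(value=e_a - e_b, provenance=provenance)


def conformation_adjusted_difference(e_cr_a: float, e_cr_b: float,
                                     de_conf: float) -> float:
    """Packing advantage of polymorph b over a, net of its conformational
    penalty: |E_cr_b| − |E_cr_a| − |ΔE_conf| (kcal/mol)."""
    return abs(e_cr_b) - abs(e_cr_a) - abs(de_conf)
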