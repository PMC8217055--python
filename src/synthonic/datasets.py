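"""Published reference data for the ritonavir polymorph case study.

Force-field-level lattice and attachment energies, BFDH face data and
conformer single-point energies for ritonavir forms I (CSD refcode
YIGPIO02, monoclinic P2₁) and II (YIGPIO03, orthorhombic P2₁2₁2₁), as
tabulated in the literature.  These numbers are *inputs*: the heavy
calculations behind them (semi-empirical charges, database structures)
are not reproduced here, but all derived quantities — d-spacings,
anisotropy factors, surface energies, particle-weighted surface energies,
packing coefficients, component percentages and the conformation-adjusted
lattice-energy difference — can be recomputed from them with this
package's closed-form operations.

Attachment energies and lattice energies are kcal/mol; d-spacings Å;
cell volumes Å³; surface energies mJ/m²; fractional areas in %.
"""

from __future__ import annotations

from .synthetic_data import table2_cells

FORM_I_CELL, FORM_II_CELL = table2_cells()

# conformer single-point energies (gas-phase DFT, kcal/mol)
CONFORMER_ENERGY = {"form_i": -1842838.84, "form_ii": -1842830.75}

# lattice energy and component breakdown (kcal/mol)
LATTICE = {
    "form_i": {"e_cr": -78.29, "vdw": -53.77, "coulomb": -11.39,
               "hbond": -13.13,
               "percent": {"vdw": 68.6, "coulomb": 14.5, "hbond": 16.8}},
    "form_ii": {"e_cr": -92.33, "vdw": -55.55, "coulomb": -18.54,
                "hbond": -18.24,
                "percent": {"vdw": 60.2, "coulomb": 20.1, "hbond": 19.8}},
}

# molecular descriptors
MOLECULAR = {
    "weight": 720.9,                       # g/mol
    "volume": {"form_i": 721.24, "form_ii": 676.74},        # Å³
    "packing_coefficient": {"form_i": 0.80, "form_ii": 0.73},
}

# per-face habit data: d-spacing (Å), fractional area (%), multiplicity,
# attachment energy (kcal/mol), anisotropy factor (%), total surface
# energy (mJ/m²).  The {1 0 -1} anisotropy entry and the form II {1 0 1}
# surface energy are known to be inconsistent with their own printed
# inputs; they are carried as printed and flagged where used.
FACES = {
    "form_i": [
        {"hkl": (0, 0, 1), "d": 25.96, "area_pct": 58.72, "mult": 2,
         "e_att": -9.87, "xi_pct": 87.39, "gamma": 98.62,
         "self_consistent_xi": True, "self_consistent_gamma": True},
        {"hkl": (1, 0, 0), "d": 12.98, "area_pct": 15.08, "mult": 2,
         "e_att": -22.30, "xi_pct": 71.53, "gamma": 111.35,
         "self_consistent_xi": True, "self_consistent_gamma": True},
        {"hkl": (1, 0, -1), "d": 12.87, "area_pct": 14.68, "mult": 2,
         "e_att": -22.19, "xi_pct": 73.18, "gamma": 109.90,
         "self_consistent_xi": False, "self_consistent_gamma": True},
        {"hkl": (0, 1, 1), "d": 5.11, "area_pct": 11.32, "mult": 4,
         "e_att": -57.29, "xi_pct": 26.82, "gamma": 112.59,
         "self_consistent_xi": True, "self_consistent_gamma": True},
    ],
    "form_ii": [
        {"hkl": (0, 1, 1), "d": 13.65, "area_pct": 58.48, "mult": 4,
         "e_att": -27.01, "xi_pct": 70.75, "gamma": 138.99,
         "self_consistent_xi": True, "self_consistent_gamma": True},
        {"hkl": (0, 0, 2), "d": 10.13, "area_pct": 12.52, "mult": 2,
         "e_att": -29.23, "xi_pct": 68.34, "gamma": 111.81,
         "self_consistent_xi": True, "self_consistent_gamma": True},
        {"hkl": (1, 0, 1), "d": 8.84, "area_pct": 25.40, "mult": 4,
         "e_att": -42.43, "xi_pct": 54.04, "gamma": 135.28,
         "self_consistent_xi": True, "self_consistent_gamma": False},
        {"hkl": (1, 1, 0), "d": 8.68, "area_pct": 3.56, "mult": 4,
         "e_att": -50.66, "xi_pct": 45.13, "gamma": 167.30,
         "self_consistent_xi": True, "self_consistent_gamma": False},
    ],
}

# whole-crystal area-weighted surface energies (mJ/m²)
PARTICLE_SURFACE_ENERGY = {"form_i": 103.58, "form_ii": 135.60}
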