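"""Crystal structure I/O and geometry.

Reads molecular-crystal structures from CIF, expands symmetry, perceives
covalent bonds across periodic boundaries and builds whole molecules, and
converts between fractional and Cartesian frames.

Conventions
-----------
* Fractional coordinates are the internal representation; the Cartesian
  frame is the standard crystallographic one (x along a, y in the a-b
  plane, z completing a right-handed set).
* Bond perception uses Cordero covalent radii with a +0.40 Å tolerance.
* van der Waals radii follow the Bondi set.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field, replace

import gemmi
import networkx as nx
import numpy as np

__all__ = [
    "UnitCell",
    "SymmetryOp",
    "Atom",
    "Molecule",
    "CrystalStructure",
    "CifParseError",
    "UnsupportedSymmetryError",
    "NotMolecularCrystalError",
    "read_cif",
    "write_cif",
    "perceive_molecules",
    "expand_cluster",
    "add_hydroxyl_hydrogen",
    "read_charge_file",
    "write_charge_file",
    "assign_charges",
]

# Cordero et al. covalent radii (Å); single-bond values.
COVALENT_RADII = {
    "H": 0.31, "B": 0.84, "C": 0.76, "N": 0.71, "O": 0.66, "F": 0.57,
    "P": 1.07, "S": 1.05, "Cl": 1.02, "Br": 1.20, "I": 1.39,
}

# Bondi van der Waals radii (Å).
VDW_RADII = {
    "H": 1.20, "B": 1.92, "C": 1.70, "N": 1.55, "O": 1.52, "F": 1.47,
    "P": 1.80, "S": 1.80, "Cl": 1.75, "Br": 1.85, "I": 1.98,
}

ATOMIC_MASSES = {
    "H": 1.008, "B": 10.811, "C": 12.011, "N": 14.007, "O": 15.999,
    "F": 18.998, "P": 30.974, "S": 32.06, "Cl": 35.45, "Br": 79.904,
    "I": 126.904,
}

BOND_TOLERANCE = 0.40      # Å added to the covalent-radius sum
DUPLICATE_SITE_CUTOFF = 0.3  # Å; guard against symmetry over-generation


class CifParseError(ValueError):
    """A required CIF block (cell, symmetry or atom loop) is missing."""


class UnsupportedSymmetryError(ValueError):
    """Space-group symbol not in the built-in table and no explicit ops."""


class NotMolecularCrystalError(ValueError):
    """Bond perception found a covalent network that is periodic (polymeric)."""


# --------------------------------------------------------------------------
# core types
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class UnitCell:
    """Triclinic unit cell; lengths in Å, angles in degrees."""

    a: float
    b: float
    c: float
    alpha: float = 90.0
    beta: float = 90.0
    gamma: float = 90.0

    def __post_init__(self):
        if min(self.a, self.b, self.c) <= 0:
            raise ValueError("cell lengths must be positive")
        for ang in (self.alpha, self.beta, self.gamma):
            if not 0.0 < ang < 180.0:
                raise ValueError("cell angles must lie in (0, 180)")

    @property
    def frac_to_cart_matrix(self) -> np.ndarray:
        """3x3 matrix M with cartesian = M @ fractional."""
        al, be, ga = (math.radians(x) for x in (self.alpha, self.beta, self.gamma))
        cos_al, cos_be, cos_ga = math.cos(al), math.cos(be), math.cos(ga)
        sin_ga = math.sin(ga)
        cz_sq = 1.0 - cos_be**2 - ((cos_al - cos_be * cos_ga) / sin_ga) ** 2
        if cz_sq <= 0:
            raise ValueError("degenerate cell angles")
        return np.array([
            [self.a, self.b * cos_ga, self.c * cos_be],
            [0.0, self.b * sin_ga, self.c * (cos_al - cos_be * cos_ga) / sin_ga],
            [0.0, 0.0, self.c * math.sqrt(cz_sq)],
        ])

    @property
    def cart_to_frac_matrix(self) -> np.ndarray:
        return np.linalg.inv(self.frac_to_cart_matrix)

    @property
    def metric_tensor(self) -> np.ndarray:
        m = self.frac_to_cart_matrix
        return m.T @ m

    @property
    def reciprocal_metric_tensor(self) -> np.ndarray:
        return np.linalg.inv(self.metric_tensor)

    @property
    def volume(self) -> float:
        """Cell volume in Å³ (determinant of the frac→cart matrix)."""
        return float(np.linalg.det(self.frac_to_cart_matrix))

    def to_cartesian(self, frac) -> np.ndarray:
        return np.asarray(frac, dtype=float) @ self.frac_to_cart_matrix.T

    def to_fractional(self, cart) -> np.ndarray:
        return np.asarray(cart, dtype=float) @ self.cart_to_frac_matrix.T

    def perpendicular_widths(self) -> np.ndarray:
        """Distance between opposite cell faces along each axis (Å)."""
        m = self.frac_to_cart_matrix
        widths = []
        for i in range(3):
            j, k = (i + 1) % 3, (i + 2) % 3
            cross = np.cross(m[:, j], m[:, k])
            widths.append(abs(self.volume) / np.linalg.norm(cross))
        return np.array(widths)


@dataclass(frozen=True)
class SymmetryOp:
    """Space-group operation in fractional coordinates: x' = R x + t."""

    rot: tuple
    trans: tuple

    @classmethod
    def from_xyz(cls, triplet: str) -> "SymmetryOp":
        op = gemmi.Op(triplet)
        den = float(gemmi.Op.DEN)
        rot = np.array(op.rot, dtype=float) / den
        trans = np.array(op.tran, dtype=float) / den
        return cls(tuple(map(tuple, rot.round(10))), tuple(trans.round(10)))

    @property
    def rotation(self) -> np.ndarray:
        return np.array(self.rot, dtype=float)

    @property
    def translation(self) -> np.ndarray:
        return np.array(self.trans, dtype=float)

    @property
    def is_identity(self) -> bool:
        return (np.allclose(self.rotation, np.eye(3))
                and np.allclose(self.translation % 1.0, 0.0))

    def apply(self, frac) -> np.ndarray:
        return np.asarray(frac, dtype=float) @ self.rotation.T + self.translation

    def triplet(self) -> str:
        den = gemmi.Op.DEN
        rot = (np.array(self.rot) * den).round().astype(int).tolist()
        tran = (np.array(self.trans) * den).round().astype(int).tolist()
        op = gemmi.Op()
        op.rot = rot
        op.tran = tran
        return op.triplet()

    def symmetry_class(self) -> str:
        """Classify the generating relation: translation | screw | other."""
        r = self.rotation
        if np.allclose(r, np.eye(3)):
            return "translation"
        det = np.linalg.det(r)
        trace = np.trace(r)
        if abs(det - 1.0) < 1e-9 and abs(trace + 1.0) < 1e-9:
            # two-fold rotation; screw if it has an intrinsic translation
            # component along the axis (t + R t)/2 non-lattice
            intrinsic = (self.translation + r @ self.translation) / 2.0
            if not np.allclose(intrinsic % 1.0, 0.0, atol=1e-9):
                return "screw"
            return "other"
        return "other"


# Built-in operator tables for the space groups the generator emits.
_BUILTIN_SPACEGROUPS = {
    "P1": ["x,y,z"],
    "P21": ["x,y,z", "-x,y+1/2,-z"],
    "P212121": ["x,y,z", "-x+1/2,-y,z+1/2", "x+1/2,-y+1/2,-z", "-x,y+1/2,-z+1/2"],
}


def _normalise_sg_symbol(symbol: str) -> str:
    s = re.sub(r"[\s_()]", "", symbol)
    s = s.replace("₁", "1")
    if s in ("P1211", "P21/m1"):  # common full Hermann-Mauguin variants
        s = "P21"
    if s == "P121":
        s = "P1"
    return s


@dataclass
class Atom:
    element: str
    label: str
    frac: np.ndarray
    charge: float | None = None
    fragment: str | None = None

    def __post_init__(self):
        self.frac = np.asarray(self.frac, dtype=float)
        if not np.all(np.isfinite(self.frac)):
            raise ValueError(f"non-finite coordinates for atom {self.label}")
        if self.element not in COVALENT_RADII:
            raise ValueError(f"unknown element {self.element!r} for atom {self.label}")

    @property
    def vdw_radius(self) -> float:
        return VDW_RADII[self.element]

    @property
    def covalent_radius(self) -> float:
        return COVALENT_RADII[self.element]

    @property
    def mass(self) -> float:
        return ATOMIC_MASSES[self.element]


@dataclass
class Molecule:
    """A whole molecule: atoms, covalent bonds and a generation identifier.

    The identifier ``ident`` is ``(asu_index, op_index, (ta, tb, tc))`` —
    which asymmetric-unit molecule, through which symmetry operator, shifted
    by which lattice translation.
    """

    atoms: list
    bonds: list = field(default_factory=list)
    cell: UnitCell | None = None
    ident: tuple = (0, 0, (0, 0, 0))

    @property
    def frac_coords(self) -> np.ndarray:
        return np.array([a.frac for a in self.atoms])

    @property
    def cart_coords(self) -> np.ndarray:
        return self.cell.to_cartesian(self.frac_coords)

    @property
    def centroid(self) -> np.ndarray:
        """Unweighted mean of atomic Cartesian positions (Å)."""
        return self.cart_coords.mean(axis=0)

    @property
    def elements(self) -> list:
        return [a.element for a in self.atoms]

    @property
    def charges(self) -> np.ndarray:
        return np.array([0.0 if a.charge is None else a.charge for a in self.atoms])

    @property
    def molecular_weight(self) -> float:
        return sum(a.mass for a in self.atoms)

    def neighbour_indices(self, i: int) -> list:
        out = []
        for a, b in self.bonds:
            if a == i:
                out.append(b)
            elif b == i:
                out.append(a)
        return out

    def transformed(self, op: SymmetryOp, tvec=(0, 0, 0), asu_index: int | None = None,
                    op_index: int = 0) -> "Molecule":
        """Apply a symmetry operator plus lattice translation to all atoms."""
        tvec = np.asarray(tvec, dtype=float)
        atoms = [replace(a, frac=op.apply(a.frac) + tvec) for a in self.atoms]
        ident = (self.ident[0] if asu_index is None else asu_index,
                 op_index, tuple(int(t) for t in np.round(tvec)))
        return Molecule(atoms=atoms, bonds=list(self.bonds), cell=self.cell, ident=ident)


@dataclass
class CrystalStructure:
    cell: UnitCell
    symmetry_ops: list
    molecules: list                  # asymmetric-unit molecules (Z' entries)
    space_group: str = "P1"

    @property
    def z_prime(self) -> int:
        return len(self.molecules)

    @property
    def z(self) -> int:
        return self.z_prime * len(self.symmetry_ops)

    def unit_cell_molecules(self) -> list:
        """All Z molecules of one cell (symmetry images wrapped to the cell)."""
        out = []
        for i, mol in enumerate(self.molecules):
            for k, op in enumerate(self.symmetry_ops):
                m = mol.transformed(op, (0, 0, 0), asu_index=i, op_index=k)
                # wrap the centroid into [0, 1)
                cfrac = m.frac_coords.mean(axis=0)
                shift = -np.floor(cfrac)
                if np.any(shift):
                    m = m.transformed(SymmetryOp.from_xyz("x,y,z"), shift,
                                      asu_index=i, op_index=k)
                out.append(m)
        return out

    def validate(self):
        """Check the duplicate-site guard over one expanded cell."""
        frac = np.vstack([m.frac_coords for m in self.unit_cell_molecules()])
        n = len(frac)
        if n > 1:
            delta = frac[:, None, :] - frac[None, :, :]
            delta -= np.round(delta)
            cart = delta @ self.cell.frac_to_cart_matrix.T
            dist = np.linalg.norm(cart, axis=-1)
            dist[np.diag_indices(n)] = np.inf
            if dist.min() < DUPLICATE_SITE_CUTOFF:
                i, j = np.unravel_index(np.argmin(dist), dist.shape)
                raise ValueError(
                    f"duplicate sites: generated atoms {i} and {j} are "
                    f"{dist.min():.3f} Å apart (< {DUPLICATE_SITE_CUTOFF} Å)")
        return self


# --------------------------------------------------------------------------
# CIF reading / writing
# --------------------------------------------------------------------------

def _element_from_label(label: str) -> str:
    m = re.match(r"([A-Z][a-z]?)", label)
    if not m:
        raise CifParseError(f"cannot infer element from site label {label!r}")
    sym = m.group(1)
    if sym not in COVALENT_RADII and sym[:1] in COVALENT_RADII:
        sym = sym[:1]
    return sym


def read_cif(path) -> CrystalStructure:
    """Parse a small-molecule CIF into a :class:`CrystalStructure`.

    Symmetry comes from ``_symmetry_equiv_pos_as_xyz`` (or the newer
    ``_space_group_symop_operation_xyz``) when present, otherwise from a
    built-in table covering P1, P2₁ and P2₁2₁2₁.  Atoms are returned in one
    un-perceived molecule; call :func:`perceive_molecules` to assign bonds.
    """
    doc = gemmi.cif.read_file(str(path))
    block = doc.sole_block()

    def cell_value(tag):
        v = block.find_value(tag)
        if v is None:
            raise CifParseError(f"missing cell item {tag}")
        return float(gemmi.cif.as_number(v))

    cell = UnitCell(
        cell_value("_cell_length_a"), cell_value("_cell_length_b"),
        cell_value("_cell_length_c"), cell_value("_cell_angle_alpha"),
        cell_value("_cell_angle_beta"), cell_value("_cell_angle_gamma"))

    triplets = [gemmi.cif.as_string(v) for v in
                block.find_loop("_symmetry_equiv_pos_as_xyz")]
    if not triplets:
        triplets = [gemmi.cif.as_string(v) for v in
                    block.find_loop("_space_group_symop_operation_xyz")]
    sg_symbol = None
    for tag in ("_symmetry_space_group_name_H-M", "_space_group_name_H-M_alt"):
        v = block.find_value(tag)
        if v is not None:
            sg_symbol = gemmi.cif.as_string(v)
            break
    if not triplets:
        if sg_symbol is None:
            raise CifParseError("missing symmetry block: no operator loop and "
                                "no space-group symbol")
        key = _normalise_sg_symbol(sg_symbol)
        if key not in _BUILTIN_SPACEGROUPS:
            raise UnsupportedSymmetryError(
                f"space group {sg_symbol!r} has no explicit operators and is "
                f"not in the built-in table {sorted(_BUILTIN_SPACEGROUPS)}")
        triplets = _BUILTIN_SPACEGROUPS[key]
    ops = [SymmetryOp.from_xyz(t) for t in triplets]

    labels = block.find_loop("_atom_site_label")
    if not labels:
        raise CifParseError("missing atom-site loop (_atom_site_label)")
    tags = ["_atom_site_label", "_atom_site_fract_x", "_atom_site_fract_y",
            "_atom_site_fract_z"]
    table = block.find(tags)
    if not table:
        raise CifParseError("incomplete atom-site loop: need "
                            "_atom_site_fract_x/_y/_z alongside _atom_site_label")
    symbols = [gemmi.cif.as_string(v) for v in block.find_loop("_atom_site_type_symbol")]
    charges = [gemmi.cif.as_number(v) for v in block.find_loop("_atom_site_charge")]

    atoms = []
    for i, row in enumerate(table):
        label = gemmi.cif.as_string(row[0])
        element = symbols[i] if i < len(symbols) else _element_from_label(label)
        frac = [gemmi.cif.as_number(row[j]) for j in (1, 2, 3)]
        charge = charges[i] if i < len(charges) else None
        atoms.append(Atom(element=element, label=label, frac=np.array(frac),
                          charge=charge))

    mol = Molecule(atoms=atoms, bonds=[], cell=cell)
    structure = CrystalStructure(cell=cell, symmetry_ops=ops, molecules=[mol],
                                 space_group=sg_symbol or "P1")
    structure.validate()
    return structure


def write_cif(structure: CrystalStructure, path, name: str = "synthonic",
              include_charges: bool = False) -> None:
    """Write the asymmetric unit in the same CIF dialect :func:`read_cif` reads."""
    cell = structure.cell
    lines = [f"data_{name}"]
    lines.append(f"_symmetry_space_group_name_H-M   '{structure.space_group}'")
    for tag, val in (("a", cell.a), ("b", cell.b), ("c", cell.c)):
        lines.append(f"_cell_length_{tag}   {val:.6f}")
    for tag, val in (("alpha", cell.alpha), ("beta", cell.beta),
                     ("gamma", cell.gamma)):
        lines.append(f"_cell_angle_{tag}   {val:.6f}")
    lines.append("loop_")
    lines.append("_symmetry_equiv_pos_as_xyz")
    for op in structure.symmetry_ops:
        lines.append(f"  '{op.triplet()}'")
    lines.append("loop_")
    lines.append("_atom_site_label")
    lines.append("_atom_site_type_symbol")
    lines.append("_atom_site_fract_x")
    lines.append("_atom_site_fract_y")
    lines.append("_atom_site_fract_z")
    if include_charges:
        lines.append("_atom_site_charge")
    for mol in structure.molecules:
        for atom in mol.atoms:
            row = (f"  {atom.label} {atom.element} "
                   f"{atom.frac[0]:.8f} {atom.frac[1]:.8f} {atom.frac[2]:.8f}")
            if include_charges:
                row += f" {0.0 if atom.charge is None else atom.charge:.6f}"
            lines.append(row)
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def export_xyz(molecules: list, path, comment: str = "") -> None:
    """Write a cluster of molecules as a plain XYZ file."""
    n = sum(len(m.atoms) for m in molecules)
    with open(path, "w") as fh:
        fh.write(f"{n}\n{comment}\n")
        for mol in molecules:
            for atom, xyz in zip(mol.atoms, mol.cart_coords):
                fh.write(f"{atom.element} {xyz[0]:.6f} {xyz[1]:.6f} {xyz[2]:.6f}\n")


# --------------------------------------------------------------------------
# molecule perception
# --------------------------------------------------------------------------

def perceive_molecules(structure: CrystalStructure,
                       tolerance: float = BOND_TOLERANCE) -> CrystalStructure:
    """Assign covalent bonds and split the asymmetric unit into whole molecules.

    Two atoms are bonded when some periodic image lies within
    ``r_cov(i) + r_cov(j) + tolerance``.  Connected components become
    molecules; atoms are translated so every molecule is whole (contiguous
    in Cartesian space) even when the deposited coordinates straddle a cell
    boundary.  A component bonded to its own periodic image raises
    :class:`NotMolecularCrystalError`.
    """
    cell = structure.cell
    atoms = [a for mol in structure.molecules for a in mol.atoms]
    n = len(atoms)
    frac = np.array([a.frac for a in atoms])

    shifts = np.array([(i, j, k) for i in (-1, 0, 1) for j in (-1, 0, 1)
                       for k in (-1, 0, 1)], dtype=float)
    graph = nx.Graph()
    graph.add_nodes_from(range(n))
    self_bonded = []
    for i in range(n):
        for j in range(i, n):
            delta = frac[j] + shifts - frac[i]
            d = np.linalg.norm(cell.to_cartesian(delta), axis=1)
            cut = atoms[i].covalent_radius + atoms[j].covalent_radius + tolerance
            if i == j:
                if np.any((d > 1e-6) & (d < cut)):
                    self_bonded.append(atoms[i].label)
                continue
            hits = np.where(d < cut)[0]
            if len(hits) > 1:
                # bonded through two distinct periodic images: the covalent
                # network wraps the cell
                raise NotMolecularCrystalError(
                    f"not a molecular crystal: atoms {atoms[i].label}/"
                    f"{atoms[j].label} bond through multiple periodic images")
            if len(hits):
                graph.add_edge(i, j, shift=shifts[hits[0]])
    if self_bonded:
        raise NotMolecularCrystalError(
            f"not a molecular crystal: atoms {self_bonded} bond to their own "
            "periodic images")

    molecules = []
    for comp in sorted(nx.connected_components(graph), key=min):
        comp = sorted(comp)
        offset = {comp[0]: np.zeros(3)}
        for u, v in nx.bfs_edges(graph.subgraph(comp), comp[0]):
            # shifts are stored from the lower to the higher atom index
            s = graph.edges[u, v]["shift"]
            shift = s if u < v else -s
            new_off = offset[u] + shift
            if v in offset:
                if not np.allclose(offset[v], new_off, atol=1e-6):
                    raise NotMolecularCrystalError(
                        "not a molecular crystal: inconsistent periodic "
                        f"unwrapping around atom {atoms[v].label}")
            else:
                offset[v] = new_off
        # cross-check every edge, not only the BFS tree
        sub = graph.subgraph(comp)
        for u, v in sub.edges:
            s = graph.edges[min(u, v), max(u, v)]["shift"]
            if not np.allclose(offset[max(u, v)] - offset[min(u, v)], s, atol=1e-6):
                raise NotMolecularCrystalError(
                    "not a molecular crystal: covalent network wraps the cell")
        new_atoms = [replace(atoms[i], frac=frac[i] + offset[i]) for i in comp]
        local = {g: l for l, g in enumerate(comp)}
        bonds = sorted((local[u], local[v]) if local[u] < local[v]
                       else (local[v], local[u]) for u, v in sub.edges)
        molecules.append(Molecule(atoms=new_atoms, bonds=bonds, cell=cell,
                                  ident=(len(molecules), 0, (0, 0, 0))))
    return CrystalStructure(cell=cell, symmetry_ops=structure.symmetry_ops,
                            molecules=molecules, space_group=structure.space_group)


# --------------------------------------------------------------------------
# cluster expansion
# --------------------------------------------------------------------------

def expand_cluster(structure: CrystalStructure, radius: float,
                   central_index: int = 0) -> list:
    """All whole molecules whose centroid lies within ``radius`` of the
    central molecule's centroid (the central molecule itself excluded).

    Membership is centroid-based: a molecule is in or out as a whole.
    Ordering is deterministic — by distance, then identifier.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    central = structure.molecules[central_index]
    c0 = central.centroid
    widths = structure.cell.perpendicular_widths()
    # margin of one molecular diameter so off-centre centroids are not missed
    extent = max(np.linalg.norm(m.cart_coords - m.centroid, axis=1).max()
                 for m in structure.molecules) if structure.molecules else 0.0
    nmax = np.ceil((radius + 2 * extent) / widths).astype(int) + 1

    c0_frac = structure.cell.to_fractional(c0)
    neighbours = []
    for i, mol in enumerate(structure.molecules):
        for k, op in enumerate(structure.symmetry_ops):
            base = mol.transformed(op, (0, 0, 0), asu_index=i, op_index=k)
            base_centroid_frac = base.frac_coords.mean(axis=0)
            # centre the translation search window on the central molecule
            t0 = np.round(c0_frac - base_centroid_frac).astype(int)
            for ta in range(t0[0] - nmax[0], t0[0] + nmax[0] + 1):
                for tb in range(t0[1] - nmax[1], t0[1] + nmax[1] + 1):
                    for tc in range(t0[2] - nmax[2], t0[2] + nmax[2] + 1):
                        t = np.array([ta, tb, tc], dtype=float)
                        cen = structure.cell.to_cartesian(base_centroid_frac + t)
                        d = np.linalg.norm(cen - c0)
                        if d < 1e-6 and i == central_index:
                            continue  # the central molecule itself
                        if d <= radius:
                            m = base.transformed(SymmetryOp.from_xyz("x,y,z"),
                                                 t, asu_index=i, op_index=k)
                            neighbours.append((d, m))
    neighbours.sort(key=lambda pair: (round(pair[0], 9), pair[1].ident))
    return [m for _, m in neighbours]


# --------------------------------------------------------------------------
# utilities
# --------------------------------------------------------------------------

def add_hydroxyl_hydrogen(molecule: Molecule, oxygen_label: str,
                          direction=(1.0, 0.0, 0.0), bond_length: float = 0.97,
                          label: str | None = None) -> Molecule:
    """Place an explicit hydroxyl hydrogen ``bond_length`` Å from an oxygen.

    Deposited structures sometimes omit the hydroxyl proton; this utility
    adds it explicitly (never silently) along a caller-chosen Cartesian
    direction.
    """
    idx = next((i for i, a in enumerate(molecule.atoms)
                if a.label == oxygen_label), None)
    if idx is None:
        raise ValueError(f"no atom labelled {oxygen_label!r}")
    direction = np.asarray(direction, dtype=float)
    direction = direction / np.linalg.norm(direction)
    o_cart = molecule.cart_coords[idx]
    h_frac = molecule.cell.to_fractional(o_cart + bond_length * direction)
    h = Atom(element="H", label=label or f"H{oxygen_label}", frac=h_frac)
    atoms = list(molecule.atoms) + [h]
    bonds = list(molecule.bonds) + [(idx, len(atoms) - 1)]
    return Molecule(atoms=atoms, bonds=bonds, cell=molecule.cell,
                    ident=molecule.ident)


def read_charge_file(path) -> dict:
    """Two-column text file (site label, charge in e) → ``{label: charge}``."""
    charges = {}
    with open(path) as fh:
        for line in fh:
            line = line.split("#")[0].strip()
            if not line:
                continue
            label, value = line.split()[:2]
            charges[label] = float(value)
    return charges


def write_charge_file(molecule: Molecule, path) -> None:
    with open(path, "w") as fh:
        for atom in molecule.atoms:
            fh.write(f"{atom.label} {0.0 if atom.charge is None else atom.charge:.6f}\n")


def assign_charges(structure: CrystalStructure, charges: dict) -> CrystalStructure:
    """Attach per-site charges (label → e) to every asymmetric-unit atom."""
    for mol in structure.molecules:
        for atom in mol.atoms:
            if atom.label not in charges:
                raise KeyError(f"no charge provided for site {atom.label!r}")
            atom.charge = charges[atom.label]
    return structure
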