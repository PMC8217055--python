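"""Crystal habit prediction: BFDH ranking, attachment energies, Wulff plots.

The lattice energy is partitioned per crystal face (hkl) into a slice
energy (interactions whose centroid separation projects inside a slab of
thickness d_hkl normal to the face) and an attachment energy (the rest):

    E_cr = E_sl(hkl) + E_att(hkl)

The relative growth rate of a face is taken proportional to |E_att|, and
the predicted habit is the Wulff polyhedron — the intersection of
half-spaces at centre-to-plane distances proportional to the growth rates,
expanded over all symmetry equivalents of each form.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import HalfspaceIntersection

from .crystal_io import CrystalStructure, UnitCell
from .energy_model import EnergyBreakdown, ForceField
from .lattice_analysis import DEFAULT_RADIUS, pair_records

__all__ = [
    "HabitFace", "WulffPolyhedron", "UnboundedHabitError", "d_spacing",
    "reflection_allowed", "form_equivalents", "bfdh_forms", "slice_partition",
    "wulff_construction",
]


class UnboundedHabitError(ValueError):
    """The requested forms do not close a convex polyhedron."""


@dataclass
class HabitFace:
    """A symmetry-related family {h k l} of crystal facets."""

    hkl: tuple
    d: float                                   # interplanar spacing, Å
    multiplicity: int = 1
    e_att: EnergyBreakdown | None = None
    e_sl: EnergyBreakdown | None = None
    growth_rate: float | None = None           # normalised to the slowest face
    area_fraction: float | None = None
    synthon_counts: dict = field(default_factory=dict)  # synthon label -> extrinsic count
    gamma: dict = field(default_factory=dict)  # surface-energy components, mJ/m²

    @property
    def label(self) -> str:
        h, k, l = self.hkl
        return "{%d %d %d}" % (h, k, l)


@dataclass
class WulffPolyhedron:
    vertices: np.ndarray
    facets: list          # list of (hkl-form tuple, normal, vertices-of-facet)
    form_areas: dict      # form tuple -> absolute area
    total_area: float

    @property
    def fractional_areas(self) -> dict:
        return {f: a / self.total_area for f, a in self.form_areas.items()}

    def caliper_extent(self, direction) -> float:
        """Width of the polyhedron along a Cartesian direction."""
        d = np.asarray(direction, dtype=float)
        d = d / np.linalg.norm(d)
        proj = self.vertices @ d
        return float(proj.max() - proj.min())

    def aspect_ratio(self, cell: UnitCell) -> dict:
        """Caliper extents along the crystallographic a, b, c directions."""
        m = cell.frac_to_cart_matrix
        return {axis: self.caliper_extent(m[:, i])
                for i, axis in enumerate("abc")}


# --------------------------------------------------------------------------
# reciprocal-space geometry
# --------------------------------------------------------------------------

def d_spacing(cell: UnitCell, hkl) -> float:
    """Interplanar spacing 1/√(hᵀ G* h) from the reciprocal metric tensor."""
    h = np.asarray(hkl, dtype=float)
    if not np.any(h):
        raise ValueError("(0 0 0) has no interplanar spacing")
    return float(1.0 / np.sqrt(h @ cell.reciprocal_metric_tensor @ h))


def plane_normal(cell: UnitCell, hkl) -> np.ndarray:
    """Unit Cartesian normal of the (hkl) plane (reciprocal-vector direction)."""
    n = np.linalg.inv(cell.frac_to_cart_matrix).T @ np.asarray(hkl, dtype=float)
    return n / np.linalg.norm(n)


def reflection_allowed(hkl, ops) -> bool:
    """Systematic-absence rule from the space-group operators.

    A reflection h is extinct when some operator with h R = h has a
    translation t with h·t non-integral.
    """
    h = np.asarray(hkl, dtype=float)
    for op in ops:
        if np.allclose(h @ op.rotation, h):
            phase = float(h @ op.translation)
            if abs(phase - round(phase)) > 1e-9:
                return False
    return True


def form_equivalents(hkl, ops, friedel: bool = True) -> list:
    """Orbit of (hkl) under the point group (rotation parts), plus Friedel mates."""
    h = np.asarray(hkl, dtype=int)
    seen = set()
    for op in ops:
        eq = tuple(np.rint(h @ op.rotation).astype(int))
        seen.add(eq)
        if friedel:
            seen.add(tuple(-x for x in eq))
    return sorted(seen, reverse=True)


def _canonical_rep(orbit) -> tuple:
    return max(orbit)


def bfdh_forms(structure: CrystalStructure, n_forms: int = 4,
               max_index: int = 3, rank_cut: float = 0.01) -> list:
    """Rank symmetry-unique forms by interplanar spacing (BFDH).

    Axial reflections killed by systematic absences are replaced by their
    smallest allowed multiple (e.g. (0 0 1) → (0 0 2) for a 2₁ screw along
    c), which halves the effective growth-slice thickness.  Forms whose
    corrected d falls below ``rank_cut`` of the best d are dropped.
    """
    ops = structure.symmetry_ops
    cell = structure.cell
    reps = {}
    for h in range(-max_index, max_index + 1):
        for k in range(-max_index, max_index + 1):
            for l in range(-max_index, max_index + 1):
                if (h, k, l) == (0, 0, 0):
                    continue
                if np.gcd.reduce(np.abs([h, k, l])) != 1:
                    continue
                orbit = form_equivalents((h, k, l), ops)
                rep = _canonical_rep(orbit)
                if rep not in reps:
                    reps[rep] = len(orbit)

    faces = []
    for rep, mult in reps.items():
        for m in (1, 2, 3, 4):
            scaled = tuple(m * x for x in rep)
            if reflection_allowed(scaled, ops):
                break
        else:
            continue
        faces.append(HabitFace(hkl=scaled, d=d_spacing(cell, scaled),
                               multiplicity=mult))
    faces.sort(key=lambda f: (-round(f.d, 9), sum(abs(x) for x in f.hkl),
                              tuple(-x for x in f.hkl)))
    if faces:
        best = faces[0].d
        faces = [f for f in faces if f.d >= rank_cut * best]
    return faces[:n_forms]


# --------------------------------------------------------------------------
# slice / attachment partition
# --------------------------------------------------------------------------

def slice_partition(structure: CrystalStructure, hkl,
                    ff: ForceField | None = None,
                    radius: float = DEFAULT_RADIUS,
                    d: float | None = None,
                    synthons: list | None = None,
                    central_index: int = 0,
                    records: list | None = None) -> HabitFace:
    """Partition the lattice energy of a face into slice and attachment parts.

    A pair interaction is *intrinsic* (contributes to E_sl) when the
    centroid separation projected on the face normal is smaller than d/2 —
    i.e. the slab of thickness d centred on the reference molecule contains
    both partners.  Everything else is *extrinsic* (contributes to E_att).
    The identity E_cr = E_sl + E_att holds by construction.
    """
    ff = ff or ForceField()
    cell = structure.cell
    hkl = tuple(int(x) for x in hkl)
    if d is None:
        d = d_spacing(cell, hkl)
    if records is None:
        records = pair_records(structure, ff, radius, central_index)
    n = plane_normal(cell, hkl)
    c0 = structure.molecules[central_index].centroid

    e_sl = EnergyBreakdown()
    e_att = EnergyBreakdown()
    extrinsic = []
    for rec in records:
        proj = abs(float(np.dot(rec.neighbour.centroid - c0, n)))
        if proj < d / 2.0 - 1e-9:
            e_sl = e_sl + rec.breakdown
        else:
            e_att = e_att + rec.breakdown
            extrinsic.append(rec)
    face = HabitFace(hkl=hkl, d=d, e_sl=0.5 * e_sl, e_att=0.5 * e_att)

    if synthons is not None:
        counts = {s.label: 0 for s in synthons}
        for rec in extrinsic:
            for s in synthons:
                if any(m is rec for m in s.members) or (
                        abs(rec.breakdown.e_total - s.breakdown.e_total) <= 0.01
                        and abs(rec.distance - s.distance) <= 0.01):
                    counts[s.label] += 1
                    break
        face.synthon_counts = counts
    return face


# --------------------------------------------------------------------------
# Wulff construction
# --------------------------------------------------------------------------

def wulff_construction(faces: list, cell: UnitCell,
                       distances: dict | None = None) -> WulffPolyhedron:
    """Convex habit polyhedron from per-form growth rates.

    Each form contributes half-spaces for all its symmetry equivalents at a
    centre-to-plane distance proportional to |E_att| (or to explicitly
    supplied ``distances``).  Both (hkl) and (-h-k-l) carry the same
    distance (Friedel pairing).  Facet areas are accumulated per form;
    fractional areas are scale-invariant and sum to one.
    """
    if distances is None:
        distances = {}
        for f in faces:
            if f.e_att is None or f.e_att.e_total == 0.0:
                raise ValueError(f"face {f.label} has no attachment energy")
            distances[f.hkl] = abs(f.e_att.e_total)
    if min(distances.values()) <= 0:
        raise ValueError("growth-rate distances must be positive")

    normals, dists, owner = [], [], []
    seen = set()
    for f in faces:
        eqs = f.equivalents if hasattr(f, "equivalents") else None
        eqs = eqs or _friedel_expand(f.hkl)
        for eq in eqs:
            n = plane_normal(cell, eq)
            key = tuple(np.round(n, 9))
            if key in seen:
                continue
            seen.add(key)
            normals.append(n)
            dists.append(distances[f.hkl])
            owner.append(f.hkl)
    normals = np.array(normals)
    dists = np.array(dists)

    # Bounded iff every direction is capped: max over normals of n·u > 0 ∀u.
    open_dir = _open_direction(normals)
    if open_dir is not None:
        raise UnboundedHabitError(
            "habit is unbounded along direction "
            f"({open_dir[0]:+.3f} {open_dir[1]:+.3f} {open_dir[2]:+.3f}) — "
            "add a capping form")

    halfspaces = np.hstack([normals, -dists[:, None]])
    hs = HalfspaceIntersection(halfspaces, np.zeros(3))
    verts = hs.intersections

    form_areas: dict = {}
    facets = []
    for i, (n, d0) in enumerate(zip(normals, dists)):
        on_plane = verts[np.abs(verts @ n - d0) < 1e-8 * max(1.0, d0)]
        if len(on_plane) < 3:
            continue
        area, ordered = _polygon_area(on_plane, n)
        if area <= 1e-12:
            continue
        form_areas[owner[i]] = form_areas.get(owner[i], 0.0) + area
        facets.append((owner[i], n, ordered))
    total = sum(form_areas.values())
    # forms that ranked but grew out of the final shape keep a zero entry
    for f in faces:
        form_areas.setdefault(f.hkl, 0.0)
    return WulffPolyhedron(vertices=verts, facets=facets,
                           form_areas=form_areas, total_area=total)


def _friedel_expand(hkl):
    """Expand a form over its Friedel pair only (used when no symmetry list
    is attached to the face); callers wanting the full orbit should pass
    faces carrying an ``equivalents`` attribute."""
    return [tuple(hkl), tuple(-x for x in hkl)]


def expand_faces_by_symmetry(faces: list, ops) -> None:
    """Attach the full symmetry orbit to each face (in-place)."""
    for f in faces:
        f.equivalents = form_equivalents(f.hkl, ops)


def _open_direction(normals: np.ndarray):
    """A direction not capped by any half-space, or None if bounded."""
    probe = [u / np.linalg.norm(u) for u in
             np.vstack([np.eye(3), -np.eye(3),
                        [[1, 1, 1], [-1, -1, -1], [1, -1, 0], [-1, 1, 0],
                         [0, 1, -1], [0, -1, 1], [1, 0, -1], [-1, 0, 1]]])]
    for u in probe:
        if (normals @ u).max() <= 1e-9:
            return u
    # fall back on vertices of the normal set's convex gaps: use mean of
    # antipodal check — if the convex hull of normals contains the origin
    # strictly, the shape is bounded.
    try:
        from scipy.optimize import linprog
        # find u, |u|<=1 with n·u <= 0 for all n and maximize ||u||_1 proxy
        res = linprog(c=-np.ones(3), A_ub=normals, b_ub=np.zeros(len(normals)),
                      bounds=[(-1, 1)] * 3, method="highs")
        if res.status == 0 and -res.fun > 1e-6:
            u = res.x / np.linalg.norm(res.x)
            if (normals @ u).max() <= 1e-9:
                return u
    except Exception:
        pass
    return None


def _polygon_area(points: np.ndarray, normal: np.ndarray):
    """Area of a planar convex polygon given unordered vertices."""
    centroid = points.mean(axis=0)
    # in-plane basis
    ref = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(ref, normal)) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    u = np.cross(normal, ref)
    u /= np.linalg.norm(u)
    v = np.cross(normal, u)
    rel = points - centroid
    ang = np.arctan2(rel @ v, rel @ u)
    order = np.argsort(ang)
    pts = points[order]
    area = 0.0
    for i in range(len(pts)):
        area += np.dot(normal, np.cross(pts[i], pts[(i + 1) % len(pts)]))
    return abs(area) / 2.0, pts


# --------------------------------------------------------------------------
# polyhedron export
# --------------------------------------------------------------------------

def write_off(poly: WulffPolyhedron, path) -> None:
    verts, faces = _indexed_mesh(poly)
    with open(path, "w") as fh:
        fh.write("OFF\n")
        fh.write(f"{len(verts)} {len(faces)} 0\n")
        for v in verts:
            fh.write(f"{v[0]:.6f} {v[1]:.6f} {v[2]:.6f}\n")
        for f in faces:
            fh.write(str(len(f)) + " " + " ".join(map(str, f)) + "\n")


def write_ply(poly: WulffPolyhedron, path) -> None:
    verts, faces = _indexed_mesh(poly)
    with open(path, "w") as fh:
        fh.write("ply\nformat ascii 1.0\n")
        fh.write(f"element vertex {len(verts)}\n")
        fh.write("property float x\nproperty float y\nproperty float z\n")
        fh.write(f"element face {len(faces)}\n")
        fh.write("property list uchar int vertex_indices\nend_header\n")
        for v in verts:
            fh.write(f"{v[0]:.6f} {v[1]:.6f} {v[2]:.6f}\n")
        for f in faces:
            fh.write(str(len(f)) + " " + " ".join(map(str, f)) + "\n")


def _indexed_mesh(poly: WulffPolyhedron):
    verts = []
    index = {}
    faces = []
    for _, _, pts in poly.facets:
        face = []
        for p in pts:
            key = tuple(np.round(p, 8))
            if key not in index:
                index[key] = len(verts)
                verts.append(p)
            face.append(index[key])
        faces.append(face)
    return verts, faces
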