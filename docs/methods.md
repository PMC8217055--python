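# Methods

`synthonic` models the solid-state and surface energetics of molecular
crystals from an atom–atom, rigid-molecule picture: every property it
computes follows from a classification of the pairwise intermolecular
interactions (synthons) of a central molecule with its crystalline
environment. This note records the model, its tunable parameters, the
numerical choices, and what the synthetic test fixtures do and do not
demonstrate.

## Lattice energy

The crystal lattice (packing) energy per molecule is a direct sum over
whole molecules whose centroid lies within a summation radius *r* of the
central molecule's centroid,

    E_cr(r) = ½ Σ_k E_pair(central, neighbour_k),

with the handshake ½ because every pair interaction is shared by two
molecules. For Z′ > 1 the value is the arithmetic mean over the Z′
inequivalent central molecules (per-central values are retained in the
result object). There is no Ewald summation: electrostatics are summed
directly and convergence is assessed by profiling E_cr(r) on a 1 Å grid
(default 1–30 Å), exactly the convergence-by-radius design the workflow
is built around. The convergence radius is the smallest grid radius at
which |E(r) − E(r_max)|/|E(r_max)| falls below a tolerance (default 1%,
assessed over a trailing 2 Å window inside `lattice_energy`, which warns —
never fails — on an unconverged sum). Shell decompositions default to the
bins (0, 9], (9, 19], (19, 22], (22, 30] Å; the last bin closes the
telescoping identity (shell percentages sum to 100% of E(r_max)) while
the first three match the coordination-shell reports this kind of
analysis conventionally prints.

### Pair potential

Interactions are Dreiding-flavoured and intermolecular only (molecules
are rigid; no valence terms):

* **van der Waals** — Lennard-Jones 12-6, `D0[(R0/r)¹² − 2(R0/r)⁶]`, with
  geometric-mean `D0` and arithmetic-mean `R0` combining. Per-element
  defaults (kcal/mol, Å): H (0.0152, 3.195), C (0.0951, 3.8983),
  N (0.0774, 3.6621), O (0.0957, 3.4046), S (0.344, 4.03). The original
  force field also has an exponential-6 flavour; the 12-6 form is the
  common default and every parameter is overridable per element.
* **hydrogen bond** — a 12-10 well `D_hb[5(R_hb/r_DA)¹² − 6(R_hb/r_DA)¹⁰]
  · cos⁴θ` on detected D–H···A triplets, with defaults D_hb = 9.5
  kcal/mol, R_hb = 2.75 Å. Donors are O/N/S bearing a covalent H,
  acceptors O/N/S; a triplet is active when r(H···A) < 3.0 Å and
  θ(D-H···A) > 90°. Per the force field's convention the LJ terms of the
  (H, A) and (D, A) pairs are replaced by the single hydrogen-bond term;
  Coulomb terms are kept for all pairs.
* **electrostatics** — vacuum Coulomb, 332.0637 kcal·Å/(mol·e²),
  dielectric 1.

Atom pairs closer than 0.5 Å (or any single distance under 0.1 Å in the
scalar LJ) raise an overlap error: the rigid-molecule model is
meaningless there.

### Partial charges

Charges come from an external file (site label + charge, or a CIF charge
loop), which always takes precedence, or from the Gasteiger–Marsili
partial-equalization (PEOE) scheme implemented here: iterative transfer
across each bond damped by (1/2)^k, divisor equal to the cation
electronegativity of the donating atom (20.02 for H), convergence when
the largest transfer drops below 1e-5 e. Hybridisation is inferred from
the bond degree. The implementation agrees with RDKit's to ~1e-4 e on
small molecules (cross-checked in the test suite); semi-empirical (MOPAC)
charges are out of scope and must be supplied as a file.

## Synthons, fragments, hydrogen-bond inventory

Pair interactions are grouped into synthons when their total energies
agree within 0.01 kcal/mol **and** their centroid distances within
0.01 Å; groups are labelled A, B, C, … by descending |E|, tagged
"H-Bond" when |E_hbond| > 0.5 kcal/mol, and annotated with the generating
symmetry relation (pure translation, 2₁ screw, or other) derived from the
operator's rotation part and intrinsic translation. A synthon's energy is
the mean over its members, so Σ multiplicity × E over all synthons closes
to 2 E_cr exactly. Contributions are reported under *both* percentage
conventions — multiplicity·E/(2|E_cr|), which sums to 100%, and
multiplicity·E/|E_cr| — because published tables mix the two and they
differ by a factor of two.

Fragment partitioning assigns every atom-atom energy term half to the
fragment of each participating atom (the hydrogen-bond term is carried by
the H and A atoms); fragment totals conserve E_cr to machine precision.

The hydrogen-bond inventory lists symmetry-unique D–H···A triplets with
r(H···A), r(D···A), θ and the charge columns q_D (the donor *proton*
charge — the convention used in published tables of this kind), q_A (the
acceptor heavy atom) and q_diff = q_D − q_A, merging triplets with equal
labels and geometry (0.01 Å / 1°) and counting multiplicity.

## Morphology

* **d-spacings** from the reciprocal metric tensor, `1/√(hᵀ G* h)`.
* **BFDH** ranks symmetry-unique forms by interplanar spacing.
  Systematic absences follow from the operators themselves (h extinct
  when hR = h but h·t is non-integral); an extinct axial reflection is
  replaced by its smallest allowed multiple, e.g. (0 0 1) → (0 0 2)
  across a 2₁ screw, halving the growth-slice thickness. Ties in d break
  by lower index sum, then lexicographic order. The index search covers
  |h|,|k|,|l| ≤ 3 by default.
* **Slice/attachment partition** — a pair interaction is *intrinsic*
  when the centroid separation projected on the face normal is below
  d_hkl/2 (a slab of thickness d centred on the reference molecule holds
  both partners), else *extrinsic*. E_sl and E_att are the half-sums of
  the two classes, so E_cr = E_sl + E_att holds identically for every
  face. Centroid-slab membership is the standard attachment-energy
  convention; the alternative (atom-based membership) is not offered.
* **Wulff construction** — half-spaces at centre-to-plane distances
  proportional to |E_att| for every symmetry equivalent of each form
  (Friedel mates carry equal distances, so polar form pairs are treated
  as equivalent — reproduced, not resolved), intersected with
  `scipy.spatial.HalfspaceIntersection`. Facet areas are accumulated per
  form; fractional areas are scale-invariant and sum to one; forms that
  grow out of the final shape keep an explicit zero. An unbounded
  intersection (no capping form) raises an error naming the open
  direction. Caliper extents along the crystallographic axes provide the
  aspect-ratio metrics.

## Surface energetics

* anisotropy factor ξ = E_sl/E_cr = (E_cr − E_att)/E_cr, in %; a warning
  (not an error) if |E_att| > |E_cr|.
* surface energy γ = Z·|E_att|·d_hkl/(2·V_cell·N_A) converted with
  1 kcal = 4184 J, N_A = 6.02214076e23, reported in mJ/m². Attachment
  energies are negative for cohesive crystals; the magnitude convention
  makes γ positive, and component-wise γ comes from the component-wise
  attachment energy with the parent's sign.
* particle surface energy γ_particle = Σ γ_hkl·SA_hkl over the predicted
  (or supplied) fractional facet areas, used exactly as given (a warning
  if they do not sum to ≈1).
* rugosity: RMS of asymmetric-unit atomic heights about their *mean*
  along the face normal (the reference-plane origin is a convention; the
  centred choice makes the metric translation-invariant).

## Descriptors

Molecular volume and surface area are voxel-counted on the union of
Bondi vdW spheres (default grid 0.2 Å; the error is of the order of one
voxel layer and the tests include a grid-refinement check). Void space is
the percentage of cell voxels farther than a probe radius (default 1.2 Å,
grid 0.3 Å) from every sphere surface of the periodically packed cell.
Exact reference values for published void percentages depend on the
generating program's undocumented algorithm and are not matched, only the
construction is. Packing coefficient is Z·V_mol/V_cell; density is
Z·M/(N_A·V_cell).

## Conformers

Torsion angles use the standard signed-dihedral convention (verified
against RDKit's in the tests), classified cis when |τ| < 90°. Deformation
energies are plain differences of externally supplied single-point
energies with a provenance tag — no electronic-structure code runs here —
and the conformation-adjusted lattice-energy difference is
|E_cr(b)| − |E_cr(a)| − |ΔE_conf|.

## Synthetic fixtures: what they show and what they don't

The generator builds three families, all deterministic per seed and all
emitted as CIF so tests exercise the full parse → analyse path:

* a **chain fixture** (P1, one-atom molecules, repeat 5.215 Å along b,
  LJ parameters chosen so the nearest-neighbour pair energy is exactly
  the well depth): analytic E_cr, a single translation synthon of
  multiplicity 2, and a habit that must elongate along b;
* an **H-bonded fixture** (P2₁2₁2₁, five-atom molecule with one hydroxyl
  donor and one carbonyl-like acceptor) built so exactly one
  symmetry-unique O–H···O bond exists across the 2₁ screw along a, with
  r(H···A) drawn in [1.9, 2.4] Å and θ in [150°, 180°];
* **random P1 fixtures** (3–5 atom chains, mixed charges summing to
  zero, 8–9.5 Å cells chosen so a 15 Å summation radius captures a
  meaningful neighbour shell) for brute-force oracle comparisons.

The brute-force check, `supercell_oracle`, enumerates every symmetry
image in an n×n×n block with plain nested loops and scalar potentials —
no neighbour lists, no vectorised path — and must agree with the
cluster-expansion lattice sum to 1e-8 kcal/mol.

These fixtures validate the *machinery* (summation, classification,
partition identities, Wulff geometry), not the *parameterization*: real
pharmaceutical structures have two orders of magnitude more atom pairs,
conformational flexibility, and charge models (semi-empirical, DFT-derived)
this package deliberately treats as inputs. Absolute lattice energies of
real polymorphs therefore depend on the supplied structure, charges and
force-field constants; the shipped reference data for the ritonavir
polymorph pair are used as closed-form *inputs* (d-spacings, ξ, γ,
γ_particle, percentages, ΔE_conf arithmetic), and two rows of the source
table that are inconsistent with their own printed inputs ({1 0 −1} ξ;
form II {1 0 1} and {1 1 0} γ) are flagged as such rather than matched.

## Problem sizes

Defaults were chosen so the full pipeline on the synthetic fixtures runs
in seconds on one core: ≤ 12 atoms per molecule, summation radii 6–15 Å
in tests (30 Å default in production use), supercell oracles at n = 3–5,
voxel grids 0.1–0.5 Å. These are the package's own test-scale choices;
all are configurable upward.
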