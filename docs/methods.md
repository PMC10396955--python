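# Methods

## Exit-vector parameters

A disubstituted scaffold is reduced to four atoms: the two scaffold
attachment atoms C1 and C2 and the first atom of each substituent, X1 (bonded
to C1) and X2 (bonded to C2). The exit vectors are n1 = unit(X1 − C1) and
n2 = unit(X2 − C2); the package reports

- r = ‖C1 − C2‖ and d = ‖X1 − X2‖ (Å);
- φ1 = angle(n1, C2 − C1) and φ2 = angle(n2, C1 − C2), the plane angles
  between each exit vector and the internuclear axis. This axis convention is
  the one under which an ideal aromatic ring gives exactly 120°, and is the
  convention used in the exit-vector-plot literature;
- θ = torsion X1–C1–C2–X2, signed by the IUPAC convention (positive =
  clockwise rotation of the far bond looking from C1's side along the axis),
  in (−180°, 180°]. θ is kept signed internally; presentation surfaces show
  |θ|, which is what scaffold-comparison tables quote.

Numerical choices: angles use two-argument arctangent forms
(atan2(‖u×v‖, u·v) for plane angles; the cross-product atan2 formula for
torsions), which remain exact at 0° and 180° where arccos loses precision.
The torsion implementation was cross-checked against an independent
project-onto-the-normal-plane construction and against RDKit's dihedral
routine on random geometries (agreement to 1e-9, including sign). Coincident
atoms and collinear torsion frames raise a degenerate-geometry error naming
the offending atoms. Nothing is rounded internally; presentation layers round
to 0.01 Å and 1°. When a substituent's first atom is chemically ambiguous
(e.g. a carboxylate), the atom actually bonded to the attachment carbon is
used — the carboxyl carbon, never an oxygen.

## Structure input

SDF/MOL (V2000) and XYZ are read as-is; small-molecule CIF is read through
gemmi and converted from fractional to Cartesian coordinates with the
standard orthogonalisation (a along x, b in the xy plane); the same closed
form is inverted for writing, and the round trip is exact to 1e-10. Only the
asymmetric unit is read — no space-group expansion — which suffices because
the analysis needs a single molecule; structures whose asymmetric unit is not
a whole molecule are out of scope. Crystallographic disorder is collapsed
deterministically: sites sharing an atom label form a group, the
highest-occupancy site wins, ties go to the first listed, kept atoms get
occupancy 1. Hydrogens are retained on read; downstream steps decide whether
to use them.

Formats without a connection table (XYZ, CIF) get bonds perceived by a
covalent-radius criterion: atoms closer than the sum of their covalent radii
plus a tolerance (default 0.45 Å, configurable) are bonded. This is
deliberately simple; it is used only to support substructure matching, not to
assign bond orders.

## Scaffold registry and attachment matching

The registry ships four entries — ortho_benzene, bcp_12
(bicyclo[1.1.1]pentane, bridgehead + adjacent bridge position), bch_12
(bicyclo[2.1.1]hexane, bridgehead + adjacent two-carbon-bridge position) and
oxa_bch (2-oxabicyclo[2.1.1]hexane, oxygen-bearing bridgehead + one-carbon
bridge) — as a plain-text TSV of SMARTS patterns with two mapped attachment
positions, user-extensible without code changes. Ring bonds are written as
"any" bonds so the same pattern matches aromatic, Kekulé and
perceived-single-bond connection tables. Matching takes the first
substructure match (in the structure's own atom order, hence deterministic)
whose tagged positions both carry a non-scaffold heavy neighbour; among
several heavy neighbours the lowest index wins. A tagged position bearing
only hydrogens disqualifies its match; a bare tagged position in a structure
with no hydrogens at all raises an explicit "add hydrogens or give indices"
error, since an unmodelled hydrogen cannot be distinguished from a missing
substituent.

For the oxa cage, the attachment positions are the oxygen-bearing bridgehead
(aryl site) and an adjacent one-carbon bridge (carboxyl site). That is where
the crossed photochemical [2+2] route places the substituents — the
two-carbon bridge cannot carry one, its second position being the ether
oxygen — and the resulting model reproduces the deposited crystal geometry,
which confirms the tagging.

## Synthetic geometries

`build_ortho_benzene(a, b)` is the analytic reference: a regular planar
hexagon of side a (so circumradius = a) with exit atoms on the external
radial bisectors at distance b. Closed forms hold exactly: r = a,
φ1 = φ2 = 120°, θ = 0 and d = 2(a + b)·sin 30° = a + b. Defaults a = 1.39 Å,
b = 1.50 Å match typical aromatic and single-bond lengths.

`build_cage_3d(recipe)` assembles a cage template with two substituent
fragments (defaults: phenyl and carboxyl, emulating the crystallised
1-aryl cage carboxylic acids), embeds `n_conformers` conformers with ETKDG
under a fixed seed, minimises with MMFF94 (UFF fallback when parameters are
missing; the provenance string records which), and keeps the lowest-energy
conformer, ties broken by conformer index. Defaults: 20 conformers — ample
for rigid cages — and seed 7. Identical recipes give bit-identical
coordinates. The oxa template pins the anti diastereomer (carboxyl anti to
the ether bridge): the syn isomer is a different compound with |θ| ≈ 45°,
not the crystallised one.

`perturb_coordinates` adds seeded isotropic Gaussian noise for robustness
tests; at σ = 0.01 Å the ideal benzene stays within a few degrees of planar
across 100 seeds.

What the generator emulates — and what it does not: models are gas-phase
force-field minima of isolated molecules. They capture the cage's intrinsic
exit-vector geometry (rigid cages vary by only a few degrees across seeds and
force fields) but not crystal-packing distortion, lattice effects, or the
exact substituents of literature-deposited crystals. Passing the desk-scale
checks therefore demonstrates that the analysis pipeline and the cage
topology are right, not that a force field reproduces any particular crystal
to fractions of a degree. Concretely, with phenyl/carboxyl substituents and
MMFF94: the oxa cage gives |θ| = 79°, d = 3.56 Å — within a degree and a
few hundredths of an Å of the crystal values (80°, 3.6 Å) — while the
1,2-bicyclo[1.1.1]pentane model settles at |θ| ≈ 65° against a literature
crystal value of 58°, and the 1,2-bicyclo[2.1.1]hexane model at ≈ 63°
against ≈ 75°. An idealised rigid bicyclo[1.1.1]pentane (bridgehead exit
vector on the three-fold axis) already gives 67–71° for any reasonable cage
dimensions, so the literature values reflect the particular deposited
compounds and their crystal environment; the package reports what the
defined model conditions yield rather than tuning toward the crystal
numbers.

## Scaffold comparison score

`evp_distance` is a weighted scaled Euclidean distance over
(r, d, φ1, φ2, |θ|) with scale constants (0.1 Å, 0.5 Å, 10°, 10°, 30°):
one unit on each axis corresponds roughly to a chemically meaningful spread
(≈0.2 Å in r reads as "longer", ≈70° in |θ| separates flat from 3D).
Weights default to 1 and, like the scales, are configurable via a TOML file.
The score is a true metric on the five-tuple (non-negative, symmetric, zero
iff equal), verified on 1,000 random pairs.

## Physicochemical reference table

The packaged CSV holds literature-reported kinetic solubility (µM, PBS
pH 7.4), clogP, logD (pH 7.4) and human-liver-microsome intrinsic clearance
(µl·min⁻¹·mg⁻¹) for four marketed ortho-substituted-phenyl bioactives and
their carbocyclic and oxa-cage analogues (12 records, 4 triples). logD
values outside the assay's reliable 1.0–4.5 window are stored as absent and
never imputed. Each record carries a provenance flag: values the source text
states numerically are marked "reported"; the remaining cells (all clogP
values, the poorly-soluble lomitapide-series solubilities, the
metabolically-stable phthalylsulfathiazole-series clearances) are synthetic
placeholders consistent with the stated qualitative trends and are flagged
"estimated" so that no quantitative claim rests on them. All fold-changes
and reductions in reports are recomputed from this table at run time.

## Known limitations

- No space-group symmetry expansion; CIFs whose asymmetric unit is a partial
  molecule are not supported.
- Bond perception is distance-only (no bond orders); aromaticity is carried
  by the input format or bypassed via order-agnostic patterns.
- Gas-phase minima stand in for crystal conformations; see above for the
  size of that gap per scaffold.
- The physchem table supports arithmetic (ratios, deltas), not prediction;
  nothing in the package computes solubility, logD or clearance from
  structure.
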