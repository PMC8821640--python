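# Methods

## The lattice model

A 1-start helical lattice is generated by a single screw operation: subunit
i sits at axial position i·Δz and azimuth i·Δφ, with rise Δz > 0 (Å) and
twist Δφ (degrees).  All operators in the package are exact arithmetic on
this generator; no coordinates are needed for the lattice-level results.

Conventions, fixed once and used everywhere:

- **Sign/handedness.** Positive twist is a right-handed rotation about +z
  when advancing along +z.  A k-start strand family whose principal
  per-step rotation k·Δφ (mod 360°) is negative is therefore left-handed.
  On the default (5.57 Å, 108°) lattice this makes the 3-start family
  (−36°/step) left-handed and the 7-start family (+36°/step) right-handed.
  Published descriptions of such filaments are not always consistent about
  the 7-start handedness; the package reports what the geometry gives
  under its stated convention.
- **Principal range.** Angles are reduced to (−180°, +180°]; the raw
  (unreduced, or mod-360 in [0°, 360°)) representation is kept alongside,
  because both appear in practice (−72° vs 288°, 216°).
- **Indexing.** Subunit 0 at the origin; indices increase with +z.
- **Tolerances.** Angle comparisons at 1e−6°, lengths at 1e−9 Å unless
  overridden.  Start families whose principal step is within tolerance of
  0° (or 180°) are classified "vertical".

## Register patterns and symmetry reduction

Species assignment is modelled on the s strands of one start family:
`species(i) = (⌊i/s⌋ + offset[i mod s]) mod q`.  Species cycle within each
strand; each strand carries a phase offset.  s·q is always a period of the
resulting label sequence, and the minimal period of a periodic sequence
divides every period, so the minimal-period search scans the divisors of
s·q over a 2·s·q window — exact, not heuristic.  An independent
brute-force full-window scan is kept in the test suite as the oracle.

The species-respecting helical symmetry is the p-step screw
(p·Δz, p·Δφ mod 360°) with p the minimal label period.  For the default
two-species, three-strand pattern with offsets (0, 0, 1): p = 6, giving
33.42 Å / −72°; the in-register alternation (s = 1, q = 2) gives p = 2,
11.14 Å / 216°.  The empirically refined values of such lattices
(e.g. 33.4 Å / −71.8°) are treated as inputs, not as derivable numbers.

**Register inference.** The inverse problem (offsets from an observed label
sequence) is solved directly: offsets are read off the first s labels and
verified against the whole observation.  Because the within-strand
progression is the fixed cycle +1 mod q, the solution is unique only up to
a *global cyclic shift* of species names — arbitrary species permutations
are not a symmetry of the model for q ≥ 3 (they break the +1 progression).
The canonical representative has offset[0] = 0.  Inconsistent observations
raise an error carrying the first mismatching index.  A window of at least
2·s·q labels is required; since the model is exactly periodic, this finite
window is sufficient.

## Toy monomers and the synthetic filament

The synthetic module emulates a two-species archaellin-like filament well
enough to exercise every downstream analysis, at pseudo-atomic resolution:

- **Tail**: 46 residues (mature numbering 14–59, first and last residue
  named Ile/Ala) as an ideal α-helix — 1.5 Å rise per residue, 100°/residue,
  2.3 Å CA orbit — wound about a straight core center-line.  Each residue
  carries N, CA, O pseudo-backbone atoms.
- **Hinge**: Ser60–Gly61 bridging tail end and head.
- **Head**: a compact cluster of 40 pseudo-residues on a 9 Å sphere whose
  centroid sits at 40 Å radius (envelope ≈ 49 Å → ~98 Å diameter); charged
  and polar residues carry one side-chain atom each (NZ, OE1, NH1, OD1,
  ND2, OG, OG1, OH) so the contact tallies have chemistry to work with.
  Head placement uses a seeded RNG (default seed 7); identical
  (config, species) inputs are bitwise reproducible.
- **Species 1** additionally carries an outward surface loop (residues
  131–137, Lys…Ala) containing consecutive asparagines in an NNTT stretch —
  two overlapping N-X-S/T sequons — extending the envelope to ~110 Å.

**Tail-contact calibration.** The tail center-line anchors — start at
(radius 4.5 Å, azimuth 0°), end at (16.5 Å, 75°), axial extent fixed by the
69 Å length — were chosen once by a coarse grid search so that on the
default lattice the minimal segment–segment distance between tail
center-lines is ≤ 6.6 Å for neighbour offsets {±1, ±3, ±4, ±7} and ≥ 9.6 Å
for all other |k| ≤ 10, a ≥ 1.4 Å margin on either side of the 8 Å core
cutoff.  The constants are version-controlled in `synth.py`; nothing is
fitted at runtime.

What the toy does **not** emulate: real side-chain rotamers and packing
(atoms of adjacent toy tails can approach closer than physical contact
distances), glycans, metal sites, density-derived species assignment, or
cryo-EM noise.  Tests passing on the fixture demonstrate the correctness of
the lattice algebra, the contact geometry and the bending kinematics — not
agreement with any deposited structure's interface counts or energetics.

## Contact analysis

Hydrogen bonds are N/O heavy-atom pairs across an interface within 3.5 Å
where one atom can donate and the other accept (capability table keyed by
residue and atom name; proline backbone N does not donate).  No angular
term is applied — donor positions at pseudo-atomic resolution do not
support one.  Salt bridges are Lys/Arg/His basic nitrogens within 4.0 Å of
Asp/Glu carboxyl oxygens.  Tail-core packing reduces each annotated tail to
its least-squares center-line segment (principal axis of the tail atoms,
clipped to their extent) and reports neighbour offsets whose segment passes
within 8.0 Å.  All three cutoffs are user-settable (`ContactCriteria`).
Spatial queries use a KD-tree; an O(N²) all-pairs scan is kept as the test
oracle.  Every report carries the disclaimer that these are geometric
distance-threshold counts, not an interface-energetics calculation.

## Bending forward model

Bending is a forward kinematic model, not a re-analysis of image data: the
straight filament axis is mapped onto a circular arc of radius 1/κ, and the
subunit whose lattice station is at z moves rigidly to arc angle θ = κ·z
with its frame rotated to follow the tangent.  Arc length along the neutral
axis is preserved exactly, so material at lateral offset d toward the bend
azimuth is stretched by (1 + dκ) and the opposite side compressed by
(1 − dκ); the bend-plane azimuth points to the **convex** side.  κ = 0 is
the identity (bitwise).  A bend with κ·(filament radius) ≥ 1 is rejected as
self-intersecting.  An optional hinge swing adds a rigid rotation of the
head about an axis through the hinge midpoint (default 0°, as no
quantitative hinge amplitude is available to emulate); an optional
superhelix mode advances the bend azimuth with z at a set pitch.

Motion reports compare two topologically identical conformations per
subunit: centroid displacement vector; head-centroid displacement after
superposing the moving tail onto the reference tail (Kabsch), isolating
head-vs-tail motion; internal head RMSD after optimal superposition (zero
for rigid heads, by construction); **tail slide**, defined as the
station-relative tail-centroid displacement projected on the local filament
axis — for a pure arc this equals d·sin θ, positive on the convex and
negative on the concave side, so opposite axial (n+10) columns slide with
opposite signs; and tail rotation about the local axis measured in the
subunit's local frame.  Head-centroid trajectories across a frame series
report path length and net displacement.

## Structure I/O

Models are written one chain per subunit: mmCIF with multi-character chain
ids `S0000…` (primary), legacy PDB limited to 62 single-character ids with
an explicit error beyond that.  Coordinates survive a write/read round trip
to better than 1e−3 Å (the PDB field precision).  Monomer readers accept a
tail range and hinge range and complete the head range to the chain's last
residue; residue numbering is preserved as given (mature numbering starting
at 14 in the fixtures).  Glycans and metals are never placed — sequons are
annotated from sequence only (N-X-S/T, overlapping matches all reported,
optional exclusion of X = proline).

## Problem sizes and determinism

Default analysis sizes keep everything exact and fast: 36-subunit fixtures
for contact maps and bending (interior reference with |k| ≤ 10 on both
sides), 60 subunits for the brute-force contact oracle, 48-subunit windows
for period scans, 200-case random suites for the register oracles and 1000
for the operator group law.  All randomness (head jitter, label corruption,
random test suites) flows through seeded NumPy generators; fixtures are
bitwise reproducible for a given seed.

## Known limitations

- Labels are symbolic; nothing infers species identity from density or
  sequence.
- Contact counts on the toy fixture are indicative of the lattice geometry
  only; they are not comparable to counts on real interfaces.
- The bend model has no energetics, no torque, and no discrete two-state
  switching; it generates conformations with the qualitative signatures of
  filament bending (convex/concave asymmetry, rigid domains, hinge-mediated
  head decoupling) for testing measurement code.
- `read_filament` reconstructs screw transforms from chain order and is
  intended for straight filaments written by this package.
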