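# helixlattice

Lattice algebra and model building for **heteropolymeric helical filaments** —
filaments such as the archaellum (the archaeal swimming propeller, a type-IV
filament relative) that are assembled from more than one subunit species on a
single helical lattice.

Cryo-EM helical reconstruction describes a filament by two numbers: the
**rise** Δz (Å) and **twist** Δφ (degrees) relating consecutive subunits.
When two chemically distinct but similar subunit species alternate on that
lattice, the true symmetry is not the 1-start screw: the smallest screw
operation mapping every subunit onto one *of the same species* is the p-step
operator, where p is the minimal period of the species labeling.  This
package provides the machinery to reason about exactly that situation:

- **Screw-operator algebra** (`symmetry`): operators T(k) = (k·Δz, k·Δφ),
  symmetry reduction Δz′ = p·Δz, Δφ′ = p·Δφ (mod 360°), k-start strand
  families with handedness, axial-column detection, helical net diagrams.
- **Register patterns** (`register`): species assignment on the s strands of
  a start family, `species(i) = (⌊i/s⌋ + offset[i mod s]) mod q`; minimal
  label periods, out-of-register strands, species pairs along any neighbour
  direction, stepped pseudo-strand motifs, and inference of the register
  from an observed label sequence.
- **Model building and I/O** (`structure`): place per-species monomers with
  the screw operators, one chain per subunit, mmCIF/PDB via gemmi; tail /
  hinge / head domain annotation; N-X-S/T glycosylation sequon scanning.
- **Contact analysis** (`contacts`): geometric hydrogen-bond and salt-bridge
  tallies between subunits, neighbour-offset contact maps, and tail
  center-line packing in the filament core.  (Distance-threshold counts
  only — no interface energetics.)
- **Bending forward model** (`bending`): map a straight filament onto a
  circular arc of curvature κ with rigid subunits, optional hinge swing of
  the head domain, and motion reports (displacement vectors, head motion
  after tail alignment, signed tail slide, head-centroid trajectories).
- **Synthetic fixtures** (`synth`): deterministic toy two-species monomers
  and a preset filament on the (5.57 Å, 108°) lattice with one of three
  3-start strands out of register — the geometry of the *Methanocaldococcus
  villosus* archaellum, in which two archaellins alternate along each
  3-start strand and the register shift makes the species lattice repeat
  only every 6 subunits (33.42 Å, −72°).

## Worked example

```python
import helixlattice as hx

sym = hx.HelicalSymmetry(rise=5.57, twist_raw=108.0)
lab = hx.labeling_from_register(hx.RegisterPattern(s=3, q=2, offsets=(0, 0, 1)))

print(lab.labels(12).tolist())
print(hx.minimal_label_period(lab))
red = hx.reduced_symmetry_for_labeling(sym, lab)
print(red.rise, red.twist)
print(sorted(hx.species_pairs_along(lab, 3)))
print(sorted(hx.species_pairs_along(lab, 7)))
print(hx.pseudo_strand_steps(lab, 0))
```

prints

```
[0, 0, 1, 1, 1, 0, 0, 0, 1, 1, 1, 0]
6
33.42 -72.0
[(0, 1), (1, 0)]
[(0, 0), (0, 1), (1, 0), (1, 1)]
(1, 1, 4)
```

meaning: with one strand out of register the species pattern repeats only
every 6 subunits, so the species-respecting helical symmetry is
33.42 Å / −72° rather than the naive 11.14 Å / 216° of an in-register
alternating filament; neighbours along the 3-start direction are always
heterotypic while the 7-start direction realizes all four ordered species
pairs; and tracing one species along the filament gives a broken
"stepped" pseudo-strand whose index gaps cycle (1, 1, 4).

The `examples/` directory has one short narrative script per capability
(symmetry reduction, register periods, 3D model building, contact maps,
bending).  Each builds its own input and prints what it computes.  A thin
`helixlattice` command-line tool wraps the same functions
(`helixlattice reduce-symmetry --rise 5.57 --twist 108 --period 6`, plus
`min-period`, `net-diagram`, `build`, `contacts`, `bend`, `fixtures`,
`infer-register`).

## Scope notes

Contact counts are geometric (distance thresholds on donor/acceptor and
charged-group heavy atoms); the package deliberately computes no
dissociation free energies, buried surface areas, map resolutions or
sequence identities, and the synthetic monomers are reduced
pseudo-atomic stand-ins, not deposited coordinates.  See
`docs/methods.md` for the model, conventions, parameters and limitations.
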