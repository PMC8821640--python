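"""Register patterns: why one out-of-register strand makes the period 6.

Two species alternate along each of the three 3-start strands.  If all three
strands were in phase, every second subunit along the 1-start would repeat the
species (period 2).  Shifting one strand by a single subunit breaks that
isotropy: the smallest index step that repeats the species pattern becomes 6.
"""

import helixlattice as hx

out_of_register = hx.RegisterPattern(s=3, q=2, offsets=(0, 0, 1))
lab = hx.labeling_from_register(out_of_register)

print("first 12 labels:", lab.labels(12).tolist())
print("minimal label period:", hx.minimal_label_period(lab))
print("out-of-register strands:", sorted(hx.out_of_register_strands(out_of_register)))

in_register = hx.labeling_from_register(hx.RegisterPattern(s=1, q=2, offsets=(0,)))
print("in-register alternation period:", hx.minimal_label_period(in_register))

sym = hx.HelicalSymmetry(rise=5.57, twist_raw=108.0)
red = hx.reduced_symmetry_for_labeling(sym, lab)
print(f"species-respecting symmetry: rise {red.rise:g} Å, twist {red.twist:g}°")

# Neighbour species depend on direction: strict alternation along the 3-start,
# all four ordered pairs along the 7-start.
print("species pairs along k=3:", sorted(hx.species_pairs_along(lab, 3)))
print("species pairs along k=7:", sorted(hx.species_pairs_along(lab, 7)))

# Tracing one species gives a broken, 'stepped' pseudo-strand: two single
# steps then a jump of four.
print("pseudo-strand gap motif:", hx.pseudo_strand_steps(lab, 0))

# The register can be recovered from an observed label sequence.
labels = hx.make_label_sequence(out_of_register, 24, error_rate=0.0, seed=7)
print("re-inferred register:", hx.infer_register(labels, 3, 2).offsets)
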