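"""Screw-operator arithmetic: from the 1-start lattice to the species lattice.

A helical filament with a 5.57 Å rise and 108° twist per subunit looks like a
homopolymer until you ask which screw operation maps every subunit onto one of
the SAME species.  For a two-species filament whose minimal label period is 6,
that operation is the 6-subunit screw.
"""

import helixlattice as hx

sym = hx.HelicalSymmetry(rise=5.57, twist_raw=108.0)

print("1-start lattice:", sym)

red6 = hx.reduce_symmetry(sym, 6)
print(f"every 6th subunit: rise {red6.rise:g} Å, twist {red6.twist:g}° "
      f"(raw {red6.twist_raw:g}°)")
# 33.42 Å / −72°: the symmetry a species-aware reconstruction must impose.

red2 = hx.reduce_symmetry(sym, 2)
print(f"every 2nd subunit: rise {red2.rise:g} Å, twist {red2.twist_raw:g}°")
# 11.14 Å / 216°: the symmetry of a hypothetical in-register alternating
# filament — the wrong choice for an out-of-register one.

for k in (3, 7, 10):
    fam = hx.start_family(sym, k)
    hand = "vertical columns" if fam.handedness == "vertical" else f"{fam.handedness}-handed"
    print(f"{k}-start family: {fam.n_strands} strands, step {fam.step_rise:g} Å "
          f"/ {fam.step_phi:g}°, {hand}")
# 3-start strands wind left (−36°/step), 7-start wind right (+36°/step), and
# every 10th subunit stacks into a vertical column (10 × 108° = 3 turns).
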