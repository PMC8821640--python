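"""Which neighbours does a subunit touch, and with which species?

For an interior subunit of the straight fixture filament, tally geometric
contacts against every neighbour n±k and reduce each tail to its center-line
segment to find the core packing pattern.
"""

import helixlattice as hx

model = hx.make_fixture_filament("mvillosus", n=36)
ref = 15

tails = hx.tail_core_contacts(model, ref)
print("tail-core contact offsets:", sorted(tails))
# {±1, ±3, ±4, ±7}: the reference tail packs against eight neighbours in the
# filament core — its 1-start, 3-start, 4-start and 7-start neighbours.

report = hx.neighbor_contact_map(model, ref, max_k=10)
print(f"({report.disclaimer})")
print(report.table.to_string(index=False))
# n_hbond / n_saltbridge are distance-threshold counts on the toy monomers;
# species_a/species_b show the heterotypic 3-start interfaces (0-1 / 1-0).
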