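"""Build the truncation/linker construct library and inspect its bookkeeping.

The assay tethers an N-terminal prefix of the 239-residue ankyrin domain to
the SecM arrest peptide through a variable linker.  Stage 1 shortens the
linker (39 -> 8 in steps of 5), stage 2 truncates the domain C-terminus in
5-residue steps at the minimal linker.
"""

from forceprofile import (
    ConstructSpec,
    build_construct,
    distance_to_ptc,
    generate_library,
    make_controls,
    repeats_spanned,
)

library = generate_library(domain_length=239)
print(f"library size: {len(library)} constructs, "
      f"L from {library[0].L} down to {library[-1].L}")

# The full protein held 40 residues from the PTC (the main folding peak).
full = build_construct(ConstructSpec("L279", domain_length=239, linker_length=23))
print(f"full construct: L = {full.L}, distance to PTC = {distance_to_ptc(full)}, "
      f"arrested chain {full.arrested_length} aa, full-length {full.full_length} aa")
# L = 279 and distance 40: the domain C-terminus clears the exit tunnel;
# the 23-residue tail difference is what separates the two gel bands.

fl_ctrl, arrest_ctrl = make_controls(full.spec)
print(f"controls: {fl_ctrl.name} (AP ...{fl_ctrl.ap.sequence[-4:]}, reads through), "
      f"{arrest_ctrl.name} (stop at AP proline, no tail)")

for domain_len in (239, 199, 164):
    span = repeats_spanned(domain_len)
    print(f"domain {domain_len} aa spans {span.n_full_repeats} full repeats "
          f"+ {span.tail_length} residue tail")
# 239 -> 7 repeats (intact domain); 199/164 -> the 1.5- and 2.5-repeat
# deletions that produce the two minor folding peaks.
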